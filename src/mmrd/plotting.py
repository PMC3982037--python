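"""Overlay plot of closed-form vs numeric concentration profiles."""

from __future__ import annotations

from pathlib import Path

from .core import Profile


def plot_overlay(pm: Profile, ref: Profile, path: str | Path) -> None:
    """Numeric reference as symbols, closed form as a solid line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    step = max(1, len(ref.grid) // 25)
    ax.plot(ref.grid.points[::step], ref.values[::step], "o",
            mfc="none", label=ref.method_tag)
    ax.plot(pm.grid.points, pm.values, "-", label=pm.method_tag)
    p = pm.params
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title(f"k={p.k:g}, alpha={p.alpha:g}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
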