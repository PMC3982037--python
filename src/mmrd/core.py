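"""Problem definition shared by the analytic and numeric solvers.

The model is the steady-state reaction-diffusion equation for a redox
mediator crossing an enzyme film of unit dimensionless thickness,

    y''(x) = k * y(x) / (1 + alpha * y(x)),      x in [0, 1],

with Dirichlet data ``y(0) = gamma0``, ``y(1) = gamma1``.  Here ``y`` is the
dimensionless mediator concentration, ``x`` the dimensionless distance into
the film, ``k`` a Thiele-modulus-like reaction-diffusion parameter and
``alpha`` the Michaelis-Menten saturation parameter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "KineticParams",
    "Grid",
    "Profile",
    "make_params",
    "make_uniform_grid",
]

#: Tags identifying which solver produced a profile.
METHOD_TAGS = frozenset(
    {"pm_first_order", "numeric_fd", "numeric_shooting", "linear_exact"}
)


@dataclass(frozen=True)
class KineticParams:
    """Dimensionless model parameters and Dirichlet boundary values.

    Parameters
    ----------
    k : float
        Reaction-diffusion parameter, strictly positive.
    alpha : float
        Saturation parameter, non-negative.  ``alpha = 0`` is the exactly
        linear limit.
    gamma0, gamma1 : float
        Mediator concentration at the film faces ``x = 0`` and ``x = 1``.
        Default 1 (mediator at bulk value on both faces).
    """

    k: float
    alpha: float
    gamma0: float = 1.0
    gamma1: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k", "alpha", "gamma0", "gamma1"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise TypeError(f"{name} must be a real number, got {v!r}")
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            object.__setattr__(self, name, float(v))
        if self.k <= 0.0:
            raise ValueError(f"k must be strictly positive, got {self.k}")
        if self.alpha < 0.0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")
        if self.gamma0 < 0.0 or self.gamma1 < 0.0:
            raise ValueError(
                "boundary concentrations gamma0 and gamma1 must be "
                f"non-negative, got ({self.gamma0}, {self.gamma1})"
            )

    def to_json(self) -> str:
        return json.dumps(
            {"k": self.k, "alpha": self.alpha,
             "gamma0": self.gamma0, "gamma1": self.gamma1}
        )

    @classmethod
    def from_json(cls, text: str) -> "KineticParams":
        d = json.loads(text)
        return cls(k=d["k"], alpha=d["alpha"],
                   gamma0=d["gamma0"], gamma1=d["gamma1"])


@dataclass(frozen=True)
class Grid:
    """Ordered evaluation abscissae on the closed interval [0, 1]."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 3:
            raise ValueError("grid needs at least 3 one-dimensional points")
        if pts[0] != 0.0 or pts[-1] != 1.0:
            raise ValueError("grid must span exactly [0, 1]")
        if not np.all(np.diff(pts) > 0.0):
            raise ValueError("grid points must be strictly increasing")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.size


@dataclass(frozen=True)
class Profile:
    """Concentration values on a grid, tagged with the producing method."""

    grid: Grid
    values: np.ndarray
    method_tag: str
    params: KineticParams
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.points.shape:
            raise ValueError("values and grid must have the same length")
        if not np.all(np.isfinite(vals)):
            raise ValueError("profile values must all be finite")
        if self.method_tag not in METHOD_TAGS:
            raise ValueError(f"unknown method_tag {self.method_tag!r}")
        object.__setattr__(self, "values", vals)

    def to_csv(self, path: str | Path) -> None:
        """Write the profile as ``x,y`` CSV at full double precision."""
        lines = ["x,y"]
        lines += [
            f"{x!r},{y!r}"
            for x, y in zip(self.grid.points.tolist(), self.values.tolist())
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, method_tag: str,
                 params: KineticParams) -> "Profile":
        rows = Path(path).read_text().strip().splitlines()
        if rows[0] != "x,y":
            raise ValueError("expected 'x,y' header")
        xy = np.array([[float(c) for c in r.split(",")] for r in rows[1:]])
        return cls(Grid(xy[:, 0]), xy[:, 1], method_tag, params)


def make_params(k: float, alpha: float,
                gamma0: float = 1.0, gamma1: float = 1.0) -> KineticParams:
    """Validate and build the model parameters (see :class:`KineticParams`)."""
    return KineticParams(k=k, alpha=alpha, gamma0=gamma0, gamma1=gamma1)


def make_uniform_grid(n: int) -> Grid:
    """Uniform grid of ``n >= 3`` points with exact endpoints 0 and 1."""
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise TypeError(f"n must be an integer, got {n!r}")
    if n < 3:
        raise ValueError(f"grid size must be at least 3, got {n}")
    pts = np.linspace(0.0, 1.0, int(n))
    pts[0], pts[-1] = 0.0, 1.0  # linspace guarantees this; keep bit-exact
    return Grid(pts)


def profiles_compatible(a: Profile, b: Profile) -> bool:
    """True when two profiles share the same grid and model parameters."""
    return (
        np.array_equal(a.grid.points, b.grid.points)
        and a.params == b.params
    )
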