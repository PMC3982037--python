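# mmrd — Michaelis–Menten reaction–diffusion mediator transport

Solvers for the steady-state transport of a redox mediator across an enzyme
film in mediated bioelectrocatalysis (amperometric biosensors, bioreactors,
biofuel cells). The dimensionless model is the two-point boundary-value
problem

```
y''(x) = k·y(x) / (1 + α·y(x)),      x ∈ [0, 1],
y(0) = γ₀,   y(1) = γ₁,
```

where `y` is the mediator concentration, `x` the distance into the film,
`k > 0` a Thiele-modulus-like reaction–diffusion parameter, and `α ≥ 0` the
Michaelis–Menten saturation parameter. By default γ₀ = γ₁ = 1 (mediator at
bulk concentration on both faces).

## What the package computes

**Closed form (perturbation series).** Truncating the rational kinetics with
the binomial `1/(1+αy) ≈ 1 − αy` and expanding `y = y₀ + α·y₁ + O(α²)` gives
a cascade of linear problems:

- `y₀'' = k·y₀` with the Dirichlet data — solved by
  `y₀ = A·e^{√k·x} + B·e^{−√k·x}`;
- `y₁'' − k·y₁ = −k·y₀²` with `y₁(0) = y₁(1) = 0` — solved in closed form by
  variation of parameters on the basis `(e^{√k·x}, e^{−√k·x})` (Wronskian
  `W = −2√k`), plus a homogeneous correction that zeroes `y₁` at both faces.

The assembled approximation `y = y₀ + α·y₁` is exact at α = 0 and has an
O(α²) defect. Internally all exponentials are evaluated in scaled form so
the boundary-layer regime (k up to 100 and beyond) is handled without loss
of precision.

**Numerical references.** A fourth-order Runge–Kutta shooting solver
(safeguarded secant iteration on the initial slope) and a finite-difference
damped-Newton solver (tridiagonal Jacobian); the latter is robust for all
parameter values and serves as the oracle in the comparison harness.

**Comparison harness.** Pointwise error metrics and a case-study sweep over
α ∈ {0.1, 1, 1.5} × k ∈ {0.1, 1, 5, 10, 20, 50, 100}, exported as CSV/JSON.

## Worked example

```python
from mmrd import (make_params, make_uniform_grid, pm_solution, pm_flux,
                  solve_bvp_fd, SolverConfig, compare_profiles)
from mmrd.comparison import restrict_profile

params = make_params(k=1.0, alpha=0.1)      # film with mild saturation
y = pm_solution(params)                      # closed-form approximation
print(f"y(0.5)  = {float(y(0.5)):.6f}")
print(f"y'(0)   = {pm_flux(params, 0.0):.6f}")

grid = make_uniform_grid(101)
ref = restrict_profile(solve_bvp_fd(params, SolverConfig(n=4001)), grid)
metrics = compare_profiles(y.profile(grid), ref)
print(f"max|PM - FD| = {metrics.max_abs_err:.2e} at x = {metrics.at_x}")
```

prints

```
y(0.5)  = 0.896099
y'(0)   = -0.422485
max|PM - FD| = 6.40e-04 at x = 0.5
```

The mediator is depleted mid-film to about 0.90 of its bulk value, the flux
into the film at `x = 0` is 0.42 in dimensionless units, and the closed form
tracks the fully nonlinear solution to 6×10⁻⁴ — far below figure resolution.

The same is available from the shell:

```sh
mmrd pm --k 1 --alpha 0.1 --out profile.csv     # closed-form profile
mmrd numeric --k 1 --alpha 0.1 --method fd      # nonlinear reference
mmrd compare --k 1 --alpha 0.1 --out cmp.json   # error metrics
mmrd sweep --out sweep.csv                      # full 21-case study
```

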