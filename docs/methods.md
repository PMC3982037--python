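# Methods

## Model and assumptions

The package solves the steady-state, one-dimensional reaction–diffusion
equation for a redox mediator in an enzyme film of unit dimensionless
thickness,

    y'' = k·y / (1 + α·y),   y(0) = γ₀,  y(1) = γ₁,

with `y ≥ 0` the dimensionless mediator concentration and `x ∈ [0, 1]` the
dimensionless position. The rational reaction term is the Michaelis–Menten
rate law: for small `α·y` consumption is first order in `y`; for large
`α·y` it saturates at `k/α`. All quantities are dimensionless:

| parameter | meaning | default | constraint |
|---|---|---|---|
| `k` | reaction rate / diffusive transport (Thiele-modulus-like) | — | `k > 0` |
| `α` | saturation of the kinetics with concentration | — | `α ≥ 0` |
| `γ₀, γ₁` | mediator concentration at the film faces | 1 | finite, `≥ 0` |

The default `γ₀ = γ₁ = 1` describes a film bathed in bulk mediator on both
faces; every code path is identical for any other Dirichlet pair. For
non-negative boundary data the solution obeys a maximum principle,
`0 ≤ y ≤ max(γ₀, γ₁)`: the reaction term has the sign of `y`, so the
profile is convex wherever positive and cannot cross zero.

The model is steady-state only; transient dynamics, flux (Robin) boundary
conditions, and electrochemical current–voltage coupling are out of scope.

## The perturbation closed form

The rational nonlinearity is first truncated binomially,
`1/(1+αy) ≈ 1 − αy`, giving `y'' = k·y·(1 − α·y)` with an O(α²y²) defect.
Expanding `y = y₀ + α·y₁ + O(α²)` and collecting powers of α (the
truncation order is exactly first; higher orders are an untested extension
point):

* **Order 1:** `y₀'' = k·y₀` with the full Dirichlet data. With `s = √k`,
  `y₀ = A·e^{sx} + B·e^{−sx}`, where `A + B = γ₀` and
  `A·e^s + B·e^{−s} = γ₁`; the 2×2 system is never singular for `k > 0`.
* **Order α:** `y₁'' − k·y₁ = −k·y₀²` with `y₁(0) = y₁(1) = 0`. Variation
  of parameters on the basis `(e^{sx}, e^{−sx})`, whose Wronskian is the
  constant `W = −2s`, gives the two antiderivatives

      I₁(x) = ∫ e^{−sx}·f(x)/W dx = (A²e^{sx} − 2AB·e^{−sx} − (B²/3)e^{−3sx})/2
      I₂(x) = ∫ e^{sx}·f(x)/W dx  = ((A²/3)e^{3sx} + 2AB·e^{sx} − B²e^{−sx})/2

  with `f = −k·y₀²`. The particular solution `−e^{sx}I₁ + e^{−sx}I₂`
  collapses to `y_p = −(A²/3)e^{2sx} + 2AB − (B²/3)e^{−2sx}`, and a
  homogeneous correction `C₁e^{sx} + C₂e^{−sx}` (same 2×2 structure as
  A, B) enforces the zero boundary values.

The assembled approximation is `y = y₀ + α·y₁`. It is exact for `α = 0`,
meets the boundary data exactly at every order, and its defect in the full
nonlinear equation is `α²k(2y₀y₁ − y₀³) + O(α³)` — the residual-scaling
test measures exactly this quadratic signature.

`α = 0` is admitted throughout even though the series treats α as the
small parameter: the linear limit is the key verification case.

### Numerical evaluation at large k

Each exponential monomial is evaluated in a scaled form whose exponent is
never positive after absorbing the coefficient's own `e^{−s}` factors
(e.g. `A·e^{sx}` is computed as `c_a·e^{−s(1−x)}` with
`c_a = (γ₁ − γ₀e^{−s})/(1 − e^{−2s})`). This avoids both overflow and the
catastrophic cancellation of differences of huge exponentials in the
boundary-layer regime; agreement with a 50-digit evaluation of the naive
formulas is at the 1e-15 relative level at `k = 100` (tested to 1e-9).
The representation overflows only for `√k` beyond ~700.

A degenerate zero-exponent monomial would integrate to a linear-in-x term;
for `k > 0` no such term arises (the constant `2AB` in `f` acquires the
basis exponential before integration), but the integrands are assembled
term-by-term so the structure is explicit.

## Numerical reference solvers

**Finite differences + damped Newton (`fd_newton`, the oracle).** Central
second differences on a uniform grid; the Newton step solves the
tridiagonal Jacobian system via banded LU (`scipy.linalg.solve_banded`).
The step is halved (up to 20 times) while the residual norm does not
decrease, which gives global convergence from the linear-interpolation
initial guess even at `α·k` ~ 150. Convergence is declared when the
largest update falls below `tol` or the residual reaches its rounding
floor (`5e-15/h²`, the noise level of the discrete operator — a linear
problem therefore converges in one step). Defaults: `n = 2001`
(`n = 4001` in the comparison harness), `tol = 1e-10`, `max_iter = 50`.
The discretization error is O(h²); at `n = 4001` and `k = 100` it is
~1e-7, well below the O(1e-4…1e-1) discrepancies being measured. The
linear-limit test uses `n = 8001`, where the FD error is ≤ 2.4e-8 across
the whole k grid.

**RK4 shooting (`shooting_rk4`, the comparator).** Classic fixed-step
fourth-order Runge–Kutta on `(y, y')` with `h = 1/(n−1)`, `n = 1001`, and
iteration on the unknown initial slope. The terminal map has two
pathologies: trajectory amplification ~`e^{√k}`, and chaotic behaviour
once a trial trajectory approaches the pole of `1 + α·y` (for `α = 1`,
slope errors of 1e-4 at `k = 20` already send trajectories through it).
The implementation therefore (1) seeds from the closed-form slope rather
than the linear-problem slope — the seed only has to land in the smooth
basin, the converged answer does not depend on it; (2) expands
geometrically to a sign-change bracket, treating diverged trials as signed
infinities; (3) mixes secant steps with bisection whenever a secant step
would leave the bracket; and (4) rejects converged-but-unphysical
trajectories (outside `[0, max(γ₀, γ₁)]`, see the maximum principle) as
spurious roots, signalling stiffness. At `k ∈ {50, 100}` with `α ≥ 1` the
slope must be resolved beyond double precision and the solver legitimately
signals failure; the FD result stands as reference there.

## Comparison harness

Profiles are compared on a shared 101-point uniform grid (resolves every
feature at figure scale; the whole 21-case sweep runs in well under a
second). The fine FD solution is restricted to the comparison grid by
exact index extraction when the grids nest, cubic spline otherwise.
Reported metrics: max absolute difference and its location (ties take the
smallest x), RMSE, and the maximum ODE residual of the closed form on the
interior points. Failed solver rows are recorded with a status flag, never
dropped silently; the CSV report carries the status as a final column and
re-exports byte-identically.

Because the original case study reports agreement only graphically, the
accuracy baseline is oracle-based: the 21 max-error values against the FD
reference at `n = 4001` were computed once and frozen as regression
fixtures (`tests/data/sweep_regression.json`); the suite requires them to
reproduce to 1e-9.

## What the tests do and do not show

The study conditions are fully synthetic — scalar parameters on a printed
grid with unit boundary data — so there is no generator noise model; the
"data" are the 21 parameter pairs themselves, and every computation is
deterministic (no random seeds anywhere). Passing tests show that the
closed form is implemented exactly as derived, that it agrees with two
independent nonlinear solvers at the O(α²) level the series predicts, and
that all invariants (boundary exactness, symmetry, maximum principle,
Wronskian constancy, quadrature identities) hold across the grid. They do
not show anything about fitting `k`, `α` to experimental currents, about
transient behaviour, or about kinetics outside the Michaelis–Menten form.

## Known limitations

* Accuracy degrades as O(α²); at `α = 1.5` the worst-case profile error is
  ~8e-2 (recorded per case in the sweep report).
* The shooting solver is a fixed-step comparator, not a production BVP
  method; use `fd_newton` for reliable references.
* Grids are uniform on [0, 1]; no adaptive refinement for extreme
  boundary layers (`k ≫ 100` needs a larger `n`).
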