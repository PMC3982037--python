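"""First-order perturbation-series solution of the mediator transport problem.

The nonlinear boundary-value problem

    y'' = k * y / (1 + alpha * y),   y(0) = gamma0,  y(1) = gamma1,

is first linearized with the binomial truncation
``1/(1 + alpha*y) ~ 1 - alpha*y``, turning the rational Michaelis-Menten
term into the polynomial forcing ``k*y*(1 - alpha*y)``.  Treating the
saturation parameter ``alpha`` as the perturbation parameter and expanding
``y = y0 + alpha*y1 + O(alpha^2)`` yields a cascade of linear problems:

    order 1:      y0'' - k*y0 = 0,          y0(0) = gamma0, y0(1) = gamma1
    order alpha:  y1'' - k*y1 = -k*y0**2,   y1(0) = y1(1) = 0

The zeroth order is the classical linear mediator profile
``y0 = A*exp(s*x) + B*exp(-s*x)`` with ``s = sqrt(k)``.  The first-order
correction is built by variation of parameters on the homogeneous basis
``(exp(s*x), exp(-s*x))`` with constant Wronskian ``W = -2*s``, giving the
closed-form particular integrals I1, I2 and a homogeneous correction
``C1*exp(s*x) + C2*exp(-s*x)`` that zeroes the correction at both film
faces.  The assembled approximation is ``y = y0 + alpha*y1``.

Internally every exponential term is evaluated in a scaled form whose
exponents never exceed ``s`` (e.g. ``A*exp(s*x)`` becomes
``ca*exp(-s*(1-x))``), so profiles stay accurate in the boundary-layer
regime of large ``k`` where differences of huge exponentials would lose
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Tuple

import numpy as np

from .core import Grid, KineticParams, Profile

__all__ = [
    "HomogeneousBasis",
    "ZerothOrderSolution",
    "FirstOrderSolution",
    "PMApproximation",
    "linearize_rhs",
    "homogeneous_basis",
    "solve_zeroth_order",
    "first_order_rhs",
    "particular_integrals",
    "solve_first_order",
    "pm_solution",
    "pm_residual",
    "pm_flux",
]


def linearize_rhs(params: KineticParams, y):
    """Binomially linearized reaction term ``k*y*(1 - alpha*y)``.

    First-order truncation of ``k*y/(1 + alpha*y)``; exact when alpha = 0.
    """
    return params.k * y * (1.0 - params.alpha * y)


@dataclass(frozen=True)
class HomogeneousBasis:
    """Exponential basis of ``u'' - k*u = 0`` and its constant Wronskian."""

    sqrt_k: float

    @property
    def wronskian(self) -> float:
        """W = yh1*yh2' - yh2*yh1' = -2*sqrt(k), independent of x."""
        return -2.0 * self.sqrt_k

    def yh1(self, x):
        return np.exp(self.sqrt_k * x)

    def yh2(self, x):
        return np.exp(-self.sqrt_k * x)

    def dyh1(self, x):
        return self.sqrt_k * np.exp(self.sqrt_k * x)

    def dyh2(self, x):
        return -self.sqrt_k * np.exp(-self.sqrt_k * x)


def homogeneous_basis(k: float) -> HomogeneousBasis:
    """Basis ``(exp(sqrt(k)*x), exp(-sqrt(k)*x))`` for ``u'' = k*u``."""
    if not (k > 0.0) or not math.isfinite(k):
        raise ValueError(f"k must be strictly positive, got {k}")
    return HomogeneousBasis(sqrt_k=math.sqrt(k))


def _dirichlet_exp_coeffs(s: float, v0: float, v1: float) -> Tuple[float, float]:
    """Scaled coefficients (ca, cb) of ``u = A*e^{s x} + B*e^{-s x}`` with
    ``u(0)=v0, u(1)=v1``, where ``A = ca*e^{-s}`` and ``B = cb``.

    Writing ``A*e^{s x} = ca*e^{-s (1-x)}`` keeps every evaluated exponent
    non-positive, which is the cancellation-safe form at large s.
    """
    em = math.exp(-s)
    denom = 1.0 - em * em  # = e^{-s} * (e^s - e^{-s}) > 0 for s > 0
    ca = (v1 - v0 * em) / denom
    cb = (v0 - v1 * em) / denom
    return ca, cb


@dataclass(frozen=True)
class ZerothOrderSolution:
    """Linear-limit profile ``y0 = A*exp(s*x) + B*exp(-s*x)``.

    A and B solve ``A + B = gamma0``, ``A*e^s + B*e^-s = gamma1``.
    """

    A: float
    B: float
    params: KineticParams
    _ca: float = field(repr=False, default=0.0)
    _cb: float = field(repr=False, default=0.0)

    @property
    def sqrt_k(self) -> float:
        return math.sqrt(self.params.k)

    def term_a(self, x):
        """``A*exp(s*x)`` in overflow/cancellation-safe form."""
        return self._ca * np.exp(-self.sqrt_k * (1.0 - np.asarray(x, float)))

    def term_b(self, x):
        """``B*exp(-s*x)``."""
        return self._cb * np.exp(-self.sqrt_k * np.asarray(x, float))

    def __call__(self, x):
        return self.term_a(x) + self.term_b(x)

    def derivative(self, x):
        return self.sqrt_k * (self.term_a(x) - self.term_b(x))


def solve_zeroth_order(params: KineticParams) -> ZerothOrderSolution:
    """Solve the order-1 problem ``y0'' = k*y0`` with the Dirichlet data."""
    s = math.sqrt(params.k)
    ca, cb = _dirichlet_exp_coeffs(s, params.gamma0, params.gamma1)
    return ZerothOrderSolution(
        A=ca * math.exp(-s), B=cb, params=params, _ca=ca, _cb=cb
    )


def first_order_rhs(zeroth: ZerothOrderSolution, x):
    """Forcing ``f(x) = -k*y0(x)**2`` of the correction equation.

    Collecting the order-alpha terms of the linearized equation under the
    series expansion gives ``y1'' - k*y1 = -k*y0**2``.
    """
    y0 = zeroth(x)
    return -zeroth.params.k * y0 * y0


def particular_integrals(
    zeroth: ZerothOrderSolution,
) -> Tuple[Callable, Callable]:
    """Closed-form variation-of-parameters antiderivatives (I1, I2).

    I1 is an antiderivative of ``yh2*f/W`` and I2 of ``yh1*f/W`` with
    ``f = -k*y0^2`` and ``W = -2*sqrt(k)``.  Each integrand is a sum of
    exponential monomials ``exp(c*sqrt(k)*x)``, c in {-3, -1, 1, 3},
    integrated term by term:

        I1(x) = (A^2*e^{s x} - 2AB*e^{-s x} - (B^2/3)*e^{-3 s x}) / 2
        I2(x) = ((A^2/3)*e^{3 s x} + 2AB*e^{s x} - B^2*e^{-s x}) / 2

    A zero-exponent monomial (which would integrate to a linear-in-x term)
    cannot arise here: for k > 0 the products of the basis exponentials
    always carry a nonzero exponent.
    """
    A, B, s = zeroth.A, zeroth.B, zeroth.sqrt_k
    ca, cb = zeroth._ca, zeroth._cb

    def I1(x):
        x = np.asarray(x, float)
        # A^2 e^{s x} = ca^2 e^{s(x-2)};  AB e^{-s x} = ca cb e^{-s(1+x)}
        return 0.5 * (
            ca * ca * np.exp(s * (x - 2.0))
            - 2.0 * ca * cb * np.exp(-s * (1.0 + x))
            - (cb * cb / 3.0) * np.exp(-3.0 * s * x)
        )

    def I2(x):
        x = np.asarray(x, float)
        # A^2 e^{3 s x} = ca^2 e^{s(3x-2)};  AB e^{s x} = ca cb e^{s(x-1)}
        return 0.5 * (
            (ca * ca / 3.0) * np.exp(s * (3.0 * x - 2.0))
            + 2.0 * ca * cb * np.exp(s * (x - 1.0))
            - cb * cb * np.exp(-s * x)
        )

    return I1, I2


@dataclass(frozen=True)
class FirstOrderSolution:
    """Correction ``y1 = -yh1*I1 + yh2*I2 + C1*yh1 + C2*yh2``.

    The particular part collapses to
    ``y_p = -(A^2/3)e^{2 s x} + 2AB - (B^2/3)e^{-2 s x}``;
    C1, C2 enforce ``y1(0) = y1(1) = 0``.
    """

    zeroth: ZerothOrderSolution
    I1: Callable = field(compare=False)
    I2: Callable = field(compare=False)
    C1: float = 0.0
    C2: float = 0.0
    _hca: float = field(repr=False, default=0.0)
    _hcb: float = field(repr=False, default=0.0)

    # -- scaled building blocks -------------------------------------------
    def _yp(self, x):
        z = self.zeroth
        ta, tb = z.term_a(x), z.term_b(x)
        return -(ta * ta) / 3.0 + 2.0 * z.A * z.B - (tb * tb) / 3.0

    def _dyp(self, x):
        z = self.zeroth
        s = z.sqrt_k
        ta, tb = z.term_a(x), z.term_b(x)
        return (2.0 * s / 3.0) * (tb * tb - ta * ta)

    def _hom(self, x):
        s = self.zeroth.sqrt_k
        x = np.asarray(x, float)
        return self._hca * np.exp(-s * (1.0 - x)) + self._hcb * np.exp(-s * x)

    def _dhom(self, x):
        s = self.zeroth.sqrt_k
        x = np.asarray(x, float)
        return s * (
            self._hca * np.exp(-s * (1.0 - x)) - self._hcb * np.exp(-s * x)
        )

    # -- public evaluators -------------------------------------------------
    def __call__(self, x):
        return self._yp(x) + self._hom(x)

    def derivative(self, x):
        return self._dyp(x) + self._dhom(x)

    def second_derivative(self, x):
        """Analytic ``y1'' = k*y1 - k*y0^2`` (the defining ODE, exact)."""
        k = self.zeroth.params.k
        y0 = self.zeroth(x)
        return k * self(x) - k * y0 * y0


def solve_first_order(zeroth: ZerothOrderSolution) -> FirstOrderSolution:
    """Build y1 via variation of parameters and zero Dirichlet correction."""
    s = zeroth.sqrt_k
    I1, I2 = particular_integrals(zeroth)
    A, B = zeroth.A, zeroth.B
    # particular part at the two boundaries (scaled forms)
    ca, cb = zeroth._ca, zeroth._cb
    em = math.exp(-s)
    yp0 = -(ca * em) ** 2 / 3.0 + 2.0 * A * B - cb * cb / 3.0
    yp1 = -(ca * ca) / 3.0 + 2.0 * A * B - (cb * em) ** 2 / 3.0
    hca, hcb = _dirichlet_exp_coeffs(s, -yp0, -yp1)
    return FirstOrderSolution(
        zeroth=zeroth, I1=I1, I2=I2,
        C1=hca * em, C2=hcb, _hca=hca, _hcb=hcb,
    )


@dataclass(frozen=True)
class PMApproximation:
    """Assembled first-order approximation ``y(x) = y0(x) + alpha*y1(x)``."""

    zeroth: ZerothOrderSolution
    first: FirstOrderSolution
    params: KineticParams

    def __call__(self, x):
        return self.zeroth(x) + self.params.alpha * self.first(x)

    def derivative(self, x):
        return (
            self.zeroth.derivative(x)
            + self.params.alpha * self.first.derivative(x)
        )

    def second_derivative(self, x):
        """Analytic ``y'' = k*y0 + alpha*(k*y1 - k*y0^2)``."""
        k, a = self.params.k, self.params.alpha
        y0 = self.zeroth(x)
        return k * y0 + a * (k * self.first(x) - k * y0 * y0)

    def profile(self, grid: Grid) -> Profile:
        return Profile(
            grid=grid,
            values=self(grid.points),
            method_tag="pm_first_order",
            params=self.params,
        )


def pm_solution(params: KineticParams) -> PMApproximation:
    """First-order perturbation approximation for the given parameters."""
    zeroth = solve_zeroth_order(params)
    first = solve_first_order(zeroth)
    return PMApproximation(zeroth=zeroth, first=first, params=params)


def pm_residual(params: KineticParams, x) -> float:
    """Defect of the PM closed form in the full nonlinear equation.

    Returns ``y''(x) - k*y(x)/(1 + alpha*y(x))`` with y'' from the closed
    form; O(alpha^2) by construction, identically ~0 when alpha = 0.
    """
    approx = pm_solution(params)
    y = approx(x)
    return approx.second_derivative(x) - params.k * y / (1.0 + params.alpha * y)


def pm_flux(params: KineticParams, x) -> float:
    """Dimensionless mediator flux ``y'(x)`` of the PM closed form."""
    return pm_solution(params).derivative(x)
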