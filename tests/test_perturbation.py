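"""Oracle tests for the perturbation-series closed form.

Each closed-form ingredient is checked against an independent route:
direct arithmetic, adaptive quadrature, a tridiagonal finite-difference
solve of the correction equation, symbolic algebra, and a 50-digit
high-precision evaluation of the naive exponential formulas.
"""

import math

import mpmath as mp
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.linalg import solve_banded

from mmrd import KineticParams, make_params, make_uniform_grid, pm_flux, pm_residual, pm_solution
from mmrd.perturbation import (
    first_order_rhs,
    homogeneous_basis,
    linearize_rhs,
    particular_integrals,
    solve_first_order,
    solve_zeroth_order,
)
from conftest import CASE_GRID, CASE_KS


class TestLinearizedRhs:
    @pytest.mark.parametrize(
        "k,alpha,y,expected",
        [(1, 0, 0.5, 0.5), (1, 1, 0.0, 0.0), (2, 0.1, 1.0, 1.8)],
    )
    def test_values(self, k, alpha, y, expected):
        p = make_params(k, alpha)
        assert linearize_rhs(p, y) == pytest.approx(expected, abs=1e-15)

    def test_truncation_error_is_second_order(self):
        """k*y*(1-a*y) approximates k*y/(1+a*y) with an O(a^2) defect."""
        k, y = 2.0, 1.0
        for alpha in (0.1, 0.05):
            p = make_params(k, alpha)
            defect = abs(linearize_rhs(p, y) - k * y / (1 + alpha * y))
            # defect = k*y*a^2*y^2/(1+a*y)
            assert defect == pytest.approx(
                k * alpha**2 * y**3 / (1 + alpha * y), rel=1e-12
            )


class TestHomogeneousBasis:
    @pytest.mark.parametrize("k,w", [(4.0, -4.0), (1.0, -2.0), (100.0, -20.0)])
    def test_wronskian_value(self, k, w):
        assert homogeneous_basis(k).wronskian == pytest.approx(w, rel=1e-15)

    @pytest.mark.parametrize("k", [0.1, 1.0, 25.0])
    def test_wronskian_constant_in_x(self, k):
        b = homogeneous_basis(k)
        for x in (0.0, 0.25, 0.3, 0.8, 1.0):
            w = b.yh1(x) * b.dyh2(x) - b.yh2(x) * b.dyh1(x)
            assert w == pytest.approx(-2.0 * math.sqrt(k), rel=1e-12)

    def test_basis_members_solve_the_ode(self):
        """u'' = k*u for both exponentials, via a central stencil."""
        k, h = 3.0, 1e-4
        b = homogeneous_basis(k)
        for u in (b.yh1, b.yh2):
            for x in (0.1, 0.5, 0.9):
                d2 = (u(x - h) - 2 * u(x) + u(x + h)) / h**2
                assert d2 == pytest.approx(k * u(x), rel=1e-7)

    def test_reciprocal_product(self):
        b = homogeneous_basis(1.0)
        for x in (0.0, 0.3, 1.0):
            assert b.yh1(x) * b.yh2(x) == pytest.approx(1.0, rel=1e-15)

    def test_nonpositive_k_rejected(self):
        for k in (0.0, -1.0):
            with pytest.raises(ValueError):
                homogeneous_basis(k)


class TestZerothOrder:
    def test_symmetric_unit_coefficients(self):
        """For k=1, gamma0=gamma1=1: A = 1/(1+e), B = e/(1+e)."""
        z = solve_zeroth_order(make_params(1.0, 0.1))
        assert z.A == pytest.approx(1.0 / (1.0 + math.e), rel=1e-14)
        assert z.B == pytest.approx(math.e / (1.0 + math.e), rel=1e-14)
        assert z.A + z.B == pytest.approx(1.0, rel=1e-14)

    def test_midpoint_against_cosh_form(self):
        """Symmetric data: y0(x) = cosh(sqrt(k)(x-1/2))/cosh(sqrt(k)/2)."""
        for k in (1.0, 10.0, 100.0):
            z = solve_zeroth_order(make_params(k, 0.0))
            s = math.sqrt(k)
            for x in (0.0, 0.3, 0.5, 0.9):
                expect = math.cosh(s * (x - 0.5)) / math.cosh(s / 2)
                assert z(x) == pytest.approx(expect, rel=1e-12)

    def test_zero_boundary_data(self):
        z = solve_zeroth_order(make_params(5.0, 1.0, gamma0=0.0, gamma1=0.0))
        assert z.A == 0.0 and z.B == 0.0
        assert np.all(z(np.linspace(0, 1, 11)) == 0.0)

    @pytest.mark.parametrize("k,alpha", CASE_GRID)
    def test_boundary_exactness(self, k, alpha):
        z = solve_zeroth_order(make_params(k, alpha))
        assert z(0.0) == pytest.approx(1.0, rel=1e-12)
        assert z(1.0) == pytest.approx(1.0, rel=1e-12)

    def test_asymmetric_boundary_system(self):
        """A, B solve A+B=g0, A*e^s+B*e^-s=g1 (checked via numpy solve)."""
        p = make_params(7.0, 0.0, gamma0=0.8, gamma1=0.2)
        z = solve_zeroth_order(p)
        s = math.sqrt(7.0)
        A, B = np.linalg.solve(
            [[1.0, 1.0], [math.exp(s), math.exp(-s)]], [0.8, 0.2]
        )
        assert z.A == pytest.approx(A, rel=1e-12)
        assert z.B == pytest.approx(B, rel=1e-12)


class TestFirstOrderForcing:
    def test_forcing_values(self):
        z = solve_zeroth_order(make_params(1.0, 0.1))
        assert first_order_rhs(z, 0.0) == pytest.approx(-1.0, rel=1e-12)
        assert first_order_rhs(z, 0.5) == pytest.approx(
            -z(0.5) ** 2, rel=1e-14
        )
        assert first_order_rhs(z, 0.5) == pytest.approx(-0.786448, abs=5e-7)

    def test_zero_for_zero_data(self):
        z = solve_zeroth_order(make_params(2.0, 1.0, gamma0=0.0, gamma1=0.0))
        assert first_order_rhs(z, 0.4) == 0.0


class TestParticularIntegrals:
    @pytest.mark.parametrize("k", [0.1, 1.0, 20.0])
    def test_against_adaptive_quadrature(self, k):
        """Closed-form antiderivatives of yh2*f/W and yh1*f/W."""
        z = solve_zeroth_order(make_params(k, 1.0))
        I1, I2 = particular_integrals(z)
        s = z.sqrt_k
        for x in (0.2, 0.7, 1.0):
            q1, _ = quad(
                lambda t: math.exp(-s * t) * first_order_rhs(z, t) / (-2 * s),
                0, x, epsabs=1e-13, epsrel=1e-13,
            )
            q2, _ = quad(
                lambda t: math.exp(s * t) * first_order_rhs(z, t) / (-2 * s),
                0, x, epsabs=1e-13, epsrel=1e-13,
            )
            assert float(I1(x) - I1(0.0)) == pytest.approx(q1, abs=1e-9)
            assert float(I2(x) - I2(0.0)) == pytest.approx(q2, abs=1e-9)

    def test_constant_for_zero_forcing(self):
        z = solve_zeroth_order(make_params(3.0, 1.0, gamma0=0.0, gamma1=0.0))
        I1, I2 = particular_integrals(z)
        xs = np.linspace(0, 1, 7)
        assert np.all(I1(xs) == I1(0.0))
        assert np.all(I2(xs) == I2(0.0))

    def test_leibniz_identity(self):
        """d/dx[-yh1*I1 + yh2*I2] == -yh1'*I1 + yh2'*I2.

        The variation-of-parameters construction makes the terms containing
        I1', I2' cancel (fundamental theorem of calculus); the particular
        solution's derivative only sees the basis derivatives.
        """
        z = solve_zeroth_order(make_params(2.0, 1.0))
        I1, I2 = particular_integrals(z)
        b = homogeneous_basis(2.0)
        h = 1e-6

        def yp(x):
            return -b.yh1(x) * I1(x) + b.yh2(x) * I2(x)

        for x in (0.2, 0.5, 0.8):
            lhs = (yp(x + h) - yp(x - h)) / (2 * h)
            rhs = -b.dyh1(x) * I1(x) + b.dyh2(x) * I2(x)
            assert lhs == pytest.approx(float(rhs), abs=1e-6)


def _fd_linear_correction(k, zeroth, n=2001):
    """Independent tridiagonal FD solve of y1'' - k*y1 = -k*y0^2, y1=0 at ends."""
    x = np.linspace(0.0, 1.0, n)
    h2 = (x[1] - x[0]) ** 2
    xi = x[1:-1]
    rhs = -k * zeroth(xi) ** 2
    ab = np.zeros((3, n - 2))
    ab[0, 1:] = 1.0 / h2
    ab[1, :] = -2.0 / h2 - k
    ab[2, :-1] = 1.0 / h2
    sol = solve_banded((1, 1), ab, rhs)
    return x, np.concatenate(([0.0], sol, [0.0]))


class TestFirstOrderSolution:
    def test_zero_data_gives_zero_correction(self):
        z = solve_zeroth_order(make_params(4.0, 1.0, gamma0=0.0, gamma1=0.0))
        f = solve_first_order(z)
        assert np.all(f(np.linspace(0, 1, 9)) == 0.0)

    @pytest.mark.parametrize("k,alpha", CASE_GRID)
    def test_zero_boundary_conditions(self, k, alpha):
        f = solve_first_order(solve_zeroth_order(make_params(k, alpha)))
        assert abs(f(0.0)) <= 1e-12
        assert abs(f(1.0)) <= 1e-12

    def test_against_fd_solve_of_correction_equation(self):
        k = 1.0
        z = solve_zeroth_order(make_params(k, 0.1))
        f = solve_first_order(z)
        x, y1_fd = _fd_linear_correction(k, z)
        idx = np.arange(0, 2001, 200)  # 11 uniform points
        np.testing.assert_allclose(f(x[idx]), y1_fd[idx], atol=1e-6)

    @pytest.mark.parametrize("k", [0.1, 5.0, 100.0])
    def test_cascade_ode_via_stencil(self, k):
        """y1'' - k*y1 + k*y0^2 = 0 with a 5-point stencil second derivative."""
        z = solve_zeroth_order(make_params(k, 1.5))
        f = solve_first_order(z)
        h = 1e-4
        for x in np.linspace(0.1, 0.9, 9):
            d2 = (
                -f(x - 2 * h) + 16 * f(x - h) - 30 * f(x)
                + 16 * f(x + h) - f(x + 2 * h)
            ) / (12 * h**2)
            assert d2 - k * f(x) + k * z(x) ** 2 == pytest.approx(0.0, abs=1e-6)


def _pm_mpmath(k, alpha, g0, g1, x, dps=50):
    """Naive exponential-form evaluation of the closed form at `dps` digits."""
    with mp.workdps(dps):
        s = mp.sqrt(k)
        A = (g1 - g0 * mp.e**-s) / (mp.e**s - mp.e**-s)
        B = (g0 * mp.e**s - g1) / (mp.e**s - mp.e**-s)

        def y0(t):
            return A * mp.e**(s * t) + B * mp.e**(-s * t)

        def yp(t):
            return (
                -(A**2 / 3) * mp.e**(2 * s * t)
                + 2 * A * B
                - (B**2 / 3) * mp.e**(-2 * s * t)
            )

        M = mp.matrix([[1, 1], [mp.e**s, mp.e**-s]])
        C = mp.lu_solve(M, mp.matrix([-yp(0), -yp(1)]))
        y1 = yp(x) + C[0] * mp.e**(s * x) + C[1] * mp.e**(-s * x)
        return y0(x) + alpha * y1


class TestAssembledApproximation:
    def test_alpha_zero_reduces_to_zeroth_order(self):
        p = make_params(3.0, 0.0)
        approx = pm_solution(p)
        xs = np.linspace(0, 1, 17)
        np.testing.assert_array_equal(approx(xs), approx.zeroth(xs))

    def test_small_k_linear_profile(self):
        """k -> 0 with alpha=0 degenerates to the straight line 1-x."""
        p = make_params(1e-8, 0.0, gamma0=1.0, gamma1=0.0)
        xs = np.linspace(0, 1, 101)
        np.testing.assert_allclose(pm_solution(p)(xs), 1.0 - xs, atol=1e-6)

    @pytest.mark.parametrize("k,alpha", CASE_GRID)
    def test_boundary_exactness(self, k, alpha):
        y = pm_solution(make_params(k, alpha))
        assert abs(y(0.0) - 1.0) <= 1e-10
        assert abs(y(1.0) - 1.0) <= 1e-10

    @settings(derandomize=True, max_examples=60)
    @given(
        k=st.floats(0.01, 200.0),
        alpha=st.floats(0.0, 2.0),
        g=st.floats(0.0, 3.0),
        x=st.floats(0.0, 1.0),
    )
    def test_symmetry_for_equal_boundaries(self, k, alpha, g, x):
        """gamma0 = gamma1 implies y(x) = y(1-x)."""
        y = pm_solution(make_params(k, alpha, gamma0=g, gamma1=g))
        assert abs(float(y(x)) - float(y(1.0 - x))) <= 1e-10

    @pytest.mark.parametrize("alpha", [0.1, 1.0, 1.5])
    def test_large_k_matches_high_precision_oracle(self, alpha):
        """Scaled-exponential evaluation agrees with 50-digit arithmetic at k=100."""
        p = make_params(100.0, alpha)
        y = pm_solution(p)
        for x in np.linspace(0.0, 1.0, 11):
            hp = float(_pm_mpmath(mp.mpf(100), mp.mpf(alpha), 1, 1, mp.mpf(float(x))))
            assert float(y(float(x))) == pytest.approx(hp, rel=1e-9, abs=1e-300)

    def test_midpoint_against_nonlinear_reference(self):
        """k=1, alpha=0.1: closed form within 5e-3 of the nonlinear solve."""
        from mmrd.numeric import SolverConfig, solve_bvp_fd

        p = make_params(1.0, 0.1)
        fd = solve_bvp_fd(p, SolverConfig(n=4001))
        mid = fd.values[2000]
        assert float(pm_solution(p)(0.5)) == pytest.approx(mid, abs=5e-3)
        # frozen regression value (first computed against the FD oracle)
        assert float(pm_solution(p)(0.5)) == pytest.approx(0.896098657811298, abs=1e-12)


class TestResidualAndFlux:
    def test_alpha_zero_residual_vanishes(self):
        p = make_params(2.0, 0.0)
        xs = np.linspace(0.05, 0.95, 19)
        assert np.max(np.abs(pm_residual(p, xs))) <= 1e-10

    def test_truncation_order_scaling(self):
        """Max defect scales as alpha^2: halving alpha quarters it."""
        xs = np.linspace(0.1, 0.9, 81)
        r_01 = np.max(np.abs(pm_residual(make_params(1.0, 0.1), xs)))
        r_02 = np.max(np.abs(pm_residual(make_params(1.0, 0.2), xs)))
        assert 3.0 <= r_02 / r_01 <= 5.0

    def test_residual_is_finite_everywhere(self):
        xs = np.linspace(0.01, 0.99, 99)
        for k, alpha in [(1.0, 0.1), (100.0, 1.5)]:
            assert np.all(np.isfinite(pm_residual(make_params(k, alpha), xs)))

    def test_flux_vanishes_at_midpoint_for_symmetric_data(self):
        for k, alpha in [(1.0, 0.1), (20.0, 1.5)]:
            assert abs(pm_flux(make_params(k, alpha), 0.5)) <= 1e-10

    def test_linear_flux_value(self):
        """alpha=0, k=1, symmetric data: y'(0) = A - B = tanh(-1/2)."""
        p = make_params(1.0, 0.0)
        assert pm_flux(p, 0.0) == pytest.approx(math.tanh(-0.5), rel=1e-12)
        assert pm_flux(p, 0.0) == pytest.approx(-0.4621172, abs=5e-8)

    def test_flux_matches_central_difference(self):
        p = make_params(5.0, 1.0)
        y = pm_solution(p)
        h = 1e-6
        for x in (0.1, 0.5, 0.9):
            cd = float(y(x + h) - y(x - h)) / (2 * h)
            assert pm_flux(p, x) == pytest.approx(cd, abs=1e-6)


def test_cascade_algebra_symbolically():
    """Collecting powers of alpha in k*y*(1-alpha*y) reproduces the cascade.

    With y = y0 + alpha*y1, the order-1 term of the linearized reaction is
    k*y0 and the order-alpha term is k*y1 - k*y0**2, so the correction
    equation is y1'' - k*y1 = -k*y0**2.  Also verifies the collapsed
    particular solution against the correction ODE symbolically.
    """
    sympy = pytest.importorskip("sympy")
    a, k, y0, y1, x, A, B = sympy.symbols("a k y0 y1 x A B", positive=True)
    rhs = sympy.expand(k * (y0 + a * y1) * (1 - a * (y0 + a * y1)))
    poly = sympy.Poly(rhs, a)
    assert poly.coeff_monomial(1) == k * y0
    assert sympy.simplify(poly.coeff_monomial(a) - (k * y1 - k * y0**2)) == 0

    s = sympy.sqrt(k)
    y0x = A * sympy.exp(s * x) + B * sympy.exp(-s * x)
    yp = (
        -(A**2 / 3) * sympy.exp(2 * s * x)
        + 2 * A * B
        - (B**2 / 3) * sympy.exp(-2 * s * x)
    )
    assert sympy.simplify(sympy.diff(yp, x, 2) - k * yp + k * y0x**2) == 0
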