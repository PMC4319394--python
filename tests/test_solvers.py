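"""Numerical solvers: hand-checked steps, convergence orders, registry."""

import math

import numpy as np
import pytest

from cellsim.errors import (IntegrationError, NonConvergenceError,
                            NumericError, SingularJacobianError,
                            SolverPropertyError, UnknownSolverError)
from cellsim.solvers import (SolverRegistry, adaptive_integrate,
                             default_registry, fixed_step, implicit_step,
                             list_solvers, newton_solve)


def f_decay(t, y):
    return -y


class TestFixedStepHandValues:
    """One step of y' = -y from y=1 with h=0.1, against hand computation."""

    def test_euler(self):
        assert fixed_step("euler", f_decay, 0.0, [1.0], 0.1) \
            == pytest.approx([0.9], abs=1e-15)

    def test_heun(self):
        assert fixed_step("heun", f_decay, 0.0, [1.0], 0.1) \
            == pytest.approx([0.905], abs=1e-15)

    def test_rk2_midpoint(self):
        assert fixed_step("rk2", f_decay, 0.0, [1.0], 0.1) \
            == pytest.approx([0.905], abs=1e-15)

    def test_rk4(self):
        # k1..k4 = -1, -0.95, -0.9525, -0.90475
        assert fixed_step("rk4", f_decay, 0.0, [1.0], 0.1) \
            == pytest.approx([0.9048375], abs=1e-15)

    def test_unknown_method(self):
        with pytest.raises(UnknownSolverError):
            fixed_step("rk5", f_decay, 0.0, [1.0], 0.1)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            fixed_step("euler", f_decay, 0.0, [1.0], 0.0)

    def test_does_not_mutate_input(self):
        y = np.array([1.0])
        fixed_step("rk4", f_decay, 0.0, y, 0.1)
        assert y[0] == 1.0

    def test_nonfinite_rate_raises_numeric_error(self):
        with pytest.raises(NumericError) as exc:
            fixed_step("euler", lambda t, y: [float("inf")], 2.5, [1.0], 0.1)
        assert exc.value.t == 2.5


def test_heun_equals_rk2_for_linear_rhs():
    """Both second-order methods coincide exactly on linear systems."""
    rng = np.random.default_rng(7)
    A = rng.normal(size=(3, 3))

    def f(t, y):
        return A @ y

    y = rng.normal(size=3)
    a = fixed_step("heun", f, 0.0, y, 0.05)
    b = fixed_step("rk2", f, 0.0, y, 0.05)
    assert np.max(np.abs(a - b)) < 1e-15


def _integrate_fixed(method, h, t_end=1.0):
    y = np.array([1.0])
    n = round(t_end / h)
    for i in range(n):
        y = fixed_step(method, f_decay, i * h, y, h)
    return float(y[0])


def _integrate_backward_euler(h, t_end=1.0):
    y = np.array([1.0])

    def F(t, y_, yp):
        return yp + y_

    n = round(t_end / h)
    for i in range(n):
        y = np.atleast_1d(implicit_step(F, i * h, y, h))
    return float(y[0])


@pytest.mark.parametrize("method,lo,hi", [
    ("euler", 0.8, 1.2),
    ("heun", 1.8, 2.2),
    ("rk2", 1.8, 2.2),
    ("rk4", 3.7, 4.3),
])
def test_observed_convergence_order(method, lo, hi):
    exact = math.exp(-1.0)
    e1 = abs(_integrate_fixed(method, 0.01) - exact)
    e2 = abs(_integrate_fixed(method, 0.005) - exact)
    p = math.log2(e1 / e2)
    assert lo <= p <= hi


def test_backward_euler_first_order():
    exact = math.exp(-1.0)
    e1 = abs(_integrate_backward_euler(0.01) - exact)
    e2 = abs(_integrate_backward_euler(0.005) - exact)
    assert 0.8 <= math.log2(e1 / e2) <= 1.2


def test_backward_euler_closed_form_step():
    # y' = -y: backward Euler gives y/(1 + h)
    y = implicit_step(lambda t, y_, yp: yp + y_, 0.0, [1.0], 0.1)
    assert float(np.atleast_1d(y)[0]) == pytest.approx(1.0 / 1.1, abs=1e-12)


def test_fixed_step_bitwise_deterministic():
    a = fixed_step("rk4", f_decay, 0.3, [2.0], 0.07)
    b = fixed_step("rk4", f_decay, 0.3, [2.0], 0.07)
    assert np.array_equal(a, b)


class TestAdaptive:
    def test_decay_closed_form(self):
        traj = adaptive_integrate(f_decay, 0.0, [10.0], 1.0, reltol=1e-8,
                                  abstol=1e-12)
        assert abs(traj(1.0)[0] - 10.0 * math.exp(-1.0)) < 1e-6

    def test_zero_length_interval(self):
        traj = adaptive_integrate(f_decay, 0.0, [10.0], 0.0)
        assert traj(0.0) == pytest.approx([10.0])

    def test_blow_up_is_an_error_not_inf(self):
        with pytest.raises(IntegrationError) as exc:
            adaptive_integrate(lambda t, y: y ** 2, 0.0, [1.0], 2.0)
        assert exc.value.t is not None

    def test_bad_tolerances_rejected(self):
        with pytest.raises(ValueError):
            adaptive_integrate(f_decay, 0.0, [1.0], 1.0, reltol=0.0)


class TestNewton:
    def test_sqrt_of_four(self):
        calls = []

        def residual(x):
            calls.append(1)
            return x * x - 4.0

        x = newton_solve(residual, np.array([3.0]), tol=1e-10)
        assert abs(x[0] - 2.0) < 1e-10
        # quadratic convergence: well under 8 Newton iterations
        # (each iteration costs 1 Jacobian + <= a few line-search calls)
        assert len(calls) < 8 * 4

    def test_linear_single_iteration(self):
        iters = []

        def residual(x):
            return x - 5.0

        x = newton_solve(residual, np.array([0.0]), tol=1e-12)
        assert abs(x[0] - 5.0) < 1e-12

    def test_linear_2x2_system(self):
        def residual(u):
            return np.array([u[0] + u[1] - 3.0, u[0] - u[1] - 1.0])

        x = newton_solve(residual, np.zeros(2), tol=1e-12)
        assert np.allclose(x, [2.0, 1.0], atol=1e-12)

    def test_singular_jacobian(self):
        with pytest.raises(SingularJacobianError):
            newton_solve(lambda x: np.array([x[0] - 1.0, x[0] - 2.0]) * 0.0
                         + np.array([1.0, 1.0]), np.zeros(2))

    def test_nonconvergence_reports_residual(self):
        with pytest.raises(NonConvergenceError) as exc:
            newton_solve(lambda x: np.array([math.sin(x[0]) + 2.0]),
                         np.array([0.0]), tol=1e-12, max_iterations=5)
        assert exc.value.residual_norm is not None

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            newton_solve(lambda x: np.array([1.0, 2.0]), np.zeros(1))


class TestRegistry:
    def test_default_ode_solvers(self):
        descriptors = list_solvers(default_registry(), "ODE")
        assert [d.name for d in descriptors] \
            == ["adaptive", "euler", "heun", "rk2", "rk4"]

    def test_default_nla_solver(self):
        (d,) = list_solvers(default_registry(), "NLA")
        assert d.name == "newton"

    def test_default_dae_solver(self):
        (d,) = list_solvers(default_registry(), "DAE")
        assert d.name == "backward_euler"

    def test_empty_registry(self):
        assert list_solvers(SolverRegistry()) == []

    def test_unknown_property_lists_valid_keys(self):
        d = default_registry().get("rk4")
        with pytest.raises(SolverPropertyError, match="step"):
            d.resolve_properties({"banana": 1})

    def test_property_range_enforced(self):
        d = default_registry().get("adaptive")
        with pytest.raises(SolverPropertyError):
            d.resolve_properties({"reltol": -1.0})

    def test_every_property_has_default(self):
        for d in default_registry().list():
            assert d.resolve_properties() == d.defaults()
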