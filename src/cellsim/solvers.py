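"""Pluggable numerical solvers.

Three solver types are supported, mirroring the classic split in cell-model
simulators: ODE steppers (four fixed-step methods plus an adaptive
stiff-capable integrator), a backward-Euler implicit step for semi-explicit
DAE handling, and a damped Newton solver for non-linear algebraic (NLA)
systems.  Solvers are looked up by name in a registry and customised through
typed properties with defaults and valid ranges.

Note that "rk2" is the midpoint method, distinct from Heun's method (both
are second order; they coincide on linear right-hand sides).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (IntegrationError, NonConvergenceError, NumericError,
                     SingularJacobianError, SolverPropertyError,
                     UnknownSolverError)


@dataclass(frozen=True)
class SolverProperty:
    key: str
    value_type: type
    default: object
    valid_range: Tuple[Optional[float], Optional[float]] = (None, None)

    def coerce(self, raw):
        try:
            value = self.value_type(raw)
        except (TypeError, ValueError):
            raise SolverPropertyError(
                f"property {self.key!r} expects {self.value_type.__name__}, "
                f"got {raw!r}") from None
        lo, hi = self.valid_range
        if lo is not None and value < lo:
            raise SolverPropertyError(
                f"property {self.key!r} must be >= {lo}, got {value}")
        if hi is not None and value > hi:
            raise SolverPropertyError(
                f"property {self.key!r} must be <= {hi}, got {value}")
        return value


@dataclass(frozen=True)
class SolverDescriptor:
    name: str
    solver_type: str                      # "ODE" | "DAE" | "NLA"
    properties: Tuple[SolverProperty, ...] = ()

    def defaults(self) -> dict:
        return {p.key: p.default for p in self.properties}

    def resolve_properties(self, overrides: dict = None) -> dict:
        props = self.defaults()
        for key, raw in (overrides or {}).items():
            match = next((p for p in self.properties if p.key == key), None)
            if match is None:
                raise SolverPropertyError(
                    f"unknown property {key!r} for solver {self.name!r}; "
                    f"valid keys: {sorted(props)}")
            props[key] = match.coerce(raw)
        return props


# ---------------------------------------------------------------------------
# fixed-step ODE methods

def _check_finite(k, t):
    if not np.all(np.isfinite(k)):
        raise NumericError(f"non-finite rate evaluation at t={t!r}", t=t)
    return k


def euler_step(f, t, y, h):
    """Forward Euler: y + h*f(t, y)."""
    y = np.asarray(y, dtype=float)
    return y + h * _check_finite(np.asarray(f(t, y), dtype=float), t)


def heun_step(f, t, y, h):
    """Heun: trapezoidal average of the slopes at both interval ends."""
    y = np.asarray(y, dtype=float)
    k1 = _check_finite(np.asarray(f(t, y), dtype=float), t)
    k2 = _check_finite(np.asarray(f(t + h, y + h * k1), dtype=float), t + h)
    return y + (h / 2.0) * (k1 + k2)

def rk2_step(f, t, y, h):
    """Second-order Runge-Kutta (midpoint rule)."""
    y = np.asarray(y, dtype=float)
    k1 = _check_finite(np.asarray(f(t, y), dtype=float), t)
    k2 = _check_finite(
        np.asarray(f(t + h / 2.0, y + (h / 2.0) * k1), dtype=float),
        t + h / 2.0)
    return y + h * k2


def rk4_step(f, t, y, h):
    """Classic fourth-order Runge-Kutta."""
    y = np.asarray(y, dtype=float)
    k1 = _check_finite(np.asarray(f(t, y), dtype=float), t)
    k2 = _check_finite(
        np.asarray(f(t + h / 2.0, y + h * k1 / 2.0), dtype=float), t)
    k3 = _check_finite(
        np.asarray(f(t + h / 2.0, y + h * k2 / 2.0), dtype=float), t)
    k4 = _check_finite(np.asarray(f(t + h, y + h * k3), dtype=float), t)
    return y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


FIXED_STEP_METHODS = {
    "euler": euler_step,
    "heun": heun_step,
    "rk2": rk2_step,
    "rk4": rk4_step,
}


def fixed_step(method: str, f, t, y, h):
    """One explicit step of the named method; ``h`` must be positive."""
    if h <= 0:
        raise ValueError("step size must be positive")
    try:
        stepper = FIXED_STEP_METHODS[method]
    except KeyError:
        raise UnknownSolverError(
            f"unknown fixed-step method {method!r}; valid: "
            f"{sorted(FIXED_STEP_METHODS)}") from None
    return stepper(f, t, y, h)


# ---------------------------------------------------------------------------
# adaptive stiff-capable integration

class Trajectory:
    """Dense solution over [t0, t_end], evaluable at arbitrary times."""

    def __init__(self, t0, t_end, y0, sol=None):
        self.t0 = float(t0)
        self.t_end = float(t_end)
        self._y0 = np.asarray(y0, dtype=float)
        self._sol = sol

    def __call__(self, t):
        if self._sol is None:      # degenerate zero-length interval
            return self._y0.copy()
        return np.asarray(self._sol(t), dtype=float)


def adaptive_integrate(f, t0, y0, t_end, reltol=1e-7, abstol=1e-12,
                       max_step=math.inf, max_steps=500000) -> Trajectory:
    """Variable-step stiff-capable integration with dense output.

    Delegates to LSODA (automatic stiff/non-stiff switching); the returned
    trajectory is interpolated at whatever grid the caller queries, rather
    than forcing integrator steps onto the grid.
    """
    if reltol <= 0 or abstol <= 0:
        raise ValueError("tolerances must be positive")
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    if t_end == t0:
        return Trajectory(t0, t_end, y0)

    class _Diverged(Exception):
        pass

    def guarded(t, y):
        # a finite-time blow-up must become an error, not an endless grind
        # of ever-smaller steps or a silent non-finite trajectory
        if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > 1e150:
            exc = _Diverged()
            exc.t = float(t)
            raise exc
        dy = np.asarray(f(t, y), dtype=float)
        if not np.all(np.isfinite(dy)):
            exc = _Diverged()
            exc.t = float(t)
            raise exc
        return dy

    try:
        with np.errstate(over="ignore", invalid="ignore"):
            sol = solve_ivp(guarded, (t0, t_end), y0, method="LSODA",
                            dense_output=True, rtol=reltol, atol=abstol,
                            max_step=max_step)
    except _Diverged as exc:
        raise IntegrationError(
            f"solution diverged (non-finite values) at t={exc.t!r}",
            t=exc.t) from None
    if not sol.success:
        t_fail = float(sol.t[-1]) if len(sol.t) else t0
        raise IntegrationError(
            f"integration failed at t={t_fail!r}: {sol.message}", t=t_fail)
    if not np.all(np.isfinite(sol.y)):
        t_fail = float(sol.t[-1])
        raise IntegrationError(
            f"non-finite solution values near t={t_fail!r}", t=t_fail)
    return Trajectory(t0, t_end, y0, sol.sol)


# ---------------------------------------------------------------------------
# Newton NLA solver

_SQRT_EPS = math.sqrt(np.finfo(float).eps)


def newton_solve(residual: Callable, guess, tol: float = 1e-12,
                 max_iterations: int = 100):
    """Damped Newton with a forward-difference Jacobian.

    The Jacobian column i uses perturbation sqrt(eps)*max(|x_i|, 1); the
    line search halves the step at most 10 times.  Convergence is declared
    when the residual's infinity norm drops below ``tol``.
    """
    x = np.atleast_1d(np.asarray(guess, dtype=float)).copy()
    n = x.size
    r = np.atleast_1d(np.asarray(residual(x), dtype=float))
    if r.size != n:
        raise ValueError("residual dimension must equal guess dimension")
    if not np.all(np.isfinite(r)):
        raise NumericError("non-finite residual at the initial guess")
    rnorm = np.max(np.abs(r))
    for _ in range(max_iterations):
        if rnorm < tol:
            return x if np.ndim(guess) else float(x[0])
        jac = np.empty((n, n))
        for i in range(n):
            dx = _SQRT_EPS * max(abs(x[i]), 1.0)
            xp = x.copy()
            xp[i] += dx
            jac[:, i] = (np.atleast_1d(residual(xp)) - r) / dx
        try:
            step = np.linalg.solve(jac, -r)
        except np.linalg.LinAlgError:
            raise SingularJacobianError(
                "singular Jacobian in Newton iteration") from None
        if not np.all(np.isfinite(step)):
            raise SingularJacobianError(
                "non-finite Newton step (Jacobian numerically singular)")
        lam = 1.0
        for _ in range(10):
            x_new = x + lam * step
            r_new = np.atleast_1d(np.asarray(residual(x_new), dtype=float))
            if np.all(np.isfinite(r_new)) \
                    and np.max(np.abs(r_new)) < rnorm:
                break
            lam *= 0.5
        x, r = x_new, r_new
        rnorm = np.max(np.abs(r)) if np.all(np.isfinite(r)) else math.inf
    if rnorm < tol:
        return x if np.ndim(guess) else float(x[0])
    raise NonConvergenceError(
        f"Newton did not converge in {max_iterations} iterations "
        f"(last |residual|_inf = {rnorm:g})", residual_norm=float(rnorm))


def implicit_step(F, t, y, h, nla=newton_solve, tol=1e-12,
                  max_iterations=100):
    """Backward-Euler step for a residual system F(t, y, y') = 0.

    Solves F(t+h, y_next, (y_next - y)/h) = 0 by Newton, starting from the
    current state.  First-order accurate; suited to semi-explicit index-1
    systems.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))

    def residual(y_next):
        return np.atleast_1d(np.asarray(
            F(t + h, y_next, (y_next - y) / h), dtype=float))

    return nla(residual, y.copy(), tol=tol, max_iterations=max_iterations)


# ---------------------------------------------------------------------------
# registry

class SolverRegistry:
    def __init__(self, descriptors=()):
        self._by_name = {}
        for d in descriptors:
            self.register(d)

    def register(self, descriptor: SolverDescriptor):
        if descriptor.name in self._by_name:
            raise SolverPropertyError(
                f"solver {descriptor.name!r} already registered")
        self._by_name[descriptor.name] = descriptor

    def get(self, name: str) -> SolverDescriptor:
        try:
            return self._by_name[name]
        except KeyError:
            raise UnknownSolverError(
                f"unknown solver {name!r}; registered: "
                f"{sorted(self._by_name)}") from None

    def list(self, solver_type: Optional[str] = None
             ) -> List[SolverDescriptor]:
        out = [d for d in self._by_name.values()
               if solver_type is None or d.solver_type == solver_type]
        return sorted(out, key=lambda d: d.name)


def list_solvers(registry: "SolverRegistry", solver_type=None):
    return registry.list(solver_type)


_STEP_PROP = SolverProperty("step", float, 0.0, (0.0, None))
_TOL_PROPS = (
    SolverProperty("reltol", float, 1e-7, (0.0, None)),
    SolverProperty("abstol", float, 1e-12, (0.0, None)),
    SolverProperty("max_step", float, math.inf, (0.0, None)),
    SolverProperty("max_steps", int, 500000, (1, None)),
)
_NEWTON_PROPS = (
    SolverProperty("tol", float, 1e-12, (0.0, None)),
    SolverProperty("max_iterations", int, 100, (1, None)),
)


def default_registry() -> SolverRegistry:
    """euler/heun/rk2/rk4/adaptive (ODE), backward_euler (DAE), newton (NLA).
    """
    fixed = tuple([_STEP_PROP])
    return SolverRegistry([
        SolverDescriptor("euler", "ODE", fixed),
        SolverDescriptor("heun", "ODE", fixed),
        SolverDescriptor("rk2", "ODE", fixed),
        SolverDescriptor("rk4", "ODE", fixed),
        SolverDescriptor("adaptive", "ODE", _TOL_PROPS),
        SolverDescriptor("backward_euler", "DAE", fixed + _NEWTON_PROPS),
        SolverDescriptor("newton", "NLA", _NEWTON_PROPS),
    ])
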