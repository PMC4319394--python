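"""Simulation orchestration: grids, sessions, data capture, export.

A run is controlled by three values — start, end and point interval — plus a
named ODE/DAE solver and a named NLA solver.  Every model parameter
(constants, computed constants, states, rates, algebraic variables) is
captured at every grid point into a :class:`DataStore`; grid values are
computed as ``start + i*interval`` (index multiplication, never repeated
addition, so the grid cannot drift).

Sessions own all mutable state — state vector, constants, NLA warm-start
cache, store — so several sessions over one runtime can be advanced
interleaved and still produce exactly the results of sequential runs.  A
session can be paused at a grid point, constants and states modified, and
resumed; modifications are applied before that point is recorded, so stored
data are always self-consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import (CapacityError, CategoryError, RegistryError)
from .runtime import RuntimeModel
from .solvers import (FIXED_STEP_METHODS, SolverRegistry, adaptive_integrate,
                      default_registry, implicit_step, newton_solve)

#: column order of the store: category rank, then name
_CATEGORY_ORDER = ("constant", "computed_constant", "state", "rate",
                   "algebraic")


@dataclass
class SimulationSetup:
    start: float
    end: float
    point_interval: float
    ode_solver: str = "rk4"
    ode_properties: Dict[str, object] = field(default_factory=dict)
    nla_solver: str = "newton"
    nla_properties: Dict[str, object] = field(default_factory=dict)
    #: in-memory cap for the captured data (all parameters, all points)
    memory_cap_bytes: int = 1 << 30

    def __post_init__(self):
        if not (self.end > self.start):
            raise ValueError("end must be greater than start")
        if not (self.point_interval > 0):
            raise ValueError("point interval must be positive")
        if self.point_interval > self.end - self.start:
            raise ValueError("point interval must not exceed end - start")

    def grid(self) -> np.ndarray:
        """start + i*interval; the last point is end when (end-start)/interval
        is integral to 1e-9 relative tolerance."""
        ratio = (self.end - self.start) / self.point_interval
        n = int(math.floor(ratio + 1e-9))
        grid = self.start + np.arange(n + 1, dtype=float) \
            * self.point_interval
        if abs(ratio - round(ratio)) <= 1e-9 * max(1.0, abs(ratio)):
            grid[-1] = self.end
        return grid


@dataclass(frozen=True)
class SeriesMeta:
    label: str        # "<component>/<name>"
    units: str
    category: str

    @property
    def column_header(self) -> str:
        return f"{self.label} ({self.units})"


class DataStore:
    """Uniform VOI grid plus one tracked series per model parameter."""

    def __init__(self, voi_meta: SeriesMeta, grid: np.ndarray,
                 metas: List[SeriesMeta]):
        self.voi_meta = voi_meta
        self.voi = np.array(grid, dtype=float)
        order = {c: i for i, c in enumerate(_CATEGORY_ORDER)}
        self.metas = sorted(metas,
                            key=lambda m: (order[m.category], m.label))
        self.data: Dict[str, np.ndarray] = {
            m.label: np.zeros(len(grid)) for m in self.metas}

    @property
    def capacity(self) -> int:
        return len(self.voi)

    def series(self, label: str) -> np.ndarray:
        return self.data[label]

    def column_headers(self) -> List[str]:
        return [self.voi_meta.column_header] \
            + [m.column_header for m in self.metas]

    def columns(self) -> List[np.ndarray]:
        return [self.voi] + [self.data[m.label] for m in self.metas]

    def equal(self, other: "DataStore") -> bool:
        """Bitwise equality of grid and all series."""
        if self.column_headers() != other.column_headers():
            return False
        return all(np.array_equal(a, b) for a, b in
                   zip(self.columns(), other.columns()))


class SimulationSession:
    """One independent run: ready -> running -> (paused ->)* done."""

    def __init__(self, runtime: RuntimeModel, setup: SimulationSetup,
                 registry: Optional[SolverRegistry] = None):
        self.runtime = runtime
        self.setup = setup
        self.registry = registry or default_registry()
        self._ode = self.registry.get(setup.ode_solver)
        if self._ode.solver_type not in ("ODE", "DAE"):
            raise RegistryError(
                f"solver {setup.ode_solver!r} is a {self._ode.solver_type} "
                "solver, not an ODE/DAE solver")
        self._ode_props = self._ode.resolve_properties(setup.ode_properties)
        nla = self.registry.get(setup.nla_solver)
        if nla.solver_type != "NLA":
            raise RegistryError(
                f"solver {setup.nla_solver!r} is not an NLA solver")
        self._nla_props = nla.resolve_properties(setup.nla_properties)

        self.grid = setup.grid()
        a = runtime.analysis
        n_tracked = len(a.all_tracked())
        need = 8 * len(self.grid) * (1 + n_tracked)
        if need > setup.memory_cap_bytes:
            raise CapacityError(
                f"run would capture {need} bytes "
                f"({1 + n_tracked} series x {len(self.grid)} points), "
                f"above the {setup.memory_cap_bytes}-byte cap")

        self.nla_state = runtime.new_nla_state()
        self._solve_nla = lambda residual, guess: np.atleast_1d(
            newton_solve(residual, guess, tol=self._nla_props["tol"],
                         max_iterations=self._nla_props["max_iterations"]))
        runtime.nla_solver = self._solve_nla
        self.constants, self.states = runtime.initialise_constants()
        self.constants = runtime.compute_computed_constants(
            self.constants, self.nla_state)

        voi_meta = SeriesMeta(a.voi.label, a.voi.units,
                              "variable_of_integration")
        metas = []
        self._meta_key: Dict[str, tuple] = {}
        for rv in a.all_tracked():
            if rv.category == "rate":
                meta = SeriesMeta(
                    f"{rv.component}/d({rv.name})/d({a.voi.name})",
                    f"{rv.units}/{a.voi.units}", "rate")
            else:
                meta = SeriesMeta(rv.label, rv.units, rv.category)
            metas.append(meta)
            self._meta_key[meta.label] = (rv.category, rv.index)
        self.store = DataStore(voi_meta, self.grid, metas)
        self.position = 0      # next grid index to record
        self.state = "ready"

    # -- parameter access ---------------------------------------------------
    def _find(self, name: str):
        """Resolve a parameter by store label ("comp/name", including rate
        labels "comp/d(x)/d(t)") or by unambiguous bare name.

        Returns (category, index)."""
        if name in self._meta_key:
            return self._meta_key[name]
        a = self.runtime.analysis
        if "/" in name:
            comp, _, vname = name.partition("/")
            rv = a.lookup(comp, vname)
        else:
            hits = [rv for rv in a.all_tracked() + [a.voi]
                    if rv.name == name and rv.category != "rate"]
            rv = hits[0] if len(hits) == 1 else None
        if rv is None:
            raise KeyError(f"unknown model parameter {name!r}")
        return rv.category, rv.index

    def modify(self, name: str, value: float):
        """Change a constant or a state mid-run (paused or before running).

        Computed constants are refreshed afterwards so dependent quantities
        stay consistent.
        """
        category, index = self._find(name)
        if category == "constant":
            self.constants[index] = float(value)
            self.constants = self.runtime.compute_computed_constants(
                self.constants, self.nla_state)
        elif category == "state":
            self.states[index] = float(value)
        else:
            raise CategoryError(
                f"parameter {name!r} is of category {category!r} and "
                "cannot be modified (only constants and states are "
                "editable)")

    # -- recording ----------------------------------------------------------
    def _record(self, idx: int):
        rt = self.runtime
        t = self.grid[idx]
        rates = rt.compute_rates(t, self.states, self.constants,
                                 self.nla_state)
        algebraic = rt.compute_algebraic(t, self.states, rates,
                                         self.constants, self.nla_state)
        a = rt.analysis
        nc = rt.n_constants
        for meta in self.store.metas:
            cat, i = self._meta_key[meta.label]
            if cat == "constant":
                v = self.constants[i]
            elif cat == "computed_constant":
                v = self.constants[nc + i]
            elif cat == "state":
                v = self.states[i]
            elif cat == "rate":
                v = rates[i]
            else:
                v = algebraic[i]
            self.store.data[meta.label][idx] = v

    # -- integration --------------------------------------------------------
    def _advance(self, target_idx: int):
        """Record points [position, target_idx) and integrate the state to
        grid[target_idx], leaving that point unrecorded (so modifications
        can be applied first)."""
        if target_idx <= self.position:
            return
        name = self.setup.ode_solver
        if name == "adaptive":
            self._advance_adaptive(target_idx)
            return
        if name == "backward_euler":
            stepper = self._backward_euler_interval
        else:
            stepper = self._fixed_interval
        for i in range(self.position, target_idx):
            self._record(i)
            stepper(i)
            self.position = i + 1

    def _substeps(self, interval: float) -> Tuple[int, float]:
        h = float(self._ode_props.get("step") or 0.0)
        if h <= 0 or h >= interval:
            return 1, interval
        n = int(math.ceil(interval / h - 1e-9))
        return n, interval / n

    def _fixed_interval(self, i: int):
        f = self.runtime.rate_function(self.constants, self.nla_state)
        t0, t1 = self.grid[i], self.grid[i + 1]
        n, h = self._substeps(t1 - t0)
        method = FIXED_STEP_METHODS[self.setup.ode_solver]
        y = self.states
        for j in range(n):
            y = method(f, t0 + j * h, y, h)
        self.states = y

    def _backward_euler_interval(self, i: int):
        f = self.runtime.rate_function(self.constants, self.nla_state)
        t0, t1 = self.grid[i], self.grid[i + 1]
        n, h = self._substeps(t1 - t0)

        def residual_form(t, y, yp):
            return yp - f(t, y)

        y = self.states
        for j in range(n):
            y = np.atleast_1d(implicit_step(
                residual_form, t0 + j * h, y, h,
                tol=self._nla_props["tol"],
                max_iterations=self._nla_props["max_iterations"]))
        self.states = y

    def _advance_adaptive(self, target_idx: int):
        f = self.runtime.rate_function(self.constants, self.nla_state)
        p = self._ode_props
        traj = adaptive_integrate(
            f, self.grid[self.position], self.states, self.grid[target_idx],
            reltol=p["reltol"], abstol=p["abstol"], max_step=p["max_step"],
            max_steps=p["max_steps"])
        for i in range(self.position, target_idx):
            self.states = traj(self.grid[i])
            self._record(i)
            self.position = i + 1
        self.states = traj(self.grid[target_idx])

    # -- public driving -----------------------------------------------------
    def run(self) -> DataStore:
        self.state = "running"
        last = len(self.grid) - 1
        self._advance(last)
        self._record(last)
        self.position = last
        self.state = "done"
        return self.store

    def run_to(self, pause_at: float) -> int:
        """Advance to the nearest grid point at or after ``pause_at`` and
        pause there (that point is not yet recorded)."""
        idx = int(np.searchsorted(self.grid, pause_at - 1e-12 *
                                  max(1.0, abs(pause_at)), side="left"))
        idx = min(idx, len(self.grid) - 1)
        self.state = "running"
        self._advance(idx)
        self.state = "paused"
        return idx


def run_simulation(runtime: RuntimeModel, setup: SimulationSetup,
                   registry: Optional[SolverRegistry] = None) -> DataStore:
    """Initialise, integrate over the whole grid, capture every parameter."""
    return SimulationSession(runtime, setup, registry).run()


def run_segments(runtime_or_session, segments,
                 setup: Optional[SimulationSetup] = None,
                 registry: Optional[SolverRegistry] = None) -> DataStore:
    """Run with pause points: ``segments`` is a list of
    ``(pause_at, {parameter: value})``; pause points must be strictly
    increasing and inside (start, end).  Each pause snaps to the nearest
    grid point at or after the requested value; modifications are applied
    there, before that point is recorded."""
    if isinstance(runtime_or_session, SimulationSession):
        session = runtime_or_session
    else:
        session = SimulationSession(runtime_or_session, setup, registry)
    last_t = -math.inf
    for pause_at, mods in segments:
        if not (session.setup.start < pause_at < session.setup.end):
            raise ValueError(
                f"pause point {pause_at!r} outside (start, end)")
        if pause_at <= last_t:
            raise ValueError("pause points must be strictly increasing")
        last_t = pause_at
        session.run_to(pause_at)
        for name, value in mods.items():
            session.modify(name, value)
    return session.run()


# ---------------------------------------------------------------------------
# data export

class ExporterRegistry:
    """Named data-store writers; "csv" is shipped."""

    def __init__(self):
        self._writers: Dict[str, object] = {}

    def register(self, name: str, writer):
        if name in self._writers:
            raise RegistryError(f"exporter {name!r} already registered")
        self._writers[name] = writer

    def names(self) -> List[str]:
        return sorted(self._writers)

    def get(self, name: str):
        try:
            return self._writers[name]
        except KeyError:
            raise RegistryError(
                f"unknown exporter {name!r}; registered: "
                f"{self.names()}") from None


def write_csv(store: DataStore, fh):
    """Comma-separated, header then one row per grid point, 17-significant-
    digit scientific notation (full round-trip precision), LF endings."""
    fh.write(",".join(store.column_headers()) + "\n")
    cols = store.columns()
    for i in range(store.capacity):
        fh.write(",".join(f"{col[i]:.17e}" for col in cols) + "\n")


def default_exporter_registry() -> ExporterRegistry:
    reg = ExporterRegistry()
    reg.register("csv", write_csv)
    return reg


def register_exporter(registry: ExporterRegistry, name: str, writer
                      ) -> ExporterRegistry:
    registry.register(name, writer)
    return registry


def export_datastore(store: DataStore, exporter: str, destination,
                     registry: Optional[ExporterRegistry] = None):
    """Write the store with the named exporter to a path or file object."""
    registry = registry or default_exporter_registry()
    writer = registry.get(exporter)
    if hasattr(destination, "write"):
        writer(store, destination)
    else:
        with open(destination, "w", encoding="utf-8", newline="") as fh:
            writer(store, fh)
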