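"""Grid construction, sessions, pause/modify/resume, data export."""

import io
import math

import numpy as np
import pytest

from cellsim.errors import CapacityError, CategoryError, RegistryError
from cellsim.simulation import (DataStore, ExporterRegistry,
                                SimulationSession, SimulationSetup,
                                default_exporter_registry, export_datastore,
                                register_exporter, run_segments,
                                run_simulation, write_csv)


def test_grid_contract():
    setup = SimulationSetup(0.0, 10.0, 0.1)
    grid = setup.grid()
    assert len(grid) == 101
    # index multiplication: no accumulation drift
    assert abs(grid[-1] - 10.0) <= 4 * np.finfo(float).eps * 10.0
    assert np.array_equal(grid, 0.0 + np.arange(101) * 0.1)


def test_minimal_grid_two_points():
    setup = SimulationSetup(0.0, 0.5, 0.5)
    assert len(setup.grid()) == 2


def test_non_integral_span_last_point_below_end():
    grid = SimulationSetup(0.0, 1.0, 0.3).grid()
    assert len(grid) == 4 and grid[-1] == pytest.approx(0.9)


def test_setup_invariants_enforced():
    with pytest.raises(ValueError):
        SimulationSetup(1.0, 1.0, 0.1)
    with pytest.raises(ValueError):
        SimulationSetup(0.0, 1.0, 0.0)
    with pytest.raises(ValueError):
        SimulationSetup(0.0, 1.0, 2.0)


def test_decay_closed_form_rk4(decay_runtime):
    setup = SimulationSetup(0.0, 10.0, 0.1, ode_solver="rk4",
                            ode_properties={"step": 0.01})
    store = run_simulation(decay_runtime, setup)
    assert store.capacity == 101
    assert abs(store.series("main/y")[-1] - 10.0 * math.exp(-10.0)) < 1e-6


def test_constants_tracked_constant(decay_runtime):
    store = run_simulation(decay_runtime, SimulationSetup(0.0, 1.0, 0.1))
    a = store.series("main/a")
    assert np.all(a == a[0])


def test_rates_series_matches_state_series(decay_runtime):
    """dy/dt = -a*y must hold at every recorded point."""
    store = run_simulation(decay_runtime, SimulationSetup(0.0, 1.0, 0.1))
    y = store.series("main/y")
    dy = store.series("main/d(y)/d(time)")
    assert np.max(np.abs(dy + y)) < 1e-12


def test_pause_modify_resume_zeroes_decay(decay_runtime):
    store = run_segments(decay_runtime, [(5.0, {"main/a": 0.0})],
                         setup=SimulationSetup(0.0, 10.0, 0.1))
    t = store.voi
    y = store.series("main/y")
    frozen = y[t >= 5.0]
    assert np.max(np.abs(frozen - frozen[0])) < 1e-12
    assert np.all(store.series("main/a")[t >= 5.0] == 0.0)
    assert np.all(store.series("main/a")[t < 5.0] == 1.0)


def test_empty_segments_equals_plain_run(decay_runtime):
    setup = SimulationSetup(0.0, 10.0, 0.1)
    assert run_segments(decay_runtime, [], setup=setup).equal(
        run_simulation(decay_runtime, setup))


def test_modifying_computed_parameter_is_category_error(fhn_runtime):
    session = SimulationSession(fhn_runtime, SimulationSetup(0.0, 1.0, 0.1))
    with pytest.raises(CategoryError, match="computed_constant"):
        session.modify("membrane/eb", 1.0)
    with pytest.raises(CategoryError, match="algebraic"):
        session.modify("membrane/u", 1.0)
    with pytest.raises(CategoryError, match="rate"):
        session.modify("membrane/d(v)/d(time)", 1.0)


def test_modifying_unknown_parameter(decay_runtime):
    session = SimulationSession(decay_runtime,
                                SimulationSetup(0.0, 1.0, 0.1))
    with pytest.raises(KeyError):
        session.modify("main/nope", 1.0)


def test_interleaved_sessions_match_sequential(decay_runtime):
    """Two sessions over one runtime, advanced alternately, must equal their
    own one-shot runs bitwise: sessions share nothing mutable."""
    setup_a = SimulationSetup(0.0, 10.0, 0.1, ode_solver="rk4")
    setup_b = SimulationSetup(0.0, 10.0, 0.1, ode_solver="euler",
                              ode_properties={"step": 0.01})
    sa = SimulationSession(decay_runtime, setup_a)
    sb = SimulationSession(decay_runtime, setup_b)
    for pause in (2.0, 4.0, 6.0, 8.0):
        sa.run_to(pause)
        sb.run_to(pause)
    store_a, store_b = sa.run(), sb.run()
    assert store_a.equal(run_simulation(decay_runtime, setup_a))
    assert store_b.equal(run_simulation(decay_runtime, setup_b))


def test_fhn_adaptive_agrees_with_rk4(fhn_runtime):
    """Two very different integrators must land on the same trajectory."""
    grid = dict(start=0.0, end=10.0, point_interval=0.1)
    adaptive = run_simulation(fhn_runtime, SimulationSetup(
        ode_solver="adaptive",
        ode_properties={"reltol": 1e-8, "abstol": 1e-10}, **grid))
    rk4 = run_simulation(fhn_runtime, SimulationSetup(
        ode_solver="rk4", ode_properties={"step": 1e-3}, **grid))
    dv = np.max(np.abs(adaptive.series("membrane/v")
                       - rk4.series("membrane/v")))
    assert dv < 1e-4


def test_conservation_probe(rng):
    """y1' = -k y1, y2' = +k y1: the total stays put to solver accuracy."""
    from cellsim.document import parse_cellml
    from cellsim.fixtures import make_conservation
    from cellsim.runtime import build_runtime
    runtime = build_runtime(parse_cellml(make_conservation()))
    store = run_simulation(runtime, SimulationSetup(
        0.0, 10.0, 0.1, ode_solver="rk4", ode_properties={"step": 0.01}))
    total = store.series("pool/y1") + store.series("pool/y2")
    assert np.max(np.abs(total - total[0])) < 1e-10


def test_capacity_error_up_front(decay_runtime):
    setup = SimulationSetup(0.0, 10.0, 0.1, memory_cap_bytes=100)
    with pytest.raises(CapacityError):
        SimulationSession(decay_runtime, setup)


def test_nla_series_constant_on_grid(nla_runtime):
    store = run_simulation(nla_runtime, SimulationSetup(0.0, 2.0, 0.1))
    assert np.max(np.abs(store.series("loop/x") - 2.0)) < 1e-10
    assert np.max(np.abs(store.series("loop/y") - 1.0)) < 1e-10
    z = store.series("loop/z")
    assert np.max(np.abs(z - 2.0 * store.voi)) < 1e-8


class TestCsvExport:
    def test_shape_and_labels(self, decay_runtime):
        store = run_simulation(decay_runtime, SimulationSetup(0.0, 10.0, 0.1))
        buf = io.StringIO()
        export_datastore(store, "csv", buf)
        lines = buf.getvalue().split("\n")
        assert lines[-1] == ""           # trailing LF
        assert len(lines) == 103         # header + 101 rows + empty tail
        header = lines[0].split(",")
        # 1 VOI + 1 constant + 1 state + 1 rate
        assert len(header) == 4
        assert header[0] == "main/time (second)"

    def test_round_trip_exact(self, fhn_runtime):
        store = run_simulation(fhn_runtime, SimulationSetup(0.0, 5.0, 0.1))
        buf = io.StringIO()
        export_datastore(store, "csv", buf)
        arr = np.loadtxt(io.StringIO(buf.getvalue()), delimiter=",",
                         skiprows=1)
        for i, col in enumerate(store.columns()):
            assert np.array_equal(arr[:, i], col)

    def test_unknown_exporter_lists_registered(self, decay_runtime):
        store = run_simulation(decay_runtime, SimulationSetup(0.0, 1.0, 0.5))
        with pytest.raises(RegistryError, match="csv"):
            export_datastore(store, "bogus", io.StringIO())


class TestExporterRegistry:
    def test_shipped_contains_exactly_csv(self):
        assert default_exporter_registry().names() == ["csv"]

    def test_register_new_exporter(self):
        reg = default_exporter_registry()
        register_exporter(reg, "tsv", lambda store, fh: None)
        assert reg.names() == ["csv", "tsv"]

    def test_duplicate_name_rejected(self):
        reg = default_exporter_registry()
        with pytest.raises(RegistryError):
            reg.register("csv", write_csv)
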