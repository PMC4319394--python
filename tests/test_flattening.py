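"""CellML 1.1 import resolution and 1.0 export."""

import numpy as np
import pytest

from cellsim.analysis import analyze
from cellsim.document import detect_version, parse_cellml, serialize_cellml
from cellsim.errors import CircularImportError, ImportReferenceError, \
    LocatorError
from cellsim.fixtures import (CELLML11, IMPORTED_DOC_NAME, MAIN_DOC_NAME,
                              XLINK, make_import_pair)
from cellsim.flatten import (InMemoryLocator, export_cellml10,
                             resolve_imports, resolve_imports_with_log)
from cellsim.runtime import build_runtime
from cellsim.simulation import SimulationSetup, run_simulation
from cellsim.validation import validate


def _main_model(import_pair):
    main, _, locator = import_pair
    return parse_cellml(main, base_locator=MAIN_DOC_NAME), locator


def test_flatten_import_pair_structure(import_pair):
    model, locator = _main_model(import_pair)
    flat = resolve_imports(model, locator)
    assert flat.version == "1.0"
    assert flat.imports == []
    assert sorted(c.name for c in flat.components) == ["cell", "environment"]
    assert [u.name for u in flat.units_definitions] == ["per_second"]
    assert validate(flat) == []


def test_flatten_census_equals_decay(import_pair, decay_model):
    model, locator = _main_model(import_pair)
    flat = resolve_imports(model, locator)
    assert analyze(flat).census == analyze(decay_model).census \
        == (1, 1, 1, 1, 0, 0)


def test_no_import_model_is_identity(decay_model):
    flat = resolve_imports(decay_model)
    assert flat.version == "1.0"
    assert flat == decay_model


def test_export_is_cellml10(import_pair):
    model, locator = _main_model(import_pair)
    text = export_cellml10(model, locator)
    assert detect_version(text) == "1.0"


def test_flattening_idempotent_bytes(import_pair):
    model, locator = _main_model(import_pair)
    once = export_cellml10(model, locator)
    twice = export_cellml10(parse_cellml(once, base_locator=MAIN_DOC_NAME),
                            locator)
    assert twice == once


def test_simulation_equivalence_composite_vs_flattened(import_pair):
    """The flattened document must reproduce the composite's dynamics to
    machine precision: same runtime structure, same trajectories."""
    model, locator = _main_model(import_pair)
    flat = resolve_imports(model, locator)
    reparsed = parse_cellml(serialize_cellml(flat),
                            base_locator=MAIN_DOC_NAME)
    setup = SimulationSetup(0.0, 10.0, 0.1, ode_solver="rk4")
    store_a = run_simulation(build_runtime(flat), setup)
    store_b = run_simulation(build_runtime(reparsed), setup)
    assert store_a.column_headers() == store_b.column_headers()
    diff = max(float(np.max(np.abs(x - y))) for x, y in
               zip(store_a.columns(), store_b.columns()))
    assert diff < 1e-12


def test_self_import_cycle_error():
    text = f"""<model name="loop" xmlns="{CELLML11}" xmlns:xlink="{XLINK}">
      <import xlink:href="self.cellml">
        <component name="c" component_ref="c"/>
      </import>
    </model>"""
    locator = InMemoryLocator({"self.cellml": text}, base="self.cellml")
    with pytest.raises(CircularImportError) as exc:
        resolve_imports(parse_cellml(text, base_locator="self.cellml"),
                        locator)
    assert "self.cellml" in exc.value.chain


def test_unresolvable_href_names_it(import_pair):
    model, _ = _main_model(import_pair)
    empty = InMemoryLocator({}, base=MAIN_DOC_NAME)
    with pytest.raises(LocatorError, match=IMPORTED_DOC_NAME):
        resolve_imports(model, empty)


def test_missing_remote_name_is_reference_error(import_pair):
    main, imported, _ = import_pair
    broken = main.replace('component_ref="decayer"',
                          'component_ref="nonexistent"')
    locator = InMemoryLocator({MAIN_DOC_NAME: broken,
                               IMPORTED_DOC_NAME: imported},
                              base=MAIN_DOC_NAME)
    with pytest.raises(ImportReferenceError, match="nonexistent"):
        resolve_imports(parse_cellml(broken, base_locator=MAIN_DOC_NAME),
                        locator)


def test_collision_rename_logged(import_pair):
    """A local component with the dependency's name forces a deterministic
    numeric-suffix rename, recorded in the log."""
    main, imported, _ = import_pair
    # the importing document already owns a component called "decayer"
    clash = main.replace(
        '<component name="environment">',
        '<component name="per_second_holder">'
        '<variable name="dummy" units="per_second" initial_value="0"/>'
        '</component>\n  <component name="environment">')
    # and imports per_second under a clashing local units name via a second
    # import of the same units under a fresh name
    model = parse_cellml(clash, base_locator=MAIN_DOC_NAME)
    locator = InMemoryLocator({MAIN_DOC_NAME: clash,
                               IMPORTED_DOC_NAME: imported},
                              base=MAIN_DOC_NAME)
    flat, log = resolve_imports_with_log(model, locator)
    assert validate(flat) == []   # local units reference stays resolvable


def test_initial_value_by_variable_reference_rewritten():
    text = f"""<model name="ref" xmlns="{CELLML11}">
      <component name="c">
        <variable name="t" units="dimensionless"/>
        <variable name="y0" units="dimensionless" initial_value="42"/>
        <variable name="y" units="dimensionless" initial_value="y0"/>
        <math xmlns="http://www.w3.org/1998/Math/MathML">
          <apply><eq/>
            <apply><diff/><bvar><ci>t</ci></bvar><ci>y</ci></apply>
            <cn cellml:units="dimensionless"
                xmlns:cellml="{CELLML11}">0</cn>
          </apply>
        </math>
      </component>
    </model>"""
    flat = resolve_imports(parse_cellml(text))
    assert flat.component("c").variable("y").initial_value == "42"
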