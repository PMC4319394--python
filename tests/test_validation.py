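"""Structural validation and dimensional analysis."""

from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from cellsim.document import parse_cellml
from cellsim.errors import DimensionalInconsistency
from cellsim.fixtures import CELLML10, MATHML
from cellsim.mathml import Apply, Ci, Cn, Derivative, Equality
from cellsim.units import (BUILTIN_UNITS, DIMENSIONLESS, Dimension,
                           UnitsEnvironment)
from cellsim.validation import (check_units, dimension_of, validate,
                                validate_structure)

UENV = UnitsEnvironment()


def _venv(**units):
    return {name: UENV.resolve(u) for name, u in units.items()}


def test_valid_fixtures_are_clean(valid_texts):
    for name, text in valid_texts.items():
        model = parse_cellml(text)
        assert validate(model) == [], name


def test_volt_plus_volt_is_volt():
    d = dimension_of(Apply("plus", (Ci("u"), Ci("v"))), UENV,
                     _venv(u="volt", v="volt"))
    assert d == BUILTIN_UNITS["volt"]
    # m^2 kg s^-3 A^-1
    assert d.exponents == (Fraction(2), Fraction(1), Fraction(-3),
                           Fraction(-1), 0, 0, 0)


def test_volt_plus_second_is_inconsistent():
    with pytest.raises(DimensionalInconsistency) as exc:
        dimension_of(Apply("plus", (Ci("u"), Ci("t"))), UENV,
                     _venv(u="volt", t="second"))
    assert exc.value.operator == "plus"


def test_millivolt_per_millisecond_prefixes_cancel():
    env = UnitsEnvironment({
        "millivolt": [("volt", -3, 1.0, 1.0, 0.0)],
        "millisecond": [("second", -3, 1.0, 1.0, 0.0)],
    })
    d = dimension_of(Derivative("v", "t"), env,
                     {"v": env.resolve("millivolt"),
                      "t": env.resolve("millisecond")})
    expected = BUILTIN_UNITS["volt"] / BUILTIN_UNITS["second"]
    assert d.exponents == expected.exponents
    assert d.multiplier == pytest.approx(1.0)


def test_transcendental_requires_dimensionless():
    with pytest.raises(DimensionalInconsistency):
        dimension_of(Apply("exp", (Ci("t"),)), UENV, _venv(t="second"))
    d = dimension_of(Apply("exp", (Ci("x"),)), UENV, _venv(x="radian"))
    assert d.dimensionless


def test_power_scales_exponents():
    d = dimension_of(
        Apply("power", (Ci("l"), Cn(3.0, "dimensionless", "3"))),
        UENV, _venv(l="metre"))
    assert d.exponents[0] == Fraction(3)


_PHYSICAL = sorted(n for n, d in BUILTIN_UNITS.items()
                   if not d.boolean and d.offset == 0.0)


@given(a=st.sampled_from(_PHYSICAL), b=st.sampled_from(_PHYSICAL))
def test_product_dimension_matches_exponent_sum_oracle(a, b):
    """dim(a*b) equals the elementwise exponent sum, checked against a
    direct arithmetic oracle independent of the dimension algebra."""
    d = dimension_of(Apply("times", (Ci("a"), Ci("b"))), UENV,
                     _venv(a=a, b=b))
    oracle = tuple(x + y for x, y in zip(BUILTIN_UNITS[a].exponents,
                                         BUILTIN_UNITS[b].exponents))
    assert d.exponents == oracle
    assert d.multiplier == pytest.approx(
        BUILTIN_UNITS[a].multiplier * BUILTIN_UNITS[b].multiplier)


def test_undefined_variable_reported_once_per_group(invalid_suite):
    model = parse_cellml(invalid_suite["undefined-variable"])
    issues = validate_structure(model)
    assert [i.code for i in issues] == ["undefined-variable"]


def test_connection_to_missing_component_location(invalid_suite):
    text = invalid_suite["dangling-connection"]
    model = parse_cellml(text)
    issues = validate_structure(model)
    assert [i.code for i in issues] == ["dangling-connection"]
    line = issues[0].location.line
    assert "ghost" in text.splitlines()[line - 1]


def test_circular_units_single_error(invalid_suite):
    model = parse_cellml(invalid_suite["circular-units"])
    assert validate_structure(model) == []
    issues = check_units(model)
    assert [i.code for i in issues] == ["circular-units"]
    assert issues[0].severity == "error"


def test_units_mismatch_is_warning_not_error(invalid_suite):
    model = parse_cellml(invalid_suite["mismatched-addition"])
    assert validate_structure(model) == []
    issues = check_units(model)
    assert [(i.severity, i.code) for i in issues] \
        == [("warning", "unit-mismatch")]


def test_interface_mismatch_detected():
    text = f"""<model name="m" xmlns="{CELLML10}">
      <component name="a">
        <variable name="t" units="second" public_interface="out"/>
        <variable name="x" units="dimensionless" initial_value="1"/>
        <math xmlns="{MATHML}">
          <apply><eq/>
            <apply><diff/><bvar><ci>t</ci></bvar><ci>x</ci></apply>
            <cn cellml:units="dimensionless"
                xmlns:cellml="{CELLML10}">0</cn>
          </apply>
        </math>
      </component>
      <component name="b">
        <variable name="t" units="second" public_interface="out"/>
      </component>
      <connection>
        <map_components component_1="a" component_2="b"/>
        <map_variables variable_1="t" variable_2="t"/>
      </connection>
    </model>"""
    issues = validate_structure(parse_cellml(text))
    assert "interface-mismatch" in [i.code for i in issues]


def test_overdefined_variable():
    text = f"""<model name="m" xmlns="{CELLML10}">
      <component name="c">
        <variable name="t" units="second"/>
        <variable name="x" units="dimensionless" initial_value="1"/>
        <variable name="k" units="dimensionless" initial_value="2"/>
        <math xmlns="{MATHML}">
          <apply><eq/>
            <apply><diff/><bvar><ci>t</ci></bvar><ci>x</ci></apply>
            <ci>k</ci>
          </apply>
          <apply><eq/>
            <ci>k</ci>
            <cn cellml:units="dimensionless" xmlns:cellml="{CELLML10}">3</cn>
          </apply>
        </math>
      </component>
    </model>"""
    issues = validate_structure(parse_cellml(text))
    assert "overdefined-variable" in [i.code for i in issues]


def test_issue_ordering_deterministic(invalid_suite):
    model = parse_cellml(invalid_suite["undefined-variable"])
    a = validate_structure(model)
    b = validate_structure(parse_cellml(invalid_suite["undefined-variable"]))
    assert [i.format() for i in a] == [i.format() for i in b]
    keys = [(i.location.line, i.location.column) for i in a]
    assert keys == sorted(keys)


def test_diagnostic_line_format():
    from cellsim.mathml import SourceLocation
    from cellsim.validation import ValidationIssue
    issue = ValidationIssue("error", "some-code", "message text",
                            SourceLocation(7, 3))
    assert issue.format() == "error:7:3: [some-code] message text"
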