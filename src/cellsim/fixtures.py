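"""Programmatic generators for every test model the package needs.

All models are produced as deterministic CellML text, so the entire test
suite runs without any downloaded data: a one-state exponential decay, a
FitzHugh-Nagumo model populating all six parameter categories, a model with
an algebraic (NLA) loop, a CellML 1.1 import pair, and a suite of invalid
documents each carrying exactly one known defect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

CELLML10 = "http://www.cellml.org/cellml/1.0#"
CELLML11 = "http://www.cellml.org/cellml/1.1#"
CMETA = "http://www.cellml.org/metadata/1.0#"
MATHML = "http://www.w3.org/1998/Math/MathML"
XLINK = "http://www.w3.org/1999/xlink"
RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"


@dataclass
class FixtureSpec:
    """What a generated fixture is built to contain."""

    name: str
    parameters: dict = field(default_factory=dict)
    #: (voi, states, rates, constants, computed_constants, algebraic)
    census: tuple = ()
    defect_codes: List[str] = field(default_factory=list)
    defect_marker: str = ""  # substring locating the defect's line


def _num(x) -> str:
    x = float(x)
    return str(int(x)) if x.is_integer() else repr(x)


def make_decay(a=1.0, y0=10.0) -> str:
    """One-state exponential decay dy/dt = -a*y with real (second) units.

    The state carries the metadata id ``Ca_i`` so annotation examples have a
    stable subject.  Census: (1 VOI, 1 state, 1 rate, 1 constant, 0, 0).
    """
    return f"""<?xml version="1.0" encoding="UTF-8"?>
<model name="decay" xmlns="{CELLML10}" xmlns:cmeta="{CMETA}">
  <units name="per_second">
    <unit units="second" exponent="-1"/>
  </units>
  <component name="main">
    <variable name="time" units="second"/>
    <variable name="y" units="dimensionless" initial_value="{_num(y0)}" cmeta:id="Ca_i"/>
    <variable name="a" units="per_second" initial_value="{_num(a)}"/>
    <math xmlns="{MATHML}">
      <apply><eq/>
        <apply><diff/>
          <bvar><ci>time</ci></bvar>
          <ci>y</ci>
        </apply>
        <apply><times/>
          <apply><minus/><ci>a</ci></apply>
          <ci>y</ci>
        </apply>
      </apply>
    </math>
  </component>
</model>
"""


def make_fhn(eps=0.08, a=0.7, b=0.8, i_app=0.5, v0=-1.0, w0=1.0) -> str:
    """FitzHugh-Nagumo excitable cell, populating all six categories.

    v' = v - v^3/3 - w + i_app;  w' = eps*(v + a) - eb*w  with the computed
    constant eb = eps*b, plus the algebraic recovery gap u = v - w.  All
    quantities dimensionless (including the VOI), so units checking is clean.
    Census: (1, 2, 2, 4, 1, 1).
    """
    return f"""<?xml version="1.0" encoding="UTF-8"?>
<model name="fhn" xmlns="{CELLML10}" xmlns:cmeta="{CMETA}">
  <component name="membrane">
    <variable name="time" units="dimensionless"/>
    <variable name="v" units="dimensionless" initial_value="{_num(v0)}"/>
    <variable name="w" units="dimensionless" initial_value="{_num(w0)}"/>
    <variable name="a" units="dimensionless" initial_value="{_num(a)}"/>
    <variable name="b" units="dimensionless" initial_value="{_num(b)}"/>
    <variable name="eps" units="dimensionless" initial_value="{_num(eps)}"/>
    <variable name="i_app" units="dimensionless" initial_value="{_num(i_app)}"/>
    <variable name="eb" units="dimensionless"/>
    <variable name="u" units="dimensionless"/>
    <math xmlns="{MATHML}">
      <apply><eq/>
        <ci>eb</ci>
        <apply><times/><ci>eps</ci><ci>b</ci></apply>
      </apply>
      <apply><eq/>
        <apply><diff/>
          <bvar><ci>time</ci></bvar>
          <ci>v</ci>
        </apply>
        <apply><plus/>
          <apply><minus/>
            <apply><minus/>
              <ci>v</ci>
              <apply><divide/>
                <apply><power/><ci>v</ci><cn cellml:units="dimensionless" xmlns:cellml="{CELLML10}">3</cn></apply>
                <cn cellml:units="dimensionless" xmlns:cellml="{CELLML10}">3</cn>
              </apply>
            </apply>
            <ci>w</ci>
          </apply>
          <ci>i_app</ci>
        </apply>
      </apply>
      <apply><eq/>
        <apply><diff/>
          <bvar><ci>time</ci></bvar>
          <ci>w</ci>
        </apply>
        <apply><minus/>
          <apply><times/>
            <ci>eps</ci>
            <apply><plus/><ci>v</ci><ci>a</ci></apply>
          </apply>
          <apply><times/><ci>eb</ci><ci>w</ci></apply>
        </apply>
      </apply>
      <apply><eq/>
        <ci>u</ci>
        <apply><minus/><ci>v</ci><ci>w</ci></apply>
      </apply>
    </math>
  </component>
</model>
"""


def make_nla(z0=0.0) -> str:
    """Model with an algebraic loop: x + y = 3, x - y = 1, dz/dt = x.

    Neither loop equation is in assignment form, so equation ordering must
    emit one NLA block with two equations and two unknowns (x = 2, y = 1).
    """
    return f"""<?xml version="1.0" encoding="UTF-8"?>
<model name="nla_loop" xmlns="{CELLML10}">
  <component name="loop">
    <variable name="time" units="dimensionless"/>
    <variable name="x" units="dimensionless"/>
    <variable name="y" units="dimensionless"/>
    <variable name="z" units="dimensionless" initial_value="{_num(z0)}"/>
    <math xmlns="{MATHML}">
      <apply><eq/>
        <apply><plus/><ci>x</ci><ci>y</ci></apply>
        <cn cellml:units="dimensionless" xmlns:cellml="{CELLML10}">3</cn>
      </apply>
      <apply><eq/>
        <apply><minus/><ci>x</ci><ci>y</ci></apply>
        <cn cellml:units="dimensionless" xmlns:cellml="{CELLML10}">1</cn>
      </apply>
      <apply><eq/>
        <apply><diff/>
          <bvar><ci>time</ci></bvar>
          <ci>z</ci>
        </apply>
        <ci>x</ci>
      </apply>
    </math>
  </component>
</model>
"""


def make_conservation(k=0.5, y1_0=1.0, y2_0=0.0) -> str:
    """Two-state mass-transfer probe: y1' = -k*y1, y2' = +k*y1.

    The sum y1 + y2 is conserved exactly, which bounds a solver's drift.
    """
    return f"""<?xml version="1.0" encoding="UTF-8"?>
<model name="conservation" xmlns="{CELLML10}">
  <units name="per_second">
    <unit units="second" exponent="-1"/>
  </units>
  <component name="pool">
    <variable name="time" units="second"/>
    <variable name="y1" units="dimensionless" initial_value="{_num(y1_0)}"/>
    <variable name="y2" units="dimensionless" initial_value="{_num(y2_0)}"/>
    <variable name="k" units="per_second" initial_value="{_num(k)}"/>
    <math xmlns="{MATHML}">
      <apply><eq/>
        <apply><diff/>
          <bvar><ci>time</ci></bvar>
          <ci>y1</ci>
        </apply>
        <apply><times/>
          <apply><minus/><ci>k</ci></apply>
          <ci>y1</ci>
        </apply>
      </apply>
      <apply><eq/>
        <apply><diff/>
          <bvar><ci>time</ci></bvar>
          <ci>y2</ci>
        </apply>
        <apply><times/><ci>k</ci><ci>y1</ci></apply>
      </apply>
    </math>
  </component>
</model>
"""


IMPORTED_DOC_NAME = "decay_parts.cellml"
MAIN_DOC_NAME = "main.cellml"


def make_import_pair(a=1.0, y0=10.0):
    """A CellML 1.1 composite equivalent to :func:`make_decay`.

    The main document hosts the driver component with the VOI and imports
    both a units definition and the decaying component from the second
    document; flattening must reproduce the decay census (over two
    components) and identical dynamics.

    Returns ``(main_text, imported_text)``; bind them to a locator via
    :class:`cellsim.flatten.InMemoryLocator`.
    """
    imported = f"""<?xml version="1.0" encoding="UTF-8"?>
<model name="decay_parts" xmlns="{CELLML11}">
  <units name="per_second">
    <unit units="second" exponent="-1"/>
  </units>
  <component name="decayer">
    <variable name="time" units="second" public_interface="in"/>
    <variable name="y" units="dimensionless" initial_value="{_num(y0)}"/>
    <variable name="a" units="per_second" initial_value="{_num(a)}"/>
    <math xmlns="{MATHML}">
      <apply><eq/>
        <apply><diff/>
          <bvar><ci>time</ci></bvar>
          <ci>y</ci>
        </apply>
        <apply><times/>
          <apply><minus/><ci>a</ci></apply>
          <ci>y</ci>
        </apply>
      </apply>
    </math>
  </component>
</model>
"""
    main = f"""<?xml version="1.0" encoding="UTF-8"?>
<model name="decay_composite" xmlns="{CELLML11}" xmlns:xlink="{XLINK}">
  <import xlink:href="{IMPORTED_DOC_NAME}">
    <units name="per_second" units_ref="per_second"/>
    <component name="cell" component_ref="decayer"/>
  </import>
  <component name="environment">
    <variable name="time" units="second" public_interface="out"/>
  </component>
  <connection>
    <map_components component_1="environment" component_2="cell"/>
    <map_variables variable_1="time" variable_2="time"/>
  </connection>
</model>
"""
    return main, imported


# ---------------------------------------------------------------------------
# invalid suite

def _decay_with(extra: str = "", equation: str = "") -> str:
    """Decay skeleton with an optional extra element or replaced equation."""
    eq = equation or f"""<apply><eq/>
        <apply><diff/>
          <bvar><ci>time</ci></bvar>
          <ci>y</ci>
        </apply>
        <apply><times/>
          <apply><minus/><ci>a</ci></apply>
          <ci>y</ci>
        </apply>
      </apply>"""
    return f"""<?xml version="1.0" encoding="UTF-8"?>
<model name="broken" xmlns="{CELLML10}" xmlns:cmeta="{CMETA}">
  <units name="per_second">
    <unit units="second" exponent="-1"/>
  </units>
  <component name="main">
    <variable name="time" units="second"/>
    <variable name="y" units="dimensionless" initial_value="10"/>
    <variable name="a" units="per_second" initial_value="1"/>
    <math xmlns="{MATHML}">
      {eq}
    </math>
  </component>
{extra}</model>
"""


def make_invalid_suite() -> Dict[str, str]:
    """One document per defect code; each yields exactly that diagnostic."""
    suite: Dict[str, str] = {}

    suite["undefined-variable"] = _decay_with(
        extra="""  <component name="spare">
    <variable name="orphan" units="dimensionless"/>
  </component>
""")

    suite["duplicate-component"] = _decay_with(
        extra="""  <component name="main">
    <variable name="pad" units="second" initial_value="0"/>
  </component>
""")

    suite["mismatched-addition"] = _decay_with(
        equation=f"""<apply><eq/>
        <apply><diff/>
          <bvar><ci>time</ci></bvar>
          <ci>y</ci>
        </apply>
        <apply><plus/>
          <apply><times/>
            <apply><minus/><ci>a</ci></apply>
            <ci>y</ci>
          </apply>
          <ci>time</ci>
        </apply>
      </apply>""")

    suite["dangling-connection"] = _decay_with(
        extra="""  <connection>
    <map_components component_1="main" component_2="ghost"/>
    <map_variables variable_1="time" variable_2="time"/>
  </connection>
""")

    suite["circular-units"] = _decay_with(
        extra="""  <units name="aa">
    <unit units="bb"/>
  </units>
  <units name="bb">
    <unit units="aa"/>
  </units>
""")

    suite["circular-import"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<model name="circular_import" xmlns="{CELLML11}" xmlns:xlink="{XLINK}">
  <import xlink:href="circular_import.cellml">
    <component name="c" component_ref="c"/>
  </import>
</model>
"""

    suite["corrupted-rdf"] = _decay_with(
        extra=f"""  <rdf:RDF xmlns:rdf="{RDF}">stray literal text where a node is required</rdf:RDF>
""")

    suite["cn-without-units"] = _decay_with(
        equation="""<apply><eq/>
        <apply><diff/>
          <bvar><ci>time</ci></bvar>
          <ci>y</ci>
        </apply>
        <apply><times/>
          <apply><minus/><ci>a</ci></apply>
          <ci>y</ci>
          <cn>1</cn>
        </apply>
      </apply>""")

    return suite


#: diagnostic code each invalid document is constructed to raise
INVALID_EXPECTED_CODES: Dict[str, str] = {
    "undefined-variable": "undefined-variable",
    "duplicate-component": "duplicate-component",
    "mismatched-addition": "unit-mismatch",
    "dangling-connection": "dangling-connection",
    "circular-units": "circular-units",
    "circular-import": "circular-import",
    "corrupted-rdf": "corrupted-rdf",
    "cn-without-units": "cn-without-units",
}

#: substring whose (last) occurrence marks the line a defect is reported on
INVALID_MARKERS: Dict[str, str] = {
    "undefined-variable": 'name="orphan"',
    "duplicate-component": '<component name="main">\n    <variable name="pad"',
    "mismatched-addition": "<plus/>",
    "dangling-connection": 'component_2="ghost"',
    "circular-units": '<units name="aa">',
    "circular-import": 'xlink:href="circular_import.cellml"',
    "corrupted-rdf": "<rdf:RDF",
    "cn-without-units": "<cn>1</cn>",
}


def fixture_specs() -> List[FixtureSpec]:
    """Declared construction facts for the valid fixtures."""
    return [
        FixtureSpec("decay", {"a": 1.0, "y0": 10.0}, (1, 1, 1, 1, 0, 0)),
        FixtureSpec("fhn", {"eps": 0.08, "a": 0.7, "b": 0.8, "i_app": 0.5},
                    (1, 2, 2, 4, 1, 1)),
        FixtureSpec("nla_loop", {"z0": 0.0}, (1, 1, 1, 0, 2, 0)),
        FixtureSpec("conservation", {"k": 0.5}, (1, 2, 2, 1, 0, 0)),
    ]


def marker_line(text: str, marker: str) -> int:
    """1-based line of the *last* occurrence of ``marker`` in ``text``."""
    idx = text.rindex(marker)
    return text.count("\n", 0, idx) + 1


def write_suite(directory) -> List[str]:
    """Materialize every fixture under ``directory``; returns filenames."""
    import pathlib

    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    files = {
        "decay.cellml": make_decay(),
        "fhn.cellml": make_fhn(),
        "nla_loop.cellml": make_nla(),
        "conservation.cellml": make_conservation(),
    }
    main, imported = make_import_pair()
    files[MAIN_DOC_NAME] = main
    files[IMPORTED_DOC_NAME] = imported
    for code, text in make_invalid_suite().items():
        files[f"invalid_{code.replace('-', '_')}.cellml"] = text
    for fname, text in sorted(files.items()):
        (d / fname).write_text(text, encoding="utf-8")
    return sorted(files)
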