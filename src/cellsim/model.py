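"""Structured representation of a CellML 1.0/1.1 document.

All dataclasses compare structurally with source locations excluded, so the
parse -> serialize -> parse round trip can be asserted with plain ``==``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .mathml import Equality, SourceLocation

CELLML_1_0_NS = "http://www.cellml.org/cellml/1.0#"
CELLML_1_1_NS = "http://www.cellml.org/cellml/1.1#"
CMETA_NS = "http://www.cellml.org/metadata/1.0#"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"

_IDENT = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def is_identifier(name: str) -> bool:
    """CellML identifier: letters/digits/underscore, no leading digit."""
    return bool(_IDENT.match(name or ""))


def _locfield():
    return field(default=SourceLocation(1, 1), compare=False, repr=False)


@dataclass
class Variable:
    name: str
    units: str
    initial_value: Optional[str] = None  # decimal text or (1.1) variable name
    public_interface: str = "none"       # in | out | none
    private_interface: str = "none"
    cmeta_id: Optional[str] = None
    location: SourceLocation = _locfield()


@dataclass
class Component:
    name: str
    variables: List[Variable] = field(default_factory=list)
    equations: List[Equality] = field(default_factory=list)
    cmeta_id: Optional[str] = None
    location: SourceLocation = _locfield()

    def variable(self, name: str) -> Optional[Variable]:
        for v in self.variables:
            if v.name == name:
                return v
        return None


@dataclass
class Connection:
    component_1: str
    component_2: str
    variable_pairs: List[Tuple[str, str]] = field(default_factory=list)
    location: SourceLocation = _locfield()


@dataclass
class UnitReference:
    units: str
    prefix: int = 0          # power of ten
    exponent: float = 1.0
    multiplier: float = 1.0
    offset: float = 0.0
    location: SourceLocation = _locfield()


@dataclass
class UnitsDefinition:
    name: str
    base: bool = False
    parts: List[UnitReference] = field(default_factory=list)
    location: SourceLocation = _locfield()


@dataclass
class ImportDirective:
    href: str
    imported_units: List[Tuple[str, str]] = field(default_factory=list)
    imported_components: List[Tuple[str, str]] = field(default_factory=list)
    location: SourceLocation = _locfield()


@dataclass
class CellMLModel:
    name: str
    version: str = "1.0"                 # "1.0" | "1.1"
    components: List[Component] = field(default_factory=list)
    connections: List[Connection] = field(default_factory=list)
    units_definitions: List[UnitsDefinition] = field(default_factory=list)
    imports: List[ImportDirective] = field(default_factory=list)
    embedded_rdf: Optional[str] = None   # verbatim RDF/XML block(s)
    foreign_blocks: List[str] = field(default_factory=list)
    cmeta_id: Optional[str] = None
    base_locator: str = field(default="", compare=False)
    math_issues: List[tuple] = field(default_factory=list, compare=False)
    rdf_location: SourceLocation = _locfield()
    location: SourceLocation = _locfield()

    @property
    def namespace(self) -> str:
        return CELLML_1_1_NS if self.version == "1.1" else CELLML_1_0_NS

    def component(self, name: str) -> Optional[Component]:
        for c in self.components:
            if c.name == name:
                return c
        return None

    def units_definition(self, name: str) -> Optional[UnitsDefinition]:
        for u in self.units_definitions:
            if u.name == name:
                return u
        return None

    def cmeta_ids(self) -> set:
        """All metadata ids present anywhere in the document."""
        ids = set()
        if self.cmeta_id:
            ids.add(self.cmeta_id)
        for c in self.components:
            if c.cmeta_id:
                ids.add(c.cmeta_id)
            for v in c.variables:
                if v.cmeta_id:
                    ids.add(v.cmeta_id)
        return ids
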