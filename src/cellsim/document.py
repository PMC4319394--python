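"""Parsing and serialization of CellML documents.

Parsing keeps 1-based line/column positions for every element so validation
diagnostics can point back into the source text.  Embedded RDF/XML blocks and
foreign-namespace children of the model element are captured verbatim and
re-emitted on serialization, giving structural round-trip fidelity and
byte-level fidelity for opaque blocks.
"""

from __future__ import annotations

from typing import Optional

from lxml import etree

from . import mathml
from .errors import CellMLFormatError, CellMLSyntaxError
from .mathml import MATHML_NS, SourceLocation, math_to_element
from .model import (CELLML_1_0_NS, CELLML_1_1_NS, CMETA_NS, RDF_NS,
                    CellMLModel, Component, Connection, ImportDirective,
                    UnitReference, UnitsDefinition, Variable)
from .units import prefix_exponent

_VERSIONS = {CELLML_1_0_NS: "1.0", CELLML_1_1_NS: "1.1"}


def _make_locator(text: str):
    """Map lxml elements to (line, column) using the raw source lines.

    lxml only reports the line; the column is recovered by scanning that
    line for the element's opening tag.
    """
    lines = text.splitlines()

    def locate(elem) -> SourceLocation:
        line = getattr(elem, "sourceline", None) or 1
        col = 1
        if 1 <= line <= len(lines) and isinstance(elem.tag, str):
            name = etree.QName(elem.tag).localname
            idx = lines[line - 1].find("<" + name)
            if idx < 0:
                idx = lines[line - 1].find(name)
            if idx >= 0:
                col = idx + 1
        return SourceLocation(line, col)

    return locate


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _ns(tag) -> str:
    return etree.QName(tag).namespace or "" if isinstance(tag, str) else ""


def _cmeta_id(elem) -> Optional[str]:
    return elem.get(f"{{{CMETA_NS}}}id")


def detect_version(source) -> str:
    """Return "1.0" or "1.1" from the document namespace.

    Accepts raw text/bytes or an already-parsed :class:`CellMLModel`.
    """
    if isinstance(source, CellMLModel):
        return source.version
    text = source.decode() if isinstance(source, bytes) else source
    try:
        root = etree.fromstring(text.encode())
    except etree.XMLSyntaxError as exc:
        raise CellMLSyntaxError(str(exc),
                                line=exc.lineno, column=exc.offset) from exc
    ns = _ns(root.tag)
    if _local(root.tag) != "model" or ns not in _VERSIONS:
        raise CellMLFormatError(
            f"root element {{{ns}}}{_local(root.tag)} is not a CellML model")
    return _VERSIONS[ns]


def parse_cellml(text, base_locator: str = "", strict: bool = False
                 ) -> CellMLModel:
    """Parse CellML 1.0/1.1 text into a :class:`CellMLModel`.

    Mathematics outside the supported subset and numbers without units are
    recorded as issues on ``model.math_issues`` (and surfaced by structural
    validation); with ``strict=True`` they raise immediately.
    """
    if isinstance(text, bytes):
        text = text.decode()
    locate = _make_locator(text)
    try:
        root = etree.fromstring(text.encode())
    except etree.XMLSyntaxError as exc:
        raise CellMLSyntaxError(str(exc),
                                line=exc.lineno, column=exc.offset) from exc
    ns = _ns(root.tag)
    if _local(root.tag) != "model" or ns not in _VERSIONS:
        raise CellMLFormatError(
            f"root element {{{ns}}}{_local(root.tag)} is not a CellML model")
    version = _VERSIONS[ns]
    issues: list = None if strict else []

    model = CellMLModel(name=root.get("name", ""), version=version,
                        cmeta_id=_cmeta_id(root), base_locator=base_locator,
                        location=locate(root))
    rdf_chunks = []
    for child in root:
        if not isinstance(child.tag, str):
            continue
        cns, ctag = _ns(child.tag), _local(child.tag)
        if cns == RDF_NS:
            if not rdf_chunks:
                model.rdf_location = locate(child)
            rdf_chunks.append(etree.tostring(child, encoding="unicode", with_tail=False))
        elif cns == ns:
            if ctag == "units":
                model.units_definitions.append(_parse_units(child, locate))
            elif ctag == "component":
                model.components.append(
                    _parse_component(child, ns, locate, issues))
            elif ctag == "connection":
                model.connections.append(_parse_connection(child, locate))
            elif ctag == "import":
                model.imports.append(_parse_import(child, ns, locate))
            else:
                # reaction, group, ... preserved opaquely, not interpreted
                model.foreign_blocks.append(
                    etree.tostring(child, encoding="unicode", with_tail=False))
        else:
            model.foreign_blocks.append(
                etree.tostring(child, encoding="unicode", with_tail=False))
    if rdf_chunks:
        model.embedded_rdf = "\n".join(rdf_chunks)
    if issues:
        model.math_issues = [(code, msg, loc) for code, msg, loc in issues]
    return model


def _parse_units(elem, locate) -> UnitsDefinition:
    base = elem.get("base_units", "no") == "yes"
    parts = []
    for u in elem:
        if _local(u.tag) != "unit":
            continue
        parts.append(UnitReference(
            units=u.get("units", ""),
            prefix=prefix_exponent(u.get("prefix")),
            exponent=float(u.get("exponent", "1")),
            multiplier=float(u.get("multiplier", "1")),
            offset=float(u.get("offset", "0")),
            location=locate(u)))
    return UnitsDefinition(name=elem.get("name", ""), base=base, parts=parts,
                           location=locate(elem))


def _parse_component(elem, ns, locate, issues) -> Component:
    comp = Component(name=elem.get("name", ""), cmeta_id=_cmeta_id(elem),
                     location=locate(elem))
    for child in elem:
        ctag = _local(child.tag)
        if ctag == "variable":
            comp.variables.append(Variable(
                name=child.get("name", ""),
                units=child.get("units", ""),
                initial_value=child.get("initial_value"),
                public_interface=child.get("public_interface", "none"),
                private_interface=child.get("private_interface", "none"),
                cmeta_id=_cmeta_id(child),
                location=locate(child)))
        elif ctag == "math" and _ns(child.tag) == MATHML_NS:
            comp.equations.extend(
                mathml.parse_mathml(child, locate=locate, issues=issues))
    return comp


def _parse_connection(elem, locate) -> Connection:
    c1 = c2 = ""
    pairs = []
    loc = locate(elem)
    for child in elem:
        ctag = _local(child.tag)
        if ctag == "map_components":
            c1 = child.get("component_1", "")
            c2 = child.get("component_2", "")
            loc = locate(child)
        elif ctag == "map_variables":
            pairs.append((child.get("variable_1", ""),
                          child.get("variable_2", "")))
    return Connection(component_1=c1, component_2=c2, variable_pairs=pairs,
                      location=loc)


_XLINK_NS = "http://www.w3.org/1999/xlink"


def _parse_import(elem, ns, locate) -> ImportDirective:
    href = elem.get(f"{{{_XLINK_NS}}}href") or elem.get("href") or ""
    imp = ImportDirective(href=href, location=locate(elem))
    for child in elem:
        ctag = _local(child.tag)
        if ctag == "units":
            imp.imported_units.append(
                (child.get("name", ""), child.get("units_ref", "")))
        elif ctag == "component":
            imp.imported_components.append(
                (child.get("name", ""), child.get("component_ref", "")))
    return imp


# ---------------------------------------------------------------------------
# serialization

def serialize_cellml(model: CellMLModel) -> str:
    """Serialize a model back to CellML text.

    The guarantee is structural: re-parsing the output yields a model equal
    to the input up to source locations.  Opaque (RDF and foreign) blocks are
    re-emitted verbatim, and serialization is idempotent.
    """
    ns = model.namespace
    nsmap = {None: ns, "cmeta": CMETA_NS}
    if model.version == "1.1" and model.imports:
        nsmap["xlink"] = _XLINK_NS
    root = etree.Element(f"{{{ns}}}model", nsmap=nsmap)
    root.set("name", model.name)
    if model.cmeta_id:
        root.set(f"{{{CMETA_NS}}}id", model.cmeta_id)

    for imp in model.imports:
        e = etree.SubElement(root, f"{{{ns}}}import")
        e.set(f"{{{_XLINK_NS}}}href", imp.href)
        for local, remote in imp.imported_units:
            u = etree.SubElement(e, f"{{{ns}}}units")
            u.set("name", local)
            u.set("units_ref", remote)
        for local, remote in imp.imported_components:
            c = etree.SubElement(e, f"{{{ns}}}component")
            c.set("name", local)
            c.set("component_ref", remote)

    for ud in model.units_definitions:
        e = etree.SubElement(root, f"{{{ns}}}units")
        e.set("name", ud.name)
        if ud.base:
            e.set("base_units", "yes")
        for part in ud.parts:
            u = etree.SubElement(e, f"{{{ns}}}unit")
            u.set("units", part.units)
            if part.prefix:
                u.set("prefix", str(part.prefix))
            if part.exponent != 1.0:
                u.set("exponent", _num(part.exponent))
            if part.multiplier != 1.0:
                u.set("multiplier", _num(part.multiplier))
            if part.offset != 0.0:
                u.set("offset", _num(part.offset))

    for comp in model.components:
        e = etree.SubElement(root, f"{{{ns}}}component")
        e.set("name", comp.name)
        if comp.cmeta_id:
            e.set(f"{{{CMETA_NS}}}id", comp.cmeta_id)
        for v in comp.variables:
            ve = etree.SubElement(e, f"{{{ns}}}variable")
            ve.set("name", v.name)
            ve.set("units", v.units)
            if v.initial_value is not None:
                ve.set("initial_value", v.initial_value)
            if v.public_interface != "none":
                ve.set("public_interface", v.public_interface)
            if v.private_interface != "none":
                ve.set("private_interface", v.private_interface)
            if v.cmeta_id:
                ve.set(f"{{{CMETA_NS}}}id", v.cmeta_id)
        if comp.equations:
            e.append(math_to_element(comp.equations, ns,
                                     nsmap={None: MATHML_NS}))

    for conn in model.connections:
        e = etree.SubElement(root, f"{{{ns}}}connection")
        mc = etree.SubElement(e, f"{{{ns}}}map_components")
        mc.set("component_1", conn.component_1)
        mc.set("component_2", conn.component_2)
        for v1, v2 in conn.variable_pairs:
            mv = etree.SubElement(e, f"{{{ns}}}map_variables")
            mv.set("variable_1", v1)
            mv.set("variable_2", v2)

    body = etree.tostring(root, pretty_print=True, encoding="unicode")

    # opaque blocks (foreign elements, embedded RDF) are spliced in verbatim
    # so pretty-printing cannot disturb their bytes
    opaque = list(model.foreign_blocks)
    if model.embedded_rdf:
        opaque.append(model.embedded_rdf)
    if opaque:
        blob = "\n".join(opaque) + "\n"
        close = "</model>"
        idx = body.rfind(close)
        if idx >= 0:
            body = body[:idx] + blob + body[idx:]
        else:  # childless model serialized self-closed
            idx = body.rfind("/>")
            body = body[:idx] + ">\n" + blob + close + body[idx + 2:]
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + body


def _num(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(x)
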