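"""Typed AST for the content-MathML subset used by ODE/DAE cell models.

The subset covers arithmetic, powers/roots, transcendental functions,
relational and logical operators, piecewise expressions, first derivatives
with a bound variable, numbers with mandatory units, and the pi/true/false
constants.  Anything else is rejected loudly — an unsupported construct must
never be silently dropped, or a model would mis-simulate.

Structural equality of nodes deliberately ignores source locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

from lxml import etree

from .errors import UnsupportedMathError

MATHML_NS = "http://www.w3.org/1998/Math/MathML"


@dataclass(frozen=True)
class SourceLocation:
    """1-based line/column of an element in the source text."""

    line: int = 1
    column: int = 1

    def __post_init__(self):
        if self.line < 1 or self.column < 1:
            raise ValueError("line and column are 1-based")


_NOLOC = SourceLocation(1, 1)


def _locfield():
    return field(default=_NOLOC, compare=False, repr=False)


@dataclass(frozen=True)
class MathNode:
    pass


@dataclass(frozen=True)
class Ci(MathNode):
    """Reference to a variable by name."""

    name: str
    location: SourceLocation = _locfield()


@dataclass(frozen=True)
class Cn(MathNode):
    """Numeric literal; CellML requires a units attribute on every number."""

    value: float
    units: Optional[str]
    text: str = field(compare=False, default="")
    location: SourceLocation = _locfield()


@dataclass(frozen=True)
class Const(MathNode):
    """pi, true or false."""

    kind: str  # "pi" | "true" | "false"
    location: SourceLocation = _locfield()


@dataclass(frozen=True)
class Derivative(MathNode):
    """d(variable)/d(bound variable), first order."""

    variable: str
    bound: str
    location: SourceLocation = _locfield()


@dataclass(frozen=True)
class Apply(MathNode):
    """Operator application."""

    op: str
    args: Tuple[MathNode, ...]
    location: SourceLocation = _locfield()


@dataclass(frozen=True)
class Piecewise(MathNode):
    pieces: Tuple[Tuple[MathNode, MathNode], ...]  # (value, condition)
    otherwise: Optional[MathNode]
    location: SourceLocation = _locfield()


@dataclass(frozen=True)
class Equality(MathNode):
    """Top-level equation: lhs = rhs."""

    lhs: MathNode
    rhs: MathNode
    location: SourceLocation = _locfield()


#: operator tags accepted inside <apply>, beyond eq/diff which are special
SUPPORTED_OPERATORS = frozenset({
    "plus", "minus", "times", "divide", "power", "root",
    "exp", "ln", "log", "abs", "floor", "ceiling",
    "sin", "cos", "tan", "arcsin", "arccos", "arctan",
    "and", "or", "not",
    "eq", "neq", "lt", "leq", "gt", "geq",
})

TRANSCENDENTAL = frozenset({"exp", "ln", "log", "sin", "cos", "tan",
                            "arcsin", "arccos", "arctan"})
RELATIONAL = frozenset({"eq", "neq", "lt", "leq", "gt", "geq"})
LOGICAL = frozenset({"and", "or", "not"})


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _loc(elem, locate) -> SourceLocation:
    return locate(elem) if locate is not None else _NOLOC


def parse_mathml(math_elem, locate=None, issues=None):
    """Parse a content-MathML ``math`` element into a list of equations.

    Each top-level child must be an equality application.  ``locate`` maps an
    lxml element to a :class:`SourceLocation`.  When ``issues`` is a list,
    recoverable subset violations (unsupported operator, ``cn`` without
    units) are appended to it as ``(code, message, location)`` tuples and a
    placeholder node is produced; otherwise they raise
    :class:`UnsupportedMathError`.
    """
    out = []
    for child in math_elem:
        if not isinstance(child.tag, str):
            continue
        node = _parse_node(child, locate, issues)
        if isinstance(node, Apply) and node.op == "eq" and len(node.args) == 2:
            out.append(Equality(node.args[0], node.args[1],
                                location=node.location))
        elif isinstance(node, Equality):
            out.append(node)
        else:
            _problem(issues, "not-an-equation",
                     "top-level mathematics must be an equality",
                     _loc(child, locate))
            out.append(Equality(node, node, location=_loc(child, locate)))
    return out


def _problem(issues, code, message, location, operator=None):
    if issues is None:
        raise UnsupportedMathError(message, operator=operator,
                                   line=location.line, column=location.column)
    issues.append((code, message, location))


def _parse_node(elem, locate, issues) -> MathNode:
    tag = _local(elem.tag)
    loc = _loc(elem, locate)
    if tag == "ci":
        return Ci((elem.text or "").strip(), location=loc)
    if tag == "cn":
        text = (elem.text or "").strip()
        # cellml:units attribute (any namespace suffix "units" accepted)
        units = None
        for k, v in elem.attrib.items():
            if _local(k) == "units":
                units = v
        if units is None:
            _problem(issues, "cn-without-units",
                     f"number {text!r} has no units attribute", loc)
        if elem.get("type") == "e-notation":
            sep = next(iter(elem), None)
            mantissa = text
            expo = (sep.tail or "").strip() if sep is not None else "0"
            value = float(mantissa) * 10.0 ** float(expo)
            text = f"{mantissa}e{expo}"
        else:
            value = float(text)
        return Cn(value, units, text=text, location=loc)
    if tag == "pi":
        return Const("pi", location=loc)
    if tag in ("true", "false"):
        return Const(tag, location=loc)
    if tag == "piecewise":
        pieces = []
        otherwise = None
        for part in elem:
            ptag = _local(part.tag)
            kids = [k for k in part if isinstance(k.tag, str)]
            if ptag == "piece" and len(kids) == 2:
                pieces.append((_parse_node(kids[0], locate, issues),
                               _parse_node(kids[1], locate, issues)))
            elif ptag == "otherwise" and len(kids) == 1:
                otherwise = _parse_node(kids[0], locate, issues)
            else:
                _problem(issues, "unsupported-operator",
                         f"malformed piecewise part {ptag!r}", loc, ptag)
        return Piecewise(tuple(pieces), otherwise, location=loc)
    if tag == "apply":
        kids = [k for k in elem if isinstance(k.tag, str)]
        if not kids:
            _problem(issues, "unsupported-operator", "empty apply", loc)
            return Cn(0.0, "dimensionless", location=loc)
        op = _local(kids[0].tag)
        oploc = _loc(kids[0], locate)
        if op == "diff":
            bvar = None
            degree_ok = True
            rest = []
            for k in kids[1:]:
                if _local(k.tag) == "bvar":
                    inner = [g for g in k if isinstance(g.tag, str)]
                    for g in inner:
                        gt = _local(g.tag)
                        if gt == "ci":
                            bvar = (g.text or "").strip()
                        elif gt == "degree":
                            d = "".join(g.itertext()).strip()
                            degree_ok = d in ("1", "1.0")
                        else:
                            degree_ok = False
                else:
                    rest.append(k)
            if bvar is None or len(rest) != 1 or _local(rest[0].tag) != "ci":
                _problem(issues, "unsupported-operator",
                         "diff requires one bound variable and one ci",
                         oploc, "diff")
                return Cn(0.0, "dimensionless", location=loc)
            if not degree_ok:
                _problem(issues, "unsupported-operator",
                         "only first derivatives are supported", oploc,
                         "diff")
            return Derivative((rest[0].text or "").strip(), bvar,
                              location=loc)
        if op == "root":
            degree = None
            rest = []
            for k in kids[1:]:
                if _local(k.tag) == "degree":
                    inner = [g for g in k if isinstance(g.tag, str)]
                    degree = _parse_node(inner[0], locate, issues)
                else:
                    rest.append(k)
            args = [_parse_node(k, locate, issues) for k in rest]
            if degree is None:
                degree = Cn(2.0, "dimensionless", text="2", location=loc)
            return Apply("root", (degree, *args), location=loc)
        if op == "log":
            base = None
            rest = []
            for k in kids[1:]:
                if _local(k.tag) == "logbase":
                    inner = [g for g in k if isinstance(g.tag, str)]
                    base = _parse_node(inner[0], locate, issues)
                else:
                    rest.append(k)
            args = [_parse_node(k, locate, issues) for k in rest]
            if base is None:
                base = Cn(10.0, "dimensionless", text="10", location=loc)
            return Apply("log", (base, *args), location=loc)
        if op not in SUPPORTED_OPERATORS:
            _problem(issues, "unsupported-operator",
                     f"unsupported MathML operator <{op}>", oploc, op)
            return Cn(0.0, "dimensionless", location=loc)
        args = tuple(_parse_node(k, locate, issues) for k in kids[1:])
        return Apply(op, args, location=loc)
    _problem(issues, "unsupported-operator",
             f"unsupported MathML element <{tag}>", loc, tag)
    return Cn(0.0, "dimensionless", location=loc)


# ---------------------------------------------------------------------------
# serialization back to content MathML

def math_to_element(equations, cellml_ns: str, nsmap=None):
    """Build a ``math`` element holding the given equations."""
    m = etree.Element(f"{{{MATHML_NS}}}math",
                      nsmap=nsmap or {None: MATHML_NS})
    for eq in equations:
        m.append(_node_to_elem(eq, cellml_ns))
    return m


def _q(tag):
    return f"{{{MATHML_NS}}}{tag}"


def _node_to_elem(node: MathNode, cellml_ns: str):
    if isinstance(node, Equality):
        a = etree.Element(_q("apply"))
        etree.SubElement(a, _q("eq"))
        a.append(_node_to_elem(node.lhs, cellml_ns))
        a.append(_node_to_elem(node.rhs, cellml_ns))
        return a
    if isinstance(node, Ci):
        e = etree.Element(_q("ci"))
        e.text = node.name
        return e
    if isinstance(node, Cn):
        e = etree.Element(_q("cn"))
        e.text = node.text or repr(node.value)
        if node.units is not None:
            e.set(f"{{{cellml_ns}}}units", node.units)
        return e
    if isinstance(node, Const):
        return etree.Element(_q(node.kind))
    if isinstance(node, Derivative):
        a = etree.Element(_q("apply"))
        etree.SubElement(a, _q("diff"))
        b = etree.SubElement(a, _q("bvar"))
        ci = etree.SubElement(b, _q("ci"))
        ci.text = node.bound
        ci2 = etree.SubElement(a, _q("ci"))
        ci2.text = node.variable
        return a
    if isinstance(node, Piecewise):
        p = etree.Element(_q("piecewise"))
        for value, cond in node.pieces:
            piece = etree.SubElement(p, _q("piece"))
            piece.append(_node_to_elem(value, cellml_ns))
            piece.append(_node_to_elem(cond, cellml_ns))
        if node.otherwise is not None:
            o = etree.SubElement(p, _q("otherwise"))
            o.append(_node_to_elem(node.otherwise, cellml_ns))
        return p
    if isinstance(node, Apply):
        a = etree.Element(_q("apply"))
        if node.op == "root" and node.args:
            etree.SubElement(a, _q("root"))
            degree, *rest = node.args
            d = etree.SubElement(a, _q("degree"))
            d.append(_node_to_elem(degree, cellml_ns))
            for r in rest:
                a.append(_node_to_elem(r, cellml_ns))
            return a
        if node.op == "log" and node.args:
            etree.SubElement(a, _q("log"))
            base, *rest = node.args
            b = etree.SubElement(a, _q("logbase"))
            b.append(_node_to_elem(base, cellml_ns))
            for r in rest:
                a.append(_node_to_elem(r, cellml_ns))
            return a
        etree.SubElement(a, _q(node.op))
        for arg in node.args:
            a.append(_node_to_elem(arg, cellml_ns))
        return a
    raise TypeError(f"cannot serialize {node!r}")


def free_variables(node: MathNode) -> set:
    """Names of all variables referenced (ci and derivative operands)."""
    out: set = set()
    _collect_free(node, out)
    return out


def _collect_free(node: MathNode, out: set):
    if isinstance(node, Ci):
        out.add(node.name)
    elif isinstance(node, Derivative):
        out.add(node.variable)
        out.add(node.bound)
    elif isinstance(node, Apply):
        for a in node.args:
            _collect_free(a, out)
    elif isinstance(node, Equality):
        _collect_free(node.lhs, out)
        _collect_free(node.rhs, out)
    elif isinstance(node, Piecewise):
        for v, c in node.pieces:
            _collect_free(v, out)
            _collect_free(c, out)
        if node.otherwise is not None:
            _collect_free(node.otherwise, out)
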