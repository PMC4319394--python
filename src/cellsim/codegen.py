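"""Source export in user-definable formats.

A format description is a flat ``key: value`` text file covering statement
shape, comment syntax, array naming, indexing base, identifier casing,
number style, line wrapping, and one rendering per operator.  The built-in
C, FORTRAN 77, MATLAB and Python formats ship as such files inside the
package — the user-defined path is the only path, so the extension
mechanism is exercised constantly.

Derived operators are lowered before rendering (n-th root to a fractional
power, log with base to a quotient of natural logs), so a format file only
needs renderings for the primitive operator set.  A format missing a
rendering for an operator a model actually uses raises
:class:`FormatDescriptionError` naming the operator.
"""

from __future__ import annotations

import importlib.resources
from typing import Dict, List, Optional, Union

from .analysis import AssignStep, NlaBlock
from .errors import FormatDescriptionError
from .mathml import Apply, Ci, Cn, Const, Derivative, Piecewise
from .runtime import RuntimeModel, build_runtime

BUILTIN_FORMATS = ("c", "f77", "matlab", "python")

_PHASES = (
    ("initialise_constants", "initial values of constants and states",
     None),
    ("compute_computed_constants", "computed constants",
     ("computed_constants",)),
    ("compute_rates", "rates (with the algebraic steps they need)",
     ("algebraic", "rates")),
    ("compute_algebraic", "algebraic variables", ("algebraic",)),
)


class FormatDescription:
    """Parsed format file: repeated keys accumulate into line lists."""

    def __init__(self, text: str, origin: str = "<format>"):
        self.origin = origin
        self._single: Dict[str, str] = {}
        self._multi: Dict[str, List[str]] = {}
        for raw in text.splitlines():
            if raw.startswith("#") or not raw.strip():
                continue
            key, sep, value = raw.partition(":")
            if not sep:
                raise FormatDescriptionError(
                    f"{origin}: malformed line {raw!r}")
            key = key.strip()
            value = value[1:] if value.startswith(" ") else value
            self._multi.setdefault(key, []).append(value)
            self._single[key] = value
        if "name" not in self._single:
            raise FormatDescriptionError(f"{origin}: missing 'name'")

    @property
    def name(self) -> str:
        return self._single["name"]

    def get(self, key: str, default: Optional[str] = None) -> Optional[str]:
        return self._single.get(key, default)

    def lines(self, key: str) -> List[str]:
        return self._multi.get(key, [])

    def operator(self, op: str):
        """(kind, symbol) for an operator; kind is infix/prefix/call."""
        key = f"op.{op}"
        raw = self._single.get(key)
        if raw is None:
            raise FormatDescriptionError(
                f"format {self.name!r} has no rendering for operator "
                f"{op!r} (missing key {key!r})", operator=op)
        kind, _, symbol = raw.partition(" ")
        if kind not in ("infix", "prefix", "call"):
            raise FormatDescriptionError(
                f"format {self.name!r}: bad rendering kind {kind!r} for "
                f"operator {op!r}", operator=op)
        return kind, symbol

    def constant(self, kind: str) -> str:
        raw = self._single.get(f"const.{kind}")
        if raw is None:
            raise FormatDescriptionError(
                f"format {self.name!r} has no rendering for constant "
                f"{kind!r}", operator=kind)
        return raw

    def number(self, value: float) -> str:
        text = f"{float(value):.17g}"
        if self.get("number-style") == "fortran-d":
            if "e" in text or "E" in text:
                text = text.replace("e", "D").replace("E", "D")
            elif "." in text:
                text += "D0"
            else:
                text += ".0D0"
        elif "." not in text and "e" not in text and "E" not in text:
            text += ".0"
        return text

    def mangle(self, identifier: str) -> str:
        case = self.get("identifier-case", "keep")
        if case == "upper":
            return identifier.upper()
        if case == "lower":
            return identifier.lower()
        return identifier


def load_builtin_format(name: str) -> FormatDescription:
    ref = importlib.resources.files("cellsim") / "formats" / f"{name}.fmt"
    return FormatDescription(ref.read_text(encoding="utf-8"),
                             origin=f"{name}.fmt")


def load_format(source: Union[str, FormatDescription]) -> FormatDescription:
    """Accepts a built-in name, a path to a format file, or a parsed one."""
    if isinstance(source, FormatDescription):
        return source
    if source in BUILTIN_FORMATS:
        return load_builtin_format(source)
    with open(source, "r", encoding="utf-8") as fh:
        return FormatDescription(fh.read(), origin=str(source))


# ---------------------------------------------------------------------------
# expression rendering

class _Renderer:
    def __init__(self, fmt: FormatDescription, resolve):
        self.fmt = fmt
        self.resolve = resolve

    def render(self, node) -> str:
        if isinstance(node, Ci):
            return self.resolve(node.name)
        if isinstance(node, Cn):
            return self.fmt.number(node.value)
        if isinstance(node, Const):
            return self.fmt.constant(node.kind)
        if isinstance(node, Derivative):
            raise FormatDescriptionError(
                "derivative used as a value cannot be exported")
        if isinstance(node, Piecewise):
            template = self.fmt.get("piecewise")
            if template is None:
                raise FormatDescriptionError(
                    f"format {self.fmt.name!r} has no piecewise rendering",
                    operator="piecewise")
            out = (self.render(node.otherwise)
                   if node.otherwise is not None
                   else self.fmt.number(float("nan")))
            for value, cond in reversed(node.pieces):
                out = (template
                       .replace("{cond}", self.render(cond))
                       .replace("{then}", self.render(value))
                       .replace("{otherwise}", out))
            return out
        if isinstance(node, Apply):
            return self._apply(node)
        raise TypeError(f"cannot render {node!r}")

    def _apply(self, node: Apply) -> str:
        op, args = node.op, list(node.args)
        # lower derived operators onto the primitive set
        if op == "root":
            degree, base = args
            one = Cn(1.0, "dimensionless")
            return self._apply(Apply("power",
                                     (base, Apply("divide", (one, degree)))))
        if op == "log":
            base, x = args
            return self._apply(Apply("divide", (Apply("ln", (x,)),
                                                Apply("ln", (base,)))))
        if op == "minus" and len(args) == 1:
            kind, symbol = self.fmt.operator("unary-minus")
            rendered = self.render(args[0])
            if kind == "call":
                return f"{symbol}({rendered})"
            return f"({symbol}{rendered})"
        kind, symbol = self.fmt.operator(op)
        rendered = [self.render(a) for a in args]
        if kind == "call":
            return f"{symbol}({', '.join(rendered)})"
        if kind == "prefix":
            sep = " " if symbol and symbol[-1].isalnum() else ""
            return f"({symbol}{sep}{rendered[0]})"
        return "(" + f" {symbol} ".join(rendered) + ")"


# ---------------------------------------------------------------------------
# whole-file emission

def export_source(model_or_runtime,
                  fmt: Union[str, FormatDescription]) -> str:
    """Emit the model's equation plan as source in the given format.

    Sections: a header comment with the six category counts, then one
    function per phase (initialisation, computed constants, rates,
    algebraic).  Output is deterministic for a given model and format.
    """
    runtime = (model_or_runtime
               if isinstance(model_or_runtime, RuntimeModel)
               else build_runtime(model_or_runtime))
    fmt = load_format(fmt)
    a = runtime.analysis
    base = int(fmt.get("index-base", "0"))
    comment = fmt.get("comment", "#")
    indent = " " * int(fmt.get("indent", "4"))

    def slot(category: str, index: int) -> str:
        key = {"state": "states", "rate": "rates", "constant": "constants",
               "computed_constant": "constants", "algebraic": "algebraic"}
        i = index + base
        if category == "computed_constant":
            i = runtime.n_constants + index + base
        template = fmt.get(key[category])
        if template is None:
            raise FormatDescriptionError(
                f"format {fmt.name!r} missing array template "
                f"{key[category]!r}")
        return template.replace("{i}", str(i))

    def resolver(component: str):
        def resolve(name: str):
            rv_key = a.alias_of[(component, name)]
            if rv_key == a.voi.key:
                return fmt.get("voi", "voi")
            for group, cat in ((a.states, "state"),
                               (a.constants, "constant"),
                               (a.computed_constants, "computed_constant"),
                               (a.algebraic, "algebraic")):
                for rv in group:
                    if rv.key == rv_key:
                        return slot(cat, rv.index)
            raise KeyError(f"unresolvable reference {component}/{name}")
        return resolve

    lines: List[str] = []

    def emit_comment(text: str):
        lines.append(f"{comment} {text}".rstrip())

    emit_comment(f"model: {runtime.model.name}")
    emit_comment("category counts: 1 variable of integration, "
                 f"{runtime.n_states} states, {runtime.n_states} rates, "
                 f"{runtime.n_constants} constants, "
                 f"{runtime.n_computed} computed constants, "
                 f"{runtime.n_algebraic} algebraic")
    lines.extend(fmt.lines("file-header"))

    statement = fmt.get("statement", "{lhs} = {rhs}")
    rate_index = {rv.key: rv.index for rv in a.states}

    def emit_statement(lhs: str, rhs: str, body: List[str]):
        body.append(indent + statement.replace("{lhs}", lhs)
                    .replace("{rhs}", rhs))

    def emit_nla(block: NlaBlock, body: List[str]):
        body.append(indent + f"{comment} NLA block {block.index}: "
                    f"{len(block.unknowns)} unknowns solved simultaneously "
                    "at run time; residuals:")
        for cname, eq in block.equations:
            r = _Renderer(fmt, resolver(cname))
            body.append(indent + f"{comment}   0 = "
                        f"({r.render(eq.lhs)}) - ({r.render(eq.rhs)})")

    for fname, title, phases in _PHASES:
        body: List[str] = []
        if phases is None:
            for rv in a.constants:
                emit_statement(slot("constant", rv.index),
                               fmt.number(rv.initial_value), body)
            for rv in a.states:
                emit_statement(slot("state", rv.index),
                               fmt.number(rv.initial_value), body)
        else:
            for step in a.plan.steps:
                if step.phase not in phases:
                    continue
                if isinstance(step, AssignStep):
                    r = _Renderer(fmt, resolver(step.component))
                    rhs = r.render(step.expr)
                    if step.kind == "rate":
                        lhs = slot("rate", rate_index[step.target])
                    else:
                        cat = next(
                            rv.category for rv in
                            a.computed_constants + a.algebraic
                            if rv.key == step.target)
                        idx = next(
                            rv.index for rv in
                            a.computed_constants + a.algebraic
                            if rv.key == step.target)
                        lhs = slot(cat, idx)
                    emit_statement(lhs, rhs, body)
                else:
                    emit_nla(step, body)
        lines.append("")
        emit_comment(title)
        for raw in fmt.lines("function-open"):
            lines.append(raw.replace("{name}", fmt.mangle(fname)))
        if not body and fmt.get("function-empty"):
            body = [indent + fmt.get("function-empty")]
        lines.extend(body)
        lines.extend(fmt.lines("function-close"))

    text = "\n".join(lines).rstrip() + "\n"
    return _wrap_lines(text, fmt)


def _wrap_lines(text: str, fmt: FormatDescription) -> str:
    limit = int(fmt.get("max-line-length", "0"))
    if limit <= 0:
        return text
    cont = fmt.get("continuation", "")
    out = []
    for line in text.split("\n"):
        while len(line) > limit:
            cut = _break_point(line, limit)
            out.append(line[:cut])
            line = cont + line[cut:]
        out.append(line)
    return "\n".join(out)


def _break_point(line: str, limit: int) -> int:
    for i in range(limit - 1, 10, -1):
        if line[i] in " )+-*/,":
            return i + 1 if line[i] != " " else i
    return limit
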