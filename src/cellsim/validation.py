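"""Structural and dimensional validation with line/column diagnostics.

``validate_structure`` reports structural faults as errors;
``check_units`` expands user units definitions to dimension vectors and
reports physical inconsistencies as warnings (a dimensionally suspect model
is still simulable — only structural faults block simulation).  Circular
units definitions are errors.  Issues are always returned sorted by
(line, column, code) so reports are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import mathml
from .errors import CircularUnitsError, DimensionalInconsistency
from .mathml import (Apply, Ci, Cn, Const, Derivative, Equality, Piecewise,
                     RELATIONAL, LOGICAL, TRANSCENDENTAL, SourceLocation)
from .model import CellMLModel, is_identifier
from .units import BOOLEAN, BUILTIN_UNITS, DIMENSIONLESS, Dimension, \
    UnitsEnvironment


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    code: str
    message: str
    location: SourceLocation

    def format(self) -> str:
        """Stable one-line diagnostic: severity:line:column: [code] message."""
        return (f"{self.severity}:{self.location.line}:"
                f"{self.location.column}: [{self.code}] {self.message}")


def _sorted(issues):
    return sorted(issues, key=lambda i: (i.location.line, i.location.column,
                                         i.code, i.message))


def _error(code, msg, loc):
    return ValidationIssue("error", code, msg, loc)


def _warning(code, msg, loc):
    return ValidationIssue("warning", code, msg, loc)


# ---------------------------------------------------------------------------
# connection groups (shared with classification, kept dependency-free here)

class UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic representative: lexicographically smallest
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def connection_groups(model: CellMLModel) -> UnionFind:
    """Union-find over (component, variable) keyed by the model connections.

    Pairs naming missing components or variables are skipped — they are
    reported separately by :func:`validate_structure`.
    """
    uf = UnionFind()
    for comp in model.components:
        for var in comp.variables:
            uf.find((comp.name, var.name))
    for conn in model.connections:
        c1 = model.component(conn.component_1)
        c2 = model.component(conn.component_2)
        if c1 is None or c2 is None:
            continue
        for v1, v2 in conn.variable_pairs:
            if c1.variable(v1) is None or c2.variable(v2) is None:
                continue
            uf.union((c1.name, v1), (c2.name, v2))
    return uf


def equation_target(eq: Equality):
    """The bare side of an equation, as ("var", name) / ("deriv", name, bvar),
    preferring the left side; None when neither side is bare."""
    for side in (eq.lhs, eq.rhs):
        if isinstance(side, Ci):
            return ("var", side.name)
        if isinstance(side, Derivative):
            return ("deriv", side.variable, side.bound)
    return None


# ---------------------------------------------------------------------------
# structural validation

def validate_structure(model: CellMLModel) -> list:
    """Structural checks; an empty list means structurally valid."""
    issues = []

    # math subset violations recorded at parse time
    for code, msg, loc in model.math_issues:
        issues.append(_error(code, msg, loc))

    seen_comp: dict = {}
    for comp in model.components:
        if comp.name in seen_comp:
            issues.append(_error(
                "duplicate-component",
                f"component {comp.name!r} is defined more than once",
                comp.location))
        seen_comp.setdefault(comp.name, comp)

    seen_units: dict = {}
    for ud in model.units_definitions:
        if ud.name in seen_units:
            issues.append(_error(
                "duplicate-units",
                f"units {ud.name!r} defined more than once", ud.location))
        elif ud.name in BUILTIN_UNITS:
            issues.append(_error(
                "shadowed-units",
                f"units {ud.name!r} shadows a built-in units name",
                ud.location))
        seen_units.setdefault(ud.name, ud)

    env_names = set(seen_units) | set(BUILTIN_UNITS)
    for ud in model.units_definitions:
        for part in ud.parts:
            if part.units not in env_names:
                issues.append(_error(
                    "dangling-units",
                    f"units {ud.name!r} refers to unknown units "
                    f"{part.units!r}", part.location))

    for comp in model.components:
        seen_var = set()
        declared = {v.name for v in comp.variables}
        for var in comp.variables:
            if var.name in seen_var:
                issues.append(_error(
                    "duplicate-variable",
                    f"variable {var.name!r} duplicated in component "
                    f"{comp.name!r}", var.location))
            seen_var.add(var.name)
            if not is_identifier(var.name):
                issues.append(_error(
                    "invalid-identifier",
                    f"{var.name!r} is not a valid CellML identifier",
                    var.location))
            if var.units not in env_names:
                issues.append(_error(
                    "dangling-units",
                    f"variable {var.name!r} has unknown units "
                    f"{var.units!r}", var.location))
        for eq in comp.equations:
            for name in sorted(mathml.free_variables(eq)):
                if name not in declared:
                    issues.append(_error(
                        "undeclared-ci",
                        f"equation references undeclared variable {name!r} "
                        f"in component {comp.name!r}", eq.location))

    # connections
    connected_in: set = set()
    for conn in model.connections:
        c1 = model.component(conn.component_1)
        c2 = model.component(conn.component_2)
        if c1 is None or c2 is None:
            missing = conn.component_1 if c1 is None else conn.component_2
            issues.append(_error(
                "dangling-connection",
                f"connection refers to missing component {missing!r}",
                conn.location))
            continue
        for v1, v2 in conn.variable_pairs:
            var1, var2 = c1.variable(v1), c2.variable(v2)
            if var1 is None or var2 is None:
                missing = v1 if var1 is None else v2
                comp = conn.component_1 if var1 is None else conn.component_2
                issues.append(_error(
                    "dangling-connection",
                    f"connection maps missing variable {missing!r} of "
                    f"component {comp!r}", conn.location))
                continue
            dirs = {var1.public_interface, var2.public_interface}
            if dirs != {"in", "out"}:
                issues.append(_error(
                    "interface-mismatch",
                    f"mapping {conn.component_1}/{v1} <-> "
                    f"{conn.component_2}/{v2} must connect an 'out' "
                    "interface to an 'in' interface", conn.location))
            else:
                inc = (c1.name, v1) if var1.public_interface == "in" \
                    else (c2.name, v2)
                connected_in.add(inc)

    # definition-site accounting over resolved groups
    uf = connection_groups(model)
    defined: set = set()       # group representatives with a defining site
    targeted: dict = {}        # (comp, var) -> equation, direct targets only
    for comp in model.components:
        for var in comp.variables:
            if var.initial_value is not None:
                defined.add(uf.find((comp.name, var.name)))
        for eq in comp.equations:
            tgt = equation_target(eq)
            if tgt is not None and tgt[0] == "var":
                targeted[(comp.name, tgt[1])] = eq
                defined.add(uf.find((comp.name, tgt[1])))
            elif tgt is not None:  # derivative: defines the rate; the bound
                defined.add(uf.find((comp.name, tgt[2])))   # VOI
                defined.add(uf.find((comp.name, tgt[1])))   # state (via init)
            else:
                # implicit (NLA-style) equation: every referenced variable
                # is potentially defined by it
                for name in mathml.free_variables(eq):
                    if comp.variable(name) is not None:
                        defined.add(uf.find((comp.name, name)))
    for key in connected_in:
        defined.add(uf.find(key))

    # a variable with an initial value that is also computed by an equation
    for comp in model.components:
        for var in comp.variables:
            if (var.initial_value is not None
                    and (comp.name, var.name) in targeted):
                issues.append(_error(
                    "overdefined-variable",
                    f"variable {comp.name}/{var.name} has an initial value "
                    "and is also computed by an equation", var.location))

    # undefined variables, reported once per resolved group
    reported: set = set()
    for comp in model.components:
        for var in comp.variables:
            rep = uf.find((comp.name, var.name))
            if rep in defined or rep in reported:
                continue
            reported.add(rep)
            issues.append(_error(
                "undefined-variable",
                f"variable {comp.name}/{var.name} is never given a value "
                "(no initial value, no equation, no incoming connection)",
                var.location))

    return _sorted(issues)


# ---------------------------------------------------------------------------
# dimensional analysis

def units_environment(model: CellMLModel) -> UnitsEnvironment:
    defs = {}
    for ud in model.units_definitions:
        defs[ud.name] = [] if ud.base else [
            (p.units, p.prefix, p.exponent, p.multiplier, p.offset)
            for p in ud.parts]
    return UnitsEnvironment(defs)


def _constant_value(node):
    """Value of a constant-folded expression, or None when not constant."""
    if isinstance(node, Cn):
        return node.value
    if isinstance(node, Const) and node.kind == "pi":
        return 3.141592653589793
    if isinstance(node, Apply):
        vals = [_constant_value(a) for a in node.args]
        if any(v is None for v in vals):
            return None
        if node.op == "plus":
            return sum(vals)
        if node.op == "minus":
            return -vals[0] if len(vals) == 1 else vals[0] - vals[1]
        if node.op == "times":
            out = 1.0
            for v in vals:
                out *= v
            return out
        if node.op == "divide":
            return vals[0] / vals[1]
    return None


def dimension_of(expr, units_env: UnitsEnvironment, var_env: dict,
                 issues=None) -> Dimension:
    """Dimension vector of an expression.

    ``var_env`` maps variable name -> :class:`Dimension`.  Inconsistencies
    raise :class:`DimensionalInconsistency`, or — when ``issues`` is a list —
    are appended as warnings and analysis continues with the first operand's
    dimension (so one defect yields one report, not a cascade).
    """
    return _dim(expr, units_env, var_env, issues)


def _mismatch(op, a, b, loc, issues):
    msg = (f"operands of <{op}> have incompatible dimensions: "
           f"{a.describe()} vs {b.describe()}")
    if issues is None:
        raise DimensionalInconsistency(msg, operator=op, left=a, right=b,
                                       line=loc.line, column=loc.column)
    issues.append(_warning("unit-mismatch", msg, loc))


def _scale_mismatch(op, a, b, loc, issues):
    if issues is not None:
        issues.append(_warning(
            "unit-scale-mismatch",
            f"operands of <{op}> agree dimensionally but differ in scale "
            f"({a.multiplier:g} vs {b.multiplier:g})", loc))


def _require_dimensionless(op, d, loc, issues):
    if not d.dimensionless:
        msg = (f"argument of <{op}> must be dimensionless, got "
               f"{d.describe()}")
        if issues is None:
            raise DimensionalInconsistency(msg, operator=op, left=d,
                                           line=loc.line, column=loc.column)
        issues.append(_warning("unit-mismatch", msg, loc))


def _dim(expr, uenv, venv, issues) -> Dimension:
    if isinstance(expr, Ci):
        return venv[expr.name]
    if isinstance(expr, Cn):
        if expr.units is None:
            return DIMENSIONLESS
        return uenv.resolve(expr.units)
    if isinstance(expr, Const):
        return DIMENSIONLESS if expr.kind == "pi" else BOOLEAN
    if isinstance(expr, Derivative):
        return venv[expr.variable] / venv[expr.bound]
    if isinstance(expr, Equality):
        left = _dim(expr.lhs, uenv, venv, issues)
        right = _dim(expr.rhs, uenv, venv, issues)
        if not left.same_dimension(right):
            _mismatch("eq", left, right, expr.location, issues)
        elif not left.same_scale(right):
            _scale_mismatch("eq", left, right, expr.location, issues)
        return BOOLEAN
    if isinstance(expr, Piecewise):
        branch = None
        for value, cond in expr.pieces:
            cdim = _dim(cond, uenv, venv, issues)
            if not cdim.boolean:
                _mismatch("piecewise", BOOLEAN, cdim, expr.location, issues)
            vdim = _dim(value, uenv, venv, issues)
            branch = branch or vdim
            if not branch.same_dimension(vdim):
                _mismatch("piecewise", branch, vdim, expr.location, issues)
        if expr.otherwise is not None:
            vdim = _dim(expr.otherwise, uenv, venv, issues)
            branch = branch or vdim
            if not branch.same_dimension(vdim):
                _mismatch("piecewise", branch, vdim, expr.location, issues)
        return branch or DIMENSIONLESS
    if isinstance(expr, Apply):
        op, args = expr.op, expr.args
        loc = expr.location
        if op in ("plus", "minus"):
            dims = [_dim(a, uenv, venv, issues) for a in args]
            first = dims[0]
            for d in dims[1:]:
                if not first.same_dimension(d):
                    _mismatch(op, first, d, loc, issues)
                elif not first.same_scale(d):
                    _scale_mismatch(op, first, d, loc, issues)
            return first
        if op == "times":
            out = DIMENSIONLESS
            for a in args:
                out = out * _dim(a, uenv, venv, issues)
            return out
        if op == "divide":
            return (_dim(args[0], uenv, venv, issues)
                    / _dim(args[1], uenv, venv, issues))
        if op == "power":
            base = _dim(args[0], uenv, venv, issues)
            edim = _dim(args[1], uenv, venv, issues)
            _require_dimensionless(op, edim, loc, issues)
            k = _constant_value(args[1])
            if k is None:
                # dimension not statically determinable unless base is
                # dimensionless
                _require_dimensionless(op, base, loc, issues)
                return DIMENSIONLESS
            return base ** k
        if op == "root":
            degree, base = args[0], args[1]
            bdim = _dim(base, uenv, venv, issues)
            k = _constant_value(degree)
            if k is None or k == 0:
                _require_dimensionless(op, bdim, loc, issues)
                return DIMENSIONLESS
            return bdim ** (1.0 / k)
        if op == "log":
            for a in args:
                _require_dimensionless(
                    op, _dim(a, uenv, venv, issues), loc, issues)
            return DIMENSIONLESS
        if op in TRANSCENDENTAL:
            for a in args:
                _require_dimensionless(
                    op, _dim(a, uenv, venv, issues), loc, issues)
            return DIMENSIONLESS
        if op in ("abs", "floor", "ceiling"):
            return _dim(args[0], uenv, venv, issues)
        if op in LOGICAL:
            for a in args:
                d = _dim(a, uenv, venv, issues)
                if not d.boolean:
                    _mismatch(op, BOOLEAN, d, loc, issues)
            return BOOLEAN
        if op in RELATIONAL:
            dims = [_dim(a, uenv, venv, issues) for a in args]
            first = dims[0]
            for d in dims[1:]:
                if not first.same_dimension(d):
                    _mismatch(op, first, d, loc, issues)
                elif not first.same_scale(d):
                    _scale_mismatch(op, first, d, loc, issues)
            return BOOLEAN
        raise ValueError(f"no dimensional rule for operator {op!r}")
    raise TypeError(f"cannot dimension {expr!r}")


def check_units(model: CellMLModel) -> list:
    """Dimensional report.  Precondition: no structural errors."""
    issues: list = []
    uenv = units_environment(model)

    # expand every definition once; cycles are errors, deduplicated per cycle
    seen_cycles: set = set()
    usable: set = set()
    for ud in model.units_definitions:
        try:
            uenv.resolve(ud.name)
            usable.add(ud.name)
        except CircularUnitsError as exc:
            members = frozenset(str(exc).split(": ")[1].split(" -> "))
            if members not in seen_cycles:
                seen_cycles.add(members)
                issues.append(_error("circular-units", str(exc),
                                     ud.location))

    def vdim(units_name, fallback=DIMENSIONLESS):
        try:
            return uenv.resolve(units_name)
        except (CircularUnitsError, KeyError):
            return fallback

    for comp in model.components:
        venv = {v.name: vdim(v.units) for v in comp.variables}
        for eq in comp.equations:
            dimension_of(eq, uenv, venv, issues=issues)

    for conn in model.connections:
        c1 = model.component(conn.component_1)
        c2 = model.component(conn.component_2)
        if c1 is None or c2 is None:
            continue
        for v1, v2 in conn.variable_pairs:
            var1, var2 = c1.variable(v1), c2.variable(v2)
            if var1 is None or var2 is None:
                continue
            d1, d2 = vdim(var1.units), vdim(var2.units)
            if not d1.same_dimension(d2):
                issues.append(_warning(
                    "connection-unit-mismatch",
                    f"connected pair {c1.name}/{v1} <-> {c2.name}/{v2} "
                    f"has incompatible units ({var1.units} vs {var2.units})",
                    conn.location))
            elif not d1.same_scale(d2):
                issues.append(_warning(
                    "connection-unit-scale-mismatch",
                    f"connected pair {c1.name}/{v1} <-> {c2.name}/{v2} "
                    "agrees dimensionally but differs in scale; values pass "
                    "through unscaled", conn.location))

    return _sorted(issues)


def validate(model: CellMLModel) -> list:
    """Full report: structural issues, then units issues when structure is
    clean (units checking presumes resolvable references)."""
    issues = validate_structure(model)
    if not any(i.severity == "error" for i in issues):
        issues = _sorted(issues + check_units(model))
    return issues
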