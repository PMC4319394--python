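"""Variable classification and equation ordering for runtime construction.

Every variable of a flattened model is sorted into exactly one of six
categories — variable of integration (VOI), constant, computed constant,
state, rate, algebraic — after merging connected variables into resolved
variables via union-find.  Equations are rewritten into assignment form
where possible; mutually dependent equations (and equations with no bare
side) become non-linear-algebraic (NLA) blocks.  A topological order over
the condensation of the dependency graph yields the executable plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import networkx as nx

from . import mathml
from .errors import (ClassificationError, RedefinitionError,
                     StructuralSingularityError)
from .mathml import Ci, Derivative, Equality
from .model import CellMLModel
from .validation import UnionFind, connection_groups, equation_target

#: the six mutually exclusive parameter categories
CATEGORIES = ("variable_of_integration", "constant", "computed_constant",
              "state", "rate", "algebraic")


@dataclass(frozen=True)
class ResolvedVariable:
    """A connection-merged variable with its canonical site and category."""

    component: str
    name: str
    units: str
    category: str
    index: int
    aliases: Tuple[Tuple[str, str], ...] = ()
    initial_value: Optional[float] = None

    @property
    def key(self) -> Tuple[str, str]:
        return (self.component, self.name)

    @property
    def label(self) -> str:
        return f"{self.component}/{self.name}"


@dataclass
class AssignStep:
    """One assignment: target (a variable, or the rate of a state)."""

    kind: str                       # "var" | "rate"
    target: Tuple[str, str]         # canonical key of variable / state
    expr: object                    # MathNode (the defining side)
    component: str                  # ci-resolution context
    phase: str = "algebraic"        # computed_constants | rates | algebraic


@dataclass
class NlaBlock:
    """Simultaneous equations: residuals lhs - rhs over the unknowns."""

    equations: List[Tuple[str, Equality]]   # (component, equation)
    unknowns: List[Tuple[str, str]]         # canonical keys
    phase: str = "algebraic"
    index: int = 0


@dataclass
class EquationPlan:
    steps: List[object] = field(default_factory=list)

    @property
    def nla_blocks(self) -> List[NlaBlock]:
        return [s for s in self.steps if isinstance(s, NlaBlock)]


@dataclass
class ModelAnalysis:
    """Full classification + ordered plan of a flattened model."""

    voi: ResolvedVariable
    states: List[ResolvedVariable]
    rates: List[ResolvedVariable]
    constants: List[ResolvedVariable]
    computed_constants: List[ResolvedVariable]
    algebraic: List[ResolvedVariable]
    plan: EquationPlan
    alias_of: Dict[Tuple[str, str], Tuple[str, str]] = field(
        default_factory=dict)

    @property
    def census(self) -> Tuple[int, int, int, int, int, int]:
        """(VOI, states, rates, constants, computed constants, algebraic)."""
        return (1, len(self.states), len(self.rates), len(self.constants),
                len(self.computed_constants), len(self.algebraic))

    def all_tracked(self) -> List[ResolvedVariable]:
        return (self.constants + self.computed_constants + self.states
                + self.rates + self.algebraic)

    def lookup(self, component: str, name: str) -> Optional[ResolvedVariable]:
        key = self.alias_of.get((component, name))
        if key is None:
            return None
        for group in (self.states, self.rates, self.constants,
                      self.computed_constants, self.algebraic, [self.voi]):
            for rv in group:
                if rv.key == key and rv.category != "rate":
                    return rv
        return None


def _numeric_initial(var, group_label: str) -> float:
    try:
        return float(var.initial_value)
    except (TypeError, ValueError):
        raise ClassificationError(
            f"initial value {var.initial_value!r} of {group_label} is not "
            "numeric (initial-value-by-variable-reference requires "
            "flattening first)") from None


def analyze(model: CellMLModel) -> ModelAnalysis:
    """Classify variables and order equations of a flattened model."""
    if model.imports:
        raise ClassificationError(
            "model still has imports; flatten it before analysis")

    uf = connection_groups(model)
    members: Dict[tuple, list] = {}
    for comp in model.components:
        for var in comp.variables:
            members.setdefault(uf.find((comp.name, var.name)), []).append(
                (comp.name, var))
    for mem in members.values():
        mem.sort(key=lambda cv: (cv[0], cv[1].name))

    equations: List[Tuple[str, Equality]] = []
    for comp in model.components:
        for eq in comp.equations:
            equations.append((comp.name, eq))

    # -- derivative scan: bound variables and state variables ---------------
    bvar_groups: set = set()
    state_groups: set = set()
    deriv_sites: Dict[tuple, tuple] = {}   # state group -> (comp, var) site
    for cname, eq in equations:
        for node, bare in _derivative_nodes(eq):
            grp_b = uf.find((cname, node.bound))
            grp_v = uf.find((cname, node.variable))
            bvar_groups.add(grp_b)
            if bare:
                state_groups.add(grp_v)
                deriv_sites.setdefault(grp_v, (cname, node.variable))
            else:
                raise ClassificationError(
                    "derivatives may only appear as the defined side of an "
                    f"equation (component {cname!r})")

    if len(bvar_groups) > 1:
        raise ClassificationError(
            "multiple variables of integration: " + ", ".join(
                f"{members[g][0][0]}/{members[g][0][1].name}"
                for g in sorted(bvar_groups)))
    if not bvar_groups:
        raise ClassificationError(
            "model has no differential equation, hence no variable of "
            "integration")
    voi_group = next(iter(bvar_groups))

    # -- assignment extraction ---------------------------------------------
    assigns: List[AssignStep] = []
    residuals: List[Tuple[str, Equality]] = []
    rate_defined: set = set()
    var_defined: Dict[tuple, AssignStep] = {}
    for cname, eq in equations:
        tgt = equation_target(eq)
        if tgt is None:
            residuals.append((cname, eq))
            continue
        expr = eq.rhs if _is_bare(eq.lhs, tgt) else eq.lhs
        if tgt[0] == "deriv":
            grp = uf.find((cname, tgt[1]))
            if grp in rate_defined:
                raise RedefinitionError(
                    f"rate of {cname}/{tgt[1]} is defined twice")
            rate_defined.add(grp)
            assigns.append(AssignStep("rate", grp, expr, cname,
                                      phase="rates"))
        else:
            grp = uf.find((cname, tgt[1]))
            if grp in var_defined:
                raise RedefinitionError(
                    f"variable {cname}/{tgt[1]} is defined twice")
            if grp in state_groups or grp == voi_group:
                raise RedefinitionError(
                    f"{cname}/{tgt[1]} is already defined by the "
                    "differential structure of the model")
            step = AssignStep("var", grp, expr, cname)
            var_defined[grp] = step
            assigns.append(step)

    # -- initial values / constants ----------------------------------------
    initials: Dict[tuple, float] = {}
    for grp, mem in members.items():
        vals = []
        for cname, var in mem:
            if var.initial_value is not None:
                vals.append((cname, var))
        if not vals:
            continue
        nums = {float(v.initial_value) if _is_number(v.initial_value)
                else v.initial_value for _, v in vals}
        if len(nums) > 1:
            raise ClassificationError(
                "conflicting initial values across connected group "
                f"{mem[0][0]}/{mem[0][1].name}: {sorted(map(str, nums))}")
        cname, var = vals[0]
        initials[grp] = _numeric_initial(var, f"{cname}/{var.name}")

    for grp in state_groups:
        if grp not in initials:
            cname, var = members[grp][0]
            raise ClassificationError(
                f"state variable {cname}/{var.name} has no initial value")

    constant_groups = {grp for grp in initials
                       if grp not in state_groups and grp != voi_group
                       and grp not in var_defined}

    # -- NLA blocks ---------------------------------------------------------
    def free_groups(expr, cname):
        return {uf.find((cname, n)) for n in mathml.free_variables(expr)}

    known = state_groups | constant_groups | {voi_group}
    res_unknowns: List[set] = []
    for cname, eq in residuals:
        unknowns = {g for g in free_groups(eq, cname)
                    if g not in known and g not in var_defined}
        res_unknowns.append(unknowns)

    block_uf = UnionFind()
    for i, unknowns in enumerate(res_unknowns):
        block_uf.find(("eq", i))
        for g in unknowns:
            block_uf.union(("eq", i), ("unk", g))
    blocks: Dict[tuple, NlaBlock] = {}
    for i, (cname, eq) in enumerate(residuals):
        rep = block_uf.find(("eq", i))
        blk = blocks.setdefault(rep, NlaBlock([], []))
        blk.equations.append((cname, eq))
        for g in sorted(res_unknowns[i]):
            if g not in blk.unknowns:
                blk.unknowns.append(g)

    # -- dependency graph + SCC condensation --------------------------------
    nodes: List[object] = list(assigns) + list(blocks.values())
    orig_idx = {id(n): i for i, n in enumerate(nodes)}
    defines: Dict[int, set] = {}
    uses: Dict[int, set] = {}       # only groups some plan node defines
    full_uses: Dict[int, set] = {}  # including states/constants/VOI
    definer: Dict[tuple, int] = {}
    for idx, node in enumerate(nodes):
        if isinstance(node, AssignStep):
            d = set() if node.kind == "rate" else {node.target}
            u = free_groups(node.expr, node.component) - d
        else:
            d = set(node.unknowns)
            u = set()
            for cname, eq in node.equations:
                u |= free_groups(eq, cname)
            u -= d
        defines[idx] = d
        full_uses[idx] = u
        uses[idx] = u - state_groups - constant_groups - {voi_group}
        for g in d:
            definer[g] = idx

    g = nx.DiGraph()
    g.add_nodes_from(range(len(nodes)))
    for idx in range(len(nodes)):
        for grp in uses[idx]:
            src = definer.get(grp)
            if src is None:
                cname, var = members[grp][0]
                raise ClassificationError(
                    f"variable {cname}/{var.name} is used but never defined")
            if src != idx:
                g.add_edge(src, idx)

    merged: List[object] = []
    node_of: Dict[int, int] = {}
    for scc in nx.strongly_connected_components(g):
        scc = sorted(scc)
        if len(scc) == 1 and isinstance(nodes[scc[0]], AssignStep):
            merged_node = nodes[scc[0]]
        else:
            blk = NlaBlock([], [])
            only = nodes[scc[0]] if len(scc) == 1 else None
            if isinstance(only, NlaBlock):
                blk = only
            else:
                for idx in scc:
                    n = nodes[idx]
                    if isinstance(n, AssignStep):
                        if n.kind == "rate":
                            raise ClassificationError(
                                "a rate equation participates in an "
                                "algebraic loop; semi-explicit form required")
                        local = _local_name(members[n.target], n.component)
                        blk.equations.append(
                            (n.component, Equality(Ci(local), n.expr)))
                        blk.unknowns.append(n.target)
                    else:
                        blk.equations.extend(n.equations)
                        for u_ in n.unknowns:
                            if u_ not in blk.unknowns:
                                blk.unknowns.append(u_)
            merged_node = blk
        pos = len(merged)
        merged.append(merged_node)
        for idx in scc:
            node_of[idx] = pos

    for node in merged:
        if isinstance(node, NlaBlock):
            if len(node.equations) != len(node.unknowns):
                raise StructuralSingularityError(
                    f"NLA block has {len(node.equations)} equations for "
                    f"{len(node.unknowns)} unknowns")

    cond = nx.DiGraph()
    cond.add_nodes_from(range(len(merged)))
    for a, b in g.edges():
        if node_of[a] != node_of[b]:
            cond.add_edge(node_of[a], node_of[b])
    order = list(nx.lexicographical_topological_sort(cond))

    # -- category assignment ------------------------------------------------
    category: Dict[tuple, str] = {voi_group: "variable_of_integration"}
    for grp in state_groups:
        category[grp] = "state"
    for grp in constant_groups:
        category[grp] = "constant"

    def is_static(groups) -> bool:
        """True when every dependency is a (computed) constant — the
        defining rule for the computed-constant category."""
        return all(category.get(x) in ("constant", "computed_constant")
                   for x in groups)

    ordered_steps: List[object] = []
    for pos in order:
        node = merged[pos]
        if id(node) in orig_idx:
            u = full_uses[orig_idx[id(node)]]
        else:   # block freshly merged from an SCC: recompute its free set
            u = set()
            for cname, eq in node.equations:
                u |= free_groups(eq, cname)
            u -= set(node.unknowns)
        if isinstance(node, AssignStep):
            if node.kind == "rate":
                node.phase = "rates"
            else:
                cat = "computed_constant" if is_static(u) else "algebraic"
                category[node.target] = cat
                node.phase = ("computed_constants"
                              if cat == "computed_constant" else "algebraic")
            ordered_steps.append(node)
        else:
            cat = "computed_constant" if is_static(u) else "algebraic"
            for grp in node.unknowns:
                category[grp] = cat
            node.phase = ("computed_constants" if cat == "computed_constant"
                          else "algebraic")
            ordered_steps.append(node)

    # anything still uncategorised was never defined
    for grp, mem in members.items():
        if grp not in category:
            cname, var = mem[0]
            raise ClassificationError(
                f"variable {cname}/{var.name} is never given a value")

    # -- resolved variables with canonical sites and indices ----------------
    def canonical(grp) -> tuple:
        mem = members[grp]
        if grp == voi_group:
            for cname, var in mem:
                if var.public_interface == "out":
                    return (cname, var)
            for cname, var in mem:
                for c2, eq in equations:
                    if c2 == cname and any(
                            n.bound == var.name
                            for n, _ in _derivative_nodes(eq)):
                        return (cname, var)
            return mem[0]
        for cname, var in mem:
            if var.initial_value is not None:
                return (cname, var)
        site = deriv_sites.get(grp)
        if site:
            for cname, var in mem:
                if (cname, var.name) == site:
                    return (cname, var)
        definer_node = definer.get(grp)
        if definer_node is not None:
            n = nodes[definer_node]
            ref = n.component if isinstance(n, AssignStep) else \
                n.equations[0][0] if isinstance(n, NlaBlock) and \
                n.equations else None
            for cname, var in mem:
                if cname == ref:
                    return (cname, var)
        for cname, var in mem:
            if var.public_interface == "out":
                return (cname, var)
        return mem[0]

    def doc_order_key(grp):
        cname, var = canonical(grp)
        for ci, comp in enumerate(model.components):
            if comp.name == cname:
                for vi, v in enumerate(comp.variables):
                    if v.name == var.name:
                        return (ci, vi)
        return (len(model.components), 0)

    def build(grps, cat) -> List[ResolvedVariable]:
        out = []
        for i, grp in enumerate(sorted(grps, key=doc_order_key)):
            cname, var = canonical(grp)
            out.append(ResolvedVariable(
                component=cname, name=var.name, units=var.units,
                category=cat, index=i,
                aliases=tuple(sorted((c, v.name) for c, v in members[grp])),
                initial_value=initials.get(grp)))
        return out

    voi_rv = build([voi_group], "variable_of_integration")[0]
    state_rvs = build(sorted(state_groups, key=doc_order_key), "state")
    const_rvs = build(constant_groups, "constant")
    computed_rvs = build([grp for grp, c in category.items()
                          if c == "computed_constant"], "computed_constant")
    algebraic_rvs = build([grp for grp, c in category.items()
                           if c == "algebraic"], "algebraic")
    rate_rvs = [ResolvedVariable(
        component=s.component, name=s.name, units=s.units, category="rate",
        index=s.index, aliases=s.aliases) for s in state_rvs]

    # rewrite step targets from group rep to canonical key
    canon_key = {grp: canonical(grp)[0:1] + (canonical(grp)[1].name,)
                 for grp in members}
    alias_of = {}
    for grp, mem in members.items():
        for cname, var in mem:
            alias_of[(cname, var.name)] = canon_key[grp]
    for step in ordered_steps:
        if isinstance(step, AssignStep):
            step.target = canon_key[step.target]
        else:
            step.unknowns = [canon_key[grp] for grp in step.unknowns]
    for i, blk in enumerate(b for b in ordered_steps
                            if isinstance(b, NlaBlock)):
        blk.index = i

    return ModelAnalysis(
        voi=voi_rv, states=state_rvs, rates=rate_rvs, constants=const_rvs,
        computed_constants=computed_rvs, algebraic=algebraic_rvs,
        plan=EquationPlan(list(ordered_steps)), alias_of=alias_of)


def classify_variables(model: CellMLModel) -> Dict[ResolvedVariable, str]:
    """Map every resolved variable (and the VOI) to its category."""
    ana = analyze(model)
    out = {ana.voi: "variable_of_integration"}
    for group in (ana.states, ana.rates, ana.constants,
                  ana.computed_constants, ana.algebraic):
        for rv in group:
            out[rv] = rv.category
    return out


def order_equations(model: CellMLModel) -> EquationPlan:
    return analyze(model).plan


# ---------------------------------------------------------------------------

def _is_number(text) -> bool:
    try:
        float(text)
        return True
    except (TypeError, ValueError):
        return False


def _is_bare(side, tgt) -> bool:
    if tgt[0] == "var":
        return isinstance(side, Ci) and side.name == tgt[1]
    return isinstance(side, Derivative) and side.variable == tgt[1]


def _local_name(group_members, component: str) -> str:
    """Name under which a resolved group is visible inside ``component``."""
    for cname, var in group_members:
        if cname == component:
            return var.name
    return group_members[0][1].name


def _derivative_nodes(eq: Equality):
    """All Derivative nodes with a flag: bare (defined) side or embedded."""
    out = []

    def walk(node, bare):
        if isinstance(node, Derivative):
            out.append((node, bare))
            return
        if isinstance(node, Ci) or isinstance(node, type(None)):
            return
        for child in _children(node):
            walk(child, False)

    tgt = equation_target(eq)
    for side in (eq.lhs, eq.rhs):
        if isinstance(side, Derivative):
            out.append((side, tgt is not None and tgt[0] == "deriv"
                        and side.variable == tgt[1]))
        else:
            walk(side, False)
    return out


def _children(node):
    from .mathml import Apply, Piecewise
    if isinstance(node, Apply):
        return node.args
    if isinstance(node, Piecewise):
        kids = []
        for v, c in node.pieces:
            kids.extend((v, c))
        if node.otherwise is not None:
            kids.append(node.otherwise)
        return kids
    return ()
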