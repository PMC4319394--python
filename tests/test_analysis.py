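"""Variable classification and equation ordering."""

import pytest

from cellsim import mathml
from cellsim.analysis import AssignStep, NlaBlock, analyze, classify_variables
from cellsim.document import parse_cellml
from cellsim.errors import (ClassificationError, RedefinitionError,
                            StructuralSingularityError)
from cellsim.fixtures import CELLML10, MATHML
from cellsim.validation import connection_groups, equation_target


# ---------------------------------------------------------------------------
# independent oracle: dependency-closure classifier straight off the
# equation set, no graph library, no plan

def brute_force_census(model):
    uf = connection_groups(model)
    groups = {}
    for comp in model.components:
        for var in comp.variables:
            groups.setdefault(uf.find((comp.name, var.name)), []).append(
                (comp.name, var))
    equations = [(c.name, eq) for c in model.components
                 for eq in c.equations]

    bvars, states = set(), set()
    for cname, eq in equations:
        tgt = equation_target(eq)
        if tgt and tgt[0] == "deriv":
            bvars.add(uf.find((cname, tgt[2])))
            states.add(uf.find((cname, tgt[1])))
    (voi,) = bvars

    initialised = {g for g, mem in groups.items()
                   if any(v.initial_value is not None for _, v in mem)}

    assigned, residual_eqs = {}, []
    for cname, eq in equations:
        tgt = equation_target(eq)
        if tgt is None:
            residual_eqs.append((cname, eq))
        elif tgt[0] == "var":
            other = eq.rhs if isinstance(eq.lhs, mathml.Ci) \
                and eq.lhs.name == tgt[1] else eq.lhs
            assigned[uf.find((cname, tgt[1]))] = (cname, other)

    constants = {g for g in initialised
                 if g not in states and g != voi and g not in assigned}

    # co-unknowns of residual equations depend on everything in their block
    res_deps = {}
    for cname, eq in residual_eqs:
        free = {uf.find((cname, n)) for n in mathml.free_variables(eq)}
        unknowns = free - states - constants - {voi} - set(assigned)
        for g in unknowns:
            res_deps.setdefault(g, set()).update(free - {g})

    def closure(g, seen):
        """All groups reachable through defining equations."""
        if g in seen:
            return set()
        seen = seen | {g}
        if g in assigned:
            cname, expr = assigned[g]
            deps = {uf.find((cname, n))
                    for n in mathml.free_variables(expr)}
        elif g in res_deps:
            deps = set(res_deps[g])
        else:
            return set()
        out = set(deps)
        for d in deps:
            out |= closure(d, seen)
        return out

    computed, algebraic = set(), set()
    for g in list(assigned) + list(res_deps):
        if g in states or g in constants or g == voi:
            continue
        reach = closure(g, set())
        if voi in reach or reach & states:
            algebraic.add(g)
        else:
            computed.add(g)
    return (1, len(states), len(states), len(constants), len(computed),
            len(algebraic))


@pytest.mark.parametrize("name,expected", [
    ("decay", (1, 1, 1, 1, 0, 0)),
    ("fhn", (1, 2, 2, 4, 1, 1)),
    ("nla", (1, 1, 1, 0, 2, 0)),
    ("conservation", (1, 2, 2, 1, 0, 0)),
])
def test_census_matches_construction_and_oracle(valid_texts, name, expected):
    model = parse_cellml(valid_texts[name])
    ana = analyze(model)
    assert ana.census == expected
    assert brute_force_census(model) == expected


def test_decay_categories(decay_model):
    mapping = {rv.name: cat for rv, cat in
               classify_variables(decay_model).items()
               if cat != "rate"}
    assert mapping == {"time": "variable_of_integration", "y": "state",
                       "a": "constant"}


def test_classification_is_stable(fhn_model):
    first = analyze(fhn_model)
    second = analyze(fhn_model)
    assert first.census == second.census
    assert [type(s).__name__ for s in first.plan.steps] \
        == [type(s).__name__ for s in second.plan.steps]


def test_decay_plan_single_rate_step(decay_model):
    plan = analyze(decay_model).plan
    assert len(plan.steps) == 1
    assert plan.nla_blocks == []
    (step,) = plan.steps
    assert step.kind == "rate"


def test_nla_plan_one_block_two_unknowns(nla_model):
    plan = analyze(nla_model).plan
    (block,) = plan.nla_blocks
    assert len(block.equations) == 2
    assert len(block.unknowns) == 2


def test_plan_never_reads_undefined(valid_texts):
    """Executing the plan in order only ever reads already-known values."""
    for name, text in valid_texts.items():
        model = parse_cellml(text)
        ana = analyze(model)
        uf_known = {ana.voi.key} | {rv.key for rv in ana.states} \
            | {rv.key for rv in ana.constants}
        for step in ana.plan.steps:
            if isinstance(step, AssignStep):
                refs = {ana.alias_of[(step.component, n)]
                        for n in mathml.free_variables(step.expr)}
                assert refs <= uf_known, (name, step.target)
                if step.kind != "rate":
                    uf_known.add(step.target)
            else:
                refs = set()
                for cname, eq in step.equations:
                    refs |= {ana.alias_of[(cname, n)]
                             for n in mathml.free_variables(eq)}
                assert refs - set(step.unknowns) <= uf_known, name
                uf_known.update(step.unknowns)


def _mini_model(body, variables):
    vars_xml = "\n".join(variables)
    return f"""<model name="m" xmlns="{CELLML10}">
      <component name="c">
        {vars_xml}
        <math xmlns="{MATHML}">
          {body}
        </math>
      </component>
    </model>"""


_CN1 = (f'<cn cellml:units="dimensionless" '
        f'xmlns:cellml="{CELLML10}">1</cn>')


def test_two_bound_variables_is_an_error():
    text = _mini_model(
        f"""<apply><eq/>
              <apply><diff/><bvar><ci>t</ci></bvar><ci>y</ci></apply>
              {_CN1}
            </apply>
            <apply><eq/>
              <apply><diff/><bvar><ci>x</ci></bvar><ci>z</ci></apply>
              {_CN1}
            </apply>""",
        ['<variable name="t" units="dimensionless"/>',
         '<variable name="x" units="dimensionless"/>',
         '<variable name="y" units="dimensionless" initial_value="0"/>',
         '<variable name="z" units="dimensionless" initial_value="0"/>'])
    with pytest.raises(ClassificationError, match="multiple"):
        analyze(parse_cellml(text))


def test_no_derivative_is_an_error():
    text = _mini_model(
        f"<apply><eq/><ci>x</ci>{_CN1}</apply>",
        ['<variable name="x" units="dimensionless"/>'])
    with pytest.raises(ClassificationError, match="no differential"):
        analyze(parse_cellml(text))


def test_state_without_initial_value_is_an_error():
    text = _mini_model(
        f"""<apply><eq/>
              <apply><diff/><bvar><ci>t</ci></bvar><ci>y</ci></apply>
              {_CN1}
            </apply>""",
        ['<variable name="t" units="dimensionless"/>',
         '<variable name="y" units="dimensionless"/>'])
    with pytest.raises(ClassificationError, match="initial value"):
        analyze(parse_cellml(text))


def test_double_definition_is_an_error():
    text = _mini_model(
        f"""<apply><eq/>
              <apply><diff/><bvar><ci>t</ci></bvar><ci>y</ci></apply>
              <ci>k</ci>
            </apply>
            <apply><eq/><ci>k</ci>{_CN1}</apply>
            <apply><eq/><ci>k</ci>{_CN1}</apply>""",
        ['<variable name="t" units="dimensionless"/>',
         '<variable name="y" units="dimensionless" initial_value="0"/>',
         '<variable name="k" units="dimensionless"/>'])
    with pytest.raises(RedefinitionError):
        analyze(parse_cellml(text))


def test_singular_nla_block_is_an_error():
    # two equations, one unknown: x + x = 2 and x - 1 = 0 in residual form
    text = _mini_model(
        f"""<apply><eq/>
              <apply><diff/><bvar><ci>t</ci></bvar><ci>y</ci></apply>
              <ci>x</ci>
            </apply>
            <apply><eq/>
              <apply><plus/><ci>x</ci><ci>x</ci></apply>
              {_CN1}
            </apply>
            <apply><eq/>
              <apply><minus/><ci>x</ci>{_CN1}</apply>
              {_CN1}
            </apply>""",
        ['<variable name="t" units="dimensionless"/>',
         '<variable name="y" units="dimensionless" initial_value="0"/>',
         '<variable name="x" units="dimensionless"/>'])
    with pytest.raises(StructuralSingularityError):
        analyze(parse_cellml(text))


def test_assignment_loop_becomes_nla_block(nla_text):
    """x = y + 1 and y = 2x - 3 are each in assignment form but mutually
    dependent; the strongly connected pair must merge into one NLA block."""
    old = """<apply><eq/>
        <apply><plus/><ci>x</ci><ci>y</ci></apply>
        <cn cellml:units="dimensionless" xmlns:cellml="{ns}">3</cn>
      </apply>
      <apply><eq/>
        <apply><minus/><ci>x</ci><ci>y</ci></apply>
        <cn cellml:units="dimensionless" xmlns:cellml="{ns}">1</cn>
      </apply>""".format(ns=CELLML10)
    new = """<apply><eq/>
        <ci>x</ci>
        <apply><plus/><ci>y</ci><cn cellml:units="dimensionless" xmlns:cellml="{ns}">1</cn></apply>
      </apply>
      <apply><eq/>
        <ci>y</ci>
        <apply><minus/><apply><times/><cn cellml:units="dimensionless" xmlns:cellml="{ns}">2</cn><ci>x</ci></apply><cn cellml:units="dimensionless" xmlns:cellml="{ns}">3</cn></apply>
      </apply>""".format(ns=CELLML10)
    assert old in nla_text
    ana = analyze(parse_cellml(nla_text.replace(old, new)))
    (block,) = ana.plan.nla_blocks
    assert len(block.equations) == 2
    assert ana.census == (1, 1, 1, 0, 2, 0)
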