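"""Executable runtime generation.

The original environment this package re-implements turned a model into C
source and compiled it on the fly; here the equation plan is emitted as
native Python functions instead (generated source, ``exec``-ed once at
build time).  The evaluators are pure: they allocate fresh output arrays
and never mutate their inputs.  NLA blocks call the registered NLA solver;
warm-start caches are owned by the caller (a simulation session), never by
the runtime, so concurrent sessions over one runtime cannot interact.
"""

from __future__ import annotations

import math
from typing import Dict, Optional

import numpy as np

from .analysis import AssignStep, ModelAnalysis, NlaBlock, analyze
from .errors import ClassificationError
from .mathml import (Apply, Ci, Cn, Const, Derivative, Equality, Piecewise)
from .model import CellMLModel
from .solvers import newton_solve

_PY_FUNC = {
    "exp": "math.exp", "ln": "math.log", "abs": "abs",
    "floor": "math.floor", "ceiling": "math.ceil",
    "sin": "math.sin", "cos": "math.cos", "tan": "math.tan",
    "arcsin": "math.asin", "arccos": "math.acos", "arctan": "math.atan",
}
_PY_RELATION = {"eq": "==", "neq": "!=", "lt": "<", "leq": "<=",
                "gt": ">", "geq": ">="}


def expr_to_python(node, resolve) -> str:
    """Render an expression as Python source; ``resolve(name)`` supplies the
    code for a variable reference in the current component context."""
    if isinstance(node, Ci):
        return resolve(node.name)
    if isinstance(node, Cn):
        return repr(float(node.value))
    if isinstance(node, Const):
        return {"pi": "math.pi", "true": "True", "false": "False"}[node.kind]
    if isinstance(node, Derivative):
        raise ClassificationError(
            "derivative used as a value inside an expression")
    if isinstance(node, Piecewise):
        out = "float('nan')" if node.otherwise is None \
            else expr_to_python(node.otherwise, resolve)
        for value, cond in reversed(node.pieces):
            out = (f"({expr_to_python(value, resolve)} if "
                   f"{expr_to_python(cond, resolve)} else {out})")
        return out
    if isinstance(node, Apply):
        args = [expr_to_python(a, resolve) for a in node.args]
        op = node.op
        if op == "plus":
            return "(" + "+".join(args) + ")"
        if op == "minus":
            return f"(-{args[0]})" if len(args) == 1 \
                else f"({args[0]}-{args[1]})"
        if op == "times":
            return "(" + "*".join(args) + ")"
        if op == "divide":
            return f"({args[0]}/{args[1]})"
        if op == "power":
            return f"({args[0]})**({args[1]})"
        if op == "root":
            return f"({args[1]})**(1.0/({args[0]}))"
        if op == "log":
            return f"(math.log({args[1]})/math.log({args[0]}))"
        if op in _PY_FUNC:
            return f"{_PY_FUNC[op]}({args[0]})"
        if op in _PY_RELATION:
            return f"({args[0]} {_PY_RELATION[op]} {args[1]})"
        if op == "and":
            return "(" + " and ".join(args) + ")"
        if op == "or":
            return "(" + " or ".join(args) + ")"
        if op == "not":
            return f"(not {args[0]})"
    raise TypeError(f"cannot render {node!r}")


class RuntimeModel:
    """Classified variable arrays plus executable evaluators.

    Constants and computed constants share one ``constants`` array (plain
    constants first), matching the evaluator signatures: computed constants
    are available wherever constants are.
    """

    def __init__(self, model: CellMLModel,
                 analysis: Optional[ModelAnalysis] = None,
                 nla_solver=None):
        self.model = model
        self.analysis = analysis or analyze(model)
        self.nla_solver = nla_solver or (
            lambda residual, guess: np.atleast_1d(
                newton_solve(residual, guess, tol=1e-12)))
        a = self.analysis
        self.n_states = len(a.states)
        self.n_constants = len(a.constants)
        self.n_computed = len(a.computed_constants)
        self.n_algebraic = len(a.algebraic)
        self.counts = {
            "variable_of_integration": 1,
            "state": self.n_states, "rate": self.n_states,
            "constant": self.n_constants,
            "computed_constant": self.n_computed,
            "algebraic": self.n_algebraic,
        }
        self._slots = self._build_slots()
        self.source = self._generate_source()
        namespace = {"math": math}
        exec(compile(self.source, "<cellsim-runtime>", "exec"), namespace)
        self._initialise = namespace["initialise"]
        self._computed = namespace["compute_computed_constants"]
        self._rates = namespace["compute_rates"]
        self._algebraic = namespace["compute_algebraic"]

    # -- slot assignment ----------------------------------------------------
    def _build_slots(self) -> Dict[tuple, str]:
        a = self.analysis
        slots: Dict[tuple, str] = {a.voi.key: "voi"}
        for rv in a.states:
            slots[rv.key] = f"states[{rv.index}]"
        for rv in a.constants:
            slots[rv.key] = f"constants[{rv.index}]"
        for rv in a.computed_constants:
            slots[rv.key] = f"constants[{self.n_constants + rv.index}]"
        for rv in a.algebraic:
            slots[rv.key] = f"algebraic[{rv.index}]"
        return slots

    def slot(self, component: str, name: str) -> str:
        key = self.analysis.alias_of[(component, name)]
        return self._slots[key]

    def _resolver(self, component, overrides=None):
        def resolve(name):
            key = self.analysis.alias_of[(component, name)]
            if overrides and key in overrides:
                return overrides[key]
            return self._slots[key]
        return resolve

    # -- source generation --------------------------------------------------
    def _generate_source(self) -> str:
        a = self.analysis
        lines = ["import math", ""]

        lines.append("def initialise(constants, states):")
        body = []
        for rv in a.constants:
            body.append(f"    constants[{rv.index}] = "
                        f"{rv.initial_value!r}")
        for rv in a.states:
            body.append(f"    states[{rv.index}] = {rv.initial_value!r}")
        lines += body or ["    pass"]
        lines.append("")

        rate_index = {rv.key: rv.index for rv in a.states}

        def emit_step(step, out):
            if isinstance(step, AssignStep):
                resolve = self._resolver(step.component)
                rhs = expr_to_python(step.expr, resolve)
                if step.kind == "rate":
                    out.append(f"    rates[{rate_index[step.target]}] = "
                               f"{rhs}")
                else:
                    out.append(f"    {self._slots[step.target]} = {rhs}")
            else:
                self._emit_nla(step, out)

        for fname, phases in (
                ("compute_computed_constants", ("computed_constants",)),
                ("compute_rates", ("algebraic", "rates")),
                ("compute_algebraic", ("algebraic",))):
            lines.append(f"def {fname}(voi, states, rates, constants, "
                         "algebraic, solve_nla):")
            body = []
            for step in a.plan.steps:
                if step.phase in phases:
                    emit_step(step, body)
            lines += body or ["    pass"]
            lines.append("")
        return "\n".join(lines)

    def _emit_nla(self, block: NlaBlock, out):
        n = len(block.unknowns)
        overrides = {key: f"u[{j}]" for j, key in enumerate(block.unknowns)}
        out.append(f"    def _residual_{block.index}(u):")
        out.append("        return [")
        for cname, eq in block.equations:
            resolve = self._resolver(cname, overrides)
            lhs = expr_to_python(eq.lhs, resolve)
            rhs = expr_to_python(eq.rhs, resolve)
            out.append(f"            ({lhs}) - ({rhs}),")
        out.append("        ]")
        out.append(f"    _sol_{block.index} = solve_nla({block.index}, "
                   f"_residual_{block.index}, {n})")
        for j, key in enumerate(block.unknowns):
            out.append(f"    {self._slots[key]} = _sol_{block.index}[{j}]")

    # -- NLA dispatch -------------------------------------------------------
    def _nla_dispatch(self, nla_state):
        solver = self.nla_solver

        def solve(block_index, residual, n):
            guess = None
            if nla_state is not None:
                guess = nla_state.get(block_index)
            if guess is None:
                guess = np.zeros(n)
            sol = np.atleast_1d(np.asarray(solver(residual, guess),
                                           dtype=float))
            if nla_state is not None:
                nla_state[block_index] = sol.copy()
            return sol

        return solve

    def new_nla_state(self) -> dict:
        """Per-session warm-start cache for NLA blocks (zeros on first use).
        """
        return {}

    # -- evaluators (pure) --------------------------------------------------
    def initialise_constants(self):
        constants = np.zeros(self.n_constants + self.n_computed)
        states = np.zeros(self.n_states)
        self._initialise(constants, states)
        return constants, states

    def compute_computed_constants(self, constants, nla_state=None):
        constants = np.array(constants, dtype=float)
        scratch = np.zeros(self.n_algebraic)
        self._computed(0.0, np.zeros(self.n_states),
                       np.zeros(self.n_states), constants, scratch,
                       self._nla_dispatch(nla_state))
        return constants

    def compute_rates(self, voi, states, constants, nla_state=None):
        rates = np.zeros(self.n_states)
        scratch = np.zeros(self.n_algebraic)
        self._rates(float(voi), np.asarray(states, dtype=float), rates,
                    np.asarray(constants, dtype=float), scratch,
                    self._nla_dispatch(nla_state))
        return rates

    def compute_algebraic(self, voi, states, rates, constants,
                          nla_state=None):
        algebraic = np.zeros(self.n_algebraic)
        self._algebraic(float(voi), np.asarray(states, dtype=float),
                        np.asarray(rates, dtype=float),
                        np.asarray(constants, dtype=float), algebraic,
                        self._nla_dispatch(nla_state))
        return algebraic

    def rate_function(self, constants, nla_state=None):
        """(t, y) -> dy/dt closure for the ODE solvers."""
        constants = np.asarray(constants, dtype=float)

        def f(t, y):
            return self.compute_rates(t, y, constants, nla_state=nla_state)

        return f


def build_runtime(model: CellMLModel, nla_solver=None) -> RuntimeModel:
    """Classify, order and compile a flattened model into a runtime."""
    return RuntimeModel(model, nla_solver=nla_solver)
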