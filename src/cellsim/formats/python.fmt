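# Source-export format description: Python
name: python
comment: #
indent: 4
index-base: 0
statement: {lhs} = {rhs}
voi: voi
states: states[{i}]
rates: rates[{i}]
constants: constants[{i}]
algebraic: algebraic[{i}]
identifier-case: keep
number-style: plain
max-line-length: 0
continuation:
file-header: import math
file-header:
function-open: def {name}(voi, states, rates, constants, algebraic):
function-empty: pass
function-close:
piecewise: ({then} if {cond} else {otherwise})
const.pi: math.pi
const.true: True
const.false: False
op.plus: infix +
op.minus: infix -
op.unary-minus: prefix -
op.times: infix *
op.divide: infix /
op.power: infix **
op.exp: call math.exp
op.ln: call math.log
op.abs: call abs
op.floor: call math.floor
op.ceiling: call math.ceil
op.sin: call math.sin
op.cos: call math.cos
op.tan: call math.tan
op.arcsin: call math.asin
op.arccos: call math.acos
op.arctan: call math.atan
op.and: infix and
op.or: infix or
op.not: prefix not
op.eq: infix ==
op.neq: infix !=
op.lt: infix <
op.leq: infix <=
op.gt: infix >
op.geq: infix >=
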