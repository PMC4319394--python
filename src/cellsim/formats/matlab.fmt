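# Source-export format description: MATLAB
name: matlab
comment: %
indent: 4
index-base: 1
statement: {lhs} = {rhs};
voi: voi
states: states({i})
rates: rates({i})
constants: constants({i})
algebraic: algebraic({i})
identifier-case: keep
number-style: plain
max-line-length: 0
continuation:
function-open: function [states, rates, constants, algebraic] = {name}(voi, states, rates, constants, algebraic)
function-empty: ;
function-close: end
function-close:
piecewise: ternary({cond}, {then}, {otherwise})
const.pi: pi
const.true: true
const.false: false
op.plus: infix +
op.minus: infix -
op.unary-minus: prefix -
op.times: infix *
op.divide: infix /
op.power: infix ^
op.exp: call exp
op.ln: call log
op.abs: call abs
op.floor: call floor
op.ceiling: call ceil
op.sin: call sin
op.cos: call cos
op.tan: call tan
op.arcsin: call asin
op.arccos: call acos
op.arctan: call atan
op.and: infix &&
op.or: infix ||
op.not: prefix ~
op.eq: infix ==
op.neq: infix ~=
op.lt: infix <
op.leq: infix <=
op.gt: infix >
op.geq: infix >=
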