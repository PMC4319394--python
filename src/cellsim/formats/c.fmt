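# Source-export format description: C
name: c
comment: //
indent: 4
index-base: 0
statement: {lhs} = {rhs};
voi: voi
states: states[{i}]
rates: rates[{i}]
constants: constants[{i}]
algebraic: algebraic[{i}]
identifier-case: keep
number-style: plain
max-line-length: 0
continuation:
file-header: #include <math.h>
file-header:
function-open: void {name}(double voi, double *states, double *rates, double *constants, double *algebraic)
function-open: {
function-empty: (void)voi;
function-close: }
function-close:
piecewise: ({cond} ? {then} : {otherwise})
const.pi: M_PI
const.true: 1
const.false: 0
op.plus: infix +
op.minus: infix -
op.unary-minus: prefix -
op.times: infix *
op.divide: infix /
op.power: call pow
op.exp: call exp
op.ln: call log
op.abs: call fabs
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
op.not: prefix !
op.eq: infix ==
op.neq: infix !=
op.lt: infix <
op.leq: infix <=
op.gt: infix >
op.geq: infix >=
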