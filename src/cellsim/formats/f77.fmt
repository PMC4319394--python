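# Source-export format description: FORTRAN 77 (fixed form, 72 columns)
name: f77
comment: C
indent: 6
index-base: 1
statement: {lhs} = {rhs}
voi: VOI
states: STATES({i})
rates: RATES({i})
constants: CONSTS({i})
algebraic: ALGBRC({i})
identifier-case: upper
number-style: fortran-d
max-line-length: 72
continuation:      &
function-open:       SUBROUTINE {name}(VOI, STATES, RATES, CONSTS, ALGBRC)
function-open:       DOUBLE PRECISION VOI
function-open:       DOUBLE PRECISION STATES(*), RATES(*)
function-open:       DOUBLE PRECISION CONSTS(*), ALGBRC(*)
function-empty: CONTINUE
function-close:       RETURN
function-close:       END
function-close:
piecewise: MERGE({then}, {otherwise}, {cond})
const.pi: 3.14159265358979312D0
const.true: .TRUE.
const.false: .FALSE.
op.plus: infix +
op.minus: infix -
op.unary-minus: prefix -
op.times: infix *
op.divide: infix /
op.power: infix **
op.exp: call DEXP
op.ln: call DLOG
op.abs: call DABS
op.floor: call DFLOOR
op.ceiling: call DCEIL
op.sin: call DSIN
op.cos: call DCOS
op.tan: call DTAN
op.arcsin: call DASIN
op.arccos: call DACOS
op.arctan: call DATAN
op.and: infix .AND.
op.or: infix .OR.
op.not: prefix .NOT.
op.eq: infix .EQ.
op.neq: infix .NE.
op.lt: infix .LT.
op.leq: infix .LE.
op.gt: infix .GT.
op.geq: infix .GE.
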