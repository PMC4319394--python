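# Methods

This note records the models, algorithms and numerical choices behind
`cellsim`, and what the bundled test models do and do not exercise.

## Document model and MathML subset

CellML 1.0 and 1.1 are distinguished strictly by their published namespace
URIs; no feature sniffing.  The content-MathML subset covers what ODE/DAE
cell models use: arithmetic (`plus`, `minus`, `times`, `divide`), `power`
and `root`, `exp`/`ln`/`log`, `abs`/`floor`/`ceiling`, trigonometric
functions and inverses, boolean and relational operators, `piecewise`,
first derivatives with one bound variable, numbers with mandatory units,
and `pi`/`true`/`false`.  Anything outside the subset is a hard diagnostic,
never silently dropped — a model that cannot be represented faithfully must
not simulate.  `cn` elements without a units attribute are an error by
default (strict reading of the "every quantity has units" rule); parsing in
lenient mode records the issue and continues so validation can report it
with a position.

Round-tripping is structural, not byte-level: whitespace and attribute
order are not preserved, but `parse(serialize(m)) == m` up to source
locations, and serialization is idempotent after the first pass.  Embedded
RDF/XML and foreign-namespace elements are captured verbatim and spliced
back untouched.  `reaction`, `group` and similar elements are preserved
opaquely and not interpreted; encapsulation therefore does not affect
connection semantics here.

Source positions: the XML parser reports lines; columns are recovered by
locating the element's opening tag in the source line.  Diagnostics use the
stable one-line form `severity:line:column: [code] message`.

## Units model

Each units name resolves to a vector of rational exponents over the seven
SI base dimensions plus a multiplier (and an offset for Celsius-style
units).  The full CellML built-in table is provided (`gram` = 10⁻³ kg,
`litre` = 10⁻³ m³, `radian` dimensionless, and so on); user definitions
expand recursively with cycle detection — a circular definition is an
error.  Booleans are a pseudo-dimension incompatible with every physical
dimension, which is what makes `piecewise` conditions checkable.

Dimensional rules: addition/comparison require equal exponent vectors;
multiplication/division add/subtract exponents and combine multipliers;
`power` requires a constant dimensionless exponent (otherwise the base must
be dimensionless, since the result is not statically determinable);
transcendental functions require and yield dimensionless; a derivative has
dim(state)/dim(VOI).  Dimensional inconsistencies are **warnings** — many
repository-grade models are dimensionally sloppy but dynamically fine, and
blocking simulation on them would make the tool useless; structural faults
remain errors.  Same dimension but different multiplier (litre vs m³) is a
separate, lower-priority warning code (`unit-scale-mismatch`), and values
cross connections unscaled — no automatic unit conversion is performed
anywhere.

A user `base_units="yes"` definition maps to dimensionless rather than to a
fresh incomparable dimension; tracking custom base dimensions was judged
not worth the complexity for the models this package targets.  This is a
known limitation.

## Flattening (1.1 → 1.0)

Imported units and components instantiate under their local names;
dependencies travel with them: units referenced by an imported component
(including inside `cn` attributes), and components connected to it in its
source document, are pulled in transitively (imports in the source document
are resolved recursively first).  One instantiation is reused per
(source document, remote name) pair.  Name collisions rename the later
arrival with numeric suffixes `_1`, `_2`, …, recorded in a rename log;
`cmeta:id` collisions rename the same way and the subjects of travelling
RDF annotations are rewritten consistently.  Initial values given by
variable reference (a 1.1 feature) are rewritten to the referenced literal,
so the output is plain 1.0 and flattening is byte-idempotent.  Documents
are fetched through a locator abstraction; the CLI binds it to the
filesystem relative to the importing file and refuses remote URLs (an
explicit flag admits `file://` only) — simulations should not depend on the
network.

## Classification and equation ordering

Connected variables are merged with union-find; the canonical site of a
group is the declaration carrying the initial value or the defining
equation (the `out`-interface declaration for the VOI).  Conflicting
initial values across a group are an error.  Categories follow the
dependency rule:

* **VOI** — the unique bound variable of all derivatives (two distinct
  bound variables is an error; a model with no derivative has no VOI and is
  rejected — at least one ODE is required).
* **state / rate** — a variable whose derivative is defined / that
  derivative.  States must carry initial values.
* **constant** — has an initial value and is never computed.
* **computed constant** — a computed variable whose transitive dependencies
  contain only constants and computed constants.
* **algebraic** — every other computed variable.

Equations with a bare variable or derivative on one side become
assignments; the rest are residuals.  A dependency graph over assignments
and residual groups is condensed by strongly connected components: any SCC
larger than one step, and every residual group, becomes an NLA block with
#equations = #unknowns enforced (violations are structural singularity
errors; a rate participating in an algebraic loop is rejected — the system
would not be semi-explicit).  The topological order of the condensation is
the executable plan.  Under the dependency rule an NLA block whose inputs
are all constants classifies its unknowns as computed constants and is
solved once per run; blocks touching states or the VOI are algebraic and
re-solved at every evaluation.

## Runtime and code generation

The equation plan is emitted as Python source and compiled once
(`exec`) — the native analogue of generating C and compiling it on the fly,
with no toolchain dependency.  Evaluators are pure: fresh output arrays,
inputs never mutated, bitwise-repeatable results.  Computed constants live
at the tail of the constants array so `compute_rates(voi, states,
constants)` sees them without extra plumbing.  `compute_rates` runs the
algebraic steps its rate expressions need into a scratch array;
`compute_algebraic` recomputes all algebraic variables for recording.

NLA blocks call the registered Newton solver through a dispatch that takes
the per-session warm-start cache: the first solve of a block starts from
zeros, later solves from the previous solution (continuity along a
trajectory).  The cache is owned by the simulation session, never the
runtime, so concurrent sessions cannot influence one another.

Source export is driven by flat `key: value` format files (statement shape,
comment syntax, array naming templates, index base, identifier casing,
number style, line wrapping, one rendering per operator, piecewise
template).  The shipped C/FORTRAN 77/MATLAB/Python formats are such files
inside the package — the user-defined path is the only path.  `root` and
`log`-with-base are lowered to `power` and `ln` before rendering, so format
files cover only the primitive operator set; a format missing a rendering
an exported model needs fails naming the operator.  FORTRAN output is
fixed-form with a 72-column limit and `&` continuation lines.  Exported
sources for models with NLA blocks carry the residual equations as
comments rather than an embedded solver; the Python export is enough to
cross-check all explicit evaluators against the native runtime.

## Solvers

Fixed-step: Forward Euler, Heun (trapezoidal predictor–corrector), RK2 as
the **midpoint** rule (chosen deliberately so the method list is not
redundant next to Heun — both are second order and coincide on linear
right-hand sides), and classic RK4.  The adaptive path delegates to LSODA
(automatic stiff/non-stiff switching) with dense output: the integrator
chooses its own steps and the trajectory is interpolated at the grid
points.  Defaults: reltol 10⁻⁷, abstol 10⁻¹², unbounded max step.  A
finite-time blow-up raises an integration error carrying the failing VOI
value rather than grinding or returning non-finite data (guarded at
|y| > 10¹⁵⁰).

DAE handling is deliberately modest: semi-explicit index-1 systems go
through backward Euler (first order) with Newton, or through the explicit
path with per-step NLA solving; no BDF multistep family is reimplemented.
The Newton solver uses a forward-difference Jacobian with perturbation
√ε·max(|xᵢ|, 1), damped by at most 10 step halvings, converging on the
residual infinity norm (default tolerance 10⁻¹²).  Jacobians are always
finite-difference; no symbolic differentiation.

Observed convergence orders on the decay fixture (E(h)/E(h/2) at t = 1,
h = 0.01) sit at ≈1 for Euler and backward Euler, ≈2 for Heun/RK2 and ≈4
for RK4 — the acceptance script recomputes these every run.

## Simulation contract

The grid is start + i·interval computed by index multiplication (no
accumulation drift); the final point equals `end` exactly when
(end − start)/interval is integral within 10⁻⁹ relative tolerance,
otherwise the grid stops at the last point ≤ end.  Every parameter is
always tracked; the projected capture size (8 bytes × series × points) is
checked against a 1 GiB default cap before integration starts.

Pause points snap to the nearest grid point at or after the request;
modifications (constants and states only — editing a computed quantity is a
category error) are applied before that point is recorded, so stored data
are always self-consistent.  Changing a constant refreshes the computed
constants, keeping derived quantities coherent.  Fixed-step solvers take
⌈interval/h⌉ equal substeps per grid interval when an internal step h is
configured, else one step per interval — making trajectories independent of
how a run is chunked, which is what lets interleaved sessions reproduce
sequential runs bitwise.

CSV export: comma-separated, `\n` endings, header
`component/name (units)` per column (VOI first, then parameters in
category-then-name order), values in 17-significant-digit scientific
notation so a read-back is bit-exact.  Identifier rules forbid commas, so
no quoting is needed.  Additional exporters register by name; the shipped
registry contains exactly `csv`.

## Annotation

Subjects are `document-locator#cmeta:id`; predicates come from the closed
biomodels.net qualifier vocabularies (13 biology terms, 5 model terms —
the full published lists); objects are `http://identifiers.org/…` URIs.
Annotating an element without a metadata id mints `id_<counter>` (zero
padded, collision-skipping, deterministic in document order).  MIRIAM URNs
in pre-existing files are converted to identifiers.org form on read and
flagged as deprecated; they are never written back.  The embedded RDF/XML
block is regenerated from the sorted triple set, so annotation output is
deterministic; a malformed block is reported with its position while the
model remains simulable.  Ontology term lookup against a remote service is
out of scope: terms pass through unvalidated.

## Test models

All inputs are generated programmatically (`cellsim.fixtures`), so the
package builds and tests offline:

* **decay** — dy/dt = −a·y with real second-based units; a = 1 s⁻¹,
  y₀ = 10; closed form 10·e^(−at) anchors every solver check.
* **fhn** — FitzHugh–Nagumo (v′ = v − v³/3 − w + I, w′ = ε(v + a) − εb·w)
  with the conventional ε = 0.08, a = 0.7, b = 0.8, I = 0.5, chosen over a
  full Hodgkin–Huxley transcription as the smallest nonlinear model that
  populates all six categories (εb is a computed constant, v − w an
  algebraic variable).  All quantities dimensionless, including the VOI.
* **nla_loop** — x + y = 3, x − y = 1 feeding dz/dt = x: exercises the NLA
  block path with the known solution (2, 1) and z = z₀ + 2t.
* **conservation** — y₁′ = −k·y₁, y₂′ = +k·y₁: the exactly conserved sum
  bounds solver drift.
* **import pair** — a CellML 1.1 composite (driver component + imported
  decaying component and units) equivalent to the decay model.
* **invalid suite** — eight documents, each constructed around exactly one
  defect with a marker for its line.

These fixtures are small and clean by construction.  Passing tests
demonstrate correctness of the machinery — parsing, classification,
ordering, integration, export — not robustness against the long tail of
real repository models (multi-component encapsulation hierarchies,
reactions, heavy piecewise gating, dimensionally sloppy units), which is
exactly the gap the warnings-not-errors units policy anticipates.

## Known limitations

* Encapsulation and `reaction` elements are preserved, not interpreted.
* No unit auto-conversion across connections or around number literals;
  scale mismatches are reported, values pass through unscaled.
* DAE support is semi-explicit index-1 only; backward Euler is the only
  implicit stepper.
* Exported C/FORTRAN/MATLAB source is for inspection and reuse, not
  compiled or executed by this package (the Python export is executed in
  tests).
* One VOI per model; at least one differential equation required.
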