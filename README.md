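# cellsim

A scriptable modeling environment for **CellML**-encoded cell models.
CellML is an XML exchange format used in computational physiology to encode
systems of ordinary differential equations (ODEs) and differential-algebraic
equations (DAEs): equations are content MathML, every quantity carries
physical units, and annotations are RDF triples embedded in the document.
`cellsim` is for modellers and tool builders who want the computational core
of a CellML environment — everything needed to go from a model file to
simulation data — as a plain Python library and CLI, with no GUI and no
compiler toolchain.

## What it does

* **Parse / serialize** CellML 1.0 and 1.1 (supported content-MathML subset,
  line/column tracking, verbatim preservation of RDF and foreign XML).
* **Validate** structure (duplicate names, dangling references, interface
  direction, over/under-defined variables) and physical units, by expanding
  every units definition to a vector of rational exponents over the seven SI
  base dimensions.  Dimensional inconsistencies are warnings; structural
  faults are errors.
* **Flatten** CellML 1.1 composites: imports are resolved transitively and
  an equivalent standalone CellML 1.0 document is emitted.
* **Build a runtime**: every variable is classified into one of six
  categories — variable of integration (VOI), constant, computed constant,
  state, rate, algebraic — equations are ordered topologically, and sets of
  equations with no sequential order become non-linear-algebraic (NLA)
  blocks solved simultaneously.  Evaluators are generated as native Python.
* **Simulate** over a uniform grid (start, end, point interval) with
  pluggable solvers: Forward Euler, Heun, midpoint and classic Runge–Kutta
  (RK2/RK4), an adaptive stiff-capable integrator, backward Euler for
  semi-explicit DAE handling, and a damped Newton NLA solver.  Runs can be
  paused, constants/states modified, and resumed.  Every parameter is
  captured at every grid point; the data store exports to CSV at full
  round-trip precision.
* **Annotate** any element (via its `cmeta:id`) with biomodels.net
  qualifiers and identifiers.org URIs; deprecated MIRIAM URNs are converted
  on read.
* **Export source code** in C, FORTRAN 77, MATLAB or Python — all driven by
  user-editable format-description files; the built-ins use the same
  mechanism users do.

For a one-state decay model the runtime takes the familiar form

    dy/dt = -a·y,    y(0) = y0,

and the general contract is: states `y` evolve under `dy/dt = f(t, y, c)`
with constants `c`, computed constants fixed per run, and algebraic
variables recomputed at every recorded point.

## Worked example

The bundled fixture generator writes ready-to-run models (no downloads):

```sh
cellsim fixtures --write models
cellsim validate models/decay.cellml          # exit 0, no output: clean
cellsim simulate models/decay.cellml \
    --to 10 --interval 0.1 \
    --solver rk4 --solver-prop step=0.01 \
    --out decay.csv
```

`decay.csv` has one header line and 101 rows (grid 0, 0.1, …, 10):

```
main/time (second),main/a (per_second),main/y (dimensionless),main/d(y)/d(time) (dimensionless/second)
0.00000000000000000e+00,1.00000000000000000e+00,1.00000000000000000e+01,-1.00000000000000000e+01
...
1.00000000000000000e+01,1.00000000000000000e+00,4.53999298006346828e-04,-4.53999298006346828e-04
```

Reading the last row: at t = 10 s the state is y ≈ 4.53999298·10⁻⁴,
against the closed form 10·e⁻¹⁰ = 4.53999297624…·10⁻⁴ — an absolute error
of ~4·10⁻¹³ from RK4 with an internal step of 0.01 s.  The rate column is
exactly −a·y at every recorded point, and the constant column stays at 1.

The same pipeline from Python:

```python
from cellsim import (parse_cellml, build_runtime, run_simulation,
                     SimulationSetup)
from cellsim.fixtures import make_decay

runtime = build_runtime(parse_cellml(make_decay()))
store = run_simulation(runtime, SimulationSetup(0.0, 10.0, 0.1,
                                                ode_solver="rk4",
                                                ode_properties={"step": 0.01}))
print(store.series("main/y")[-1])        # 0.0004539992980063468
```

Other entry points: `cellsim export --to cellml10` (flatten 1.1 → 1.0),
`cellsim export --to python|c|f77|matlab|<format-file>`,
`cellsim annotate` / `cellsim annotations`, `cellsim plugins` /
`cellsim status`, `cellsim solvers`.

## Layout

```
src/cellsim/
  document.py     CellML parsing/serialization     mathml.py   MathML AST
  validation.py   structure + units checking       units.py    SI dimensions
  flatten.py      1.1 imports -> standalone 1.0    report.py   full report
  analysis.py     classification + equation plan   runtime.py  evaluators
  codegen.py      source export (formats/*.fmt)    solvers.py  ODE/DAE/NLA
  simulation.py   grids, sessions, data store      annotation.py  RDF
  plugins.py      plugin registry                  cli.py      `cellsim`
  fixtures.py     programmatic test models
```

See `docs/methods.md` for the numerical and design details.
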