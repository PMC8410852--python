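# mat2c

A source-to-source compiler that translates ODE-centric models written in a
restricted MATLAB-compatible dialect into portable C99, together with a
reference interpreter (the semantic oracle) and a numerical-equivalence
harness, so that every translation can be validated end to end.

## Who this is for

Quantitative systems pharmacology (QSP) and systems-biology models are
routinely written as MATLAB scripts: a few hundred ODEs, parameter bags,
interpolation tables, and solver calls (`ode15s`, `ode45`). Simulating such
models inside calibration or sensitivity loops is slow in an interpreted
environment, and hand-porting them to C is error-prone precisely because
there is no automatic check that the port computes the same trajectories.
`mat2c` automates both halves of that problem: it compiles the model to
plain C99 (no external libraries needed — a stiff and a nonstiff adaptive
integrator are bundled as emitted source), and it certifies the translation
by comparing the compiled output against its own reference interpreter.

## The pipeline

1. **Front end** — tokenizes each `.m` file, parses it against the
   documented dialect subset, and links the entry script with the function
   files it calls into a *program graph* (a DAG of per-file syntax trees;
   file-level cycles are rejected).
2. **Middle end** — scope resolution (a function `g` defined inside `f` is
   callable only from `f`), then multi-pass fixpoint type/shape inference
   producing an *annotated tree*: every expression carries a base kind
   (real, logical, string, struct, function handle) and a shape (scalar,
   vector(n), matrix(r,c), or dynamic). Limited polymorphism is allowed
   (a 1×1 matrix is a scalar); operator/shape compatibility is checked —
   e.g. `/` between two 1-D vectors is rejected as undefined, while the
   elementwise `./` is accepted. The annotated tree can be rendered as DOT
   for inspection.
3. **Back end** — emits one `.c`/`.h` pair: inferred scalars become C
   `double`s, everything array-valued becomes a growable column-major
   matrix backed by a small bundled runtime (`m2c_rt.c`), 1-based
   subscripts are translated to 0-based accesses, and each
   `[t, y] = odeXX(...)` call is wired to a bundled adaptive integrator
   (TR-BDF2 for the stiff family, Cash–Karp RK45 for the nonstiff family).
   A comment quoting the source line is placed above every translated
   statement, and `line_map.json` records the emitted-line → source-line
   map. During integration, any state or derivative that becomes NaN/Inf
   halts the run and reports the offending variable(s) and the current
   time.

## The equivalence statistic

Two runs of the same model (interpreter vs compiled C, or any two
timeseries on a shared output grid) are compared with the floored relative
error

```
err(A, B) = |A − B| / (1e-6 + min(|A|, |B|))
```

averaged over all state variables at each time step. The `1e-6` floor
prevents the statistic from exploding when values are extremely small; the
verdict is *pass* when the maximum over steps of the per-step mean stays
below the tolerance (default `1e-3`, matching the default relative
precision of the ODE solvers).

## Worked example

Generate the exponential-decay model (`dy/dt = −k·y`, `k = 1`, `y0 = 1`
over `t ∈ [0, 5]`), translate it, run both sides, compare:

```
$ cat src/exp_decay.m
k = 1;
y0 = 1;
rhs = @(t, y) -k .* y;
[t, y] = ode45(rhs, [0 5], y0);
yend = y(end, 1);

$ mat2c translate --entry src/exp_decay.m --out build
$ mat2c run --entry src/exp_decay.m --out interp_out
$ gcc -std=c99 -O1 -o model build/*.c -lm
$ mkdir -p c_out && ./model c_out
$ mat2c compare interp_out/ts_0.csv c_out/ts_0.csv --tol 1e-3
PASS: max per-step mean error 8.189e-04 vs tolerance 0.001 (1 variables, 200 steps)
```

The interpreter's final environment (`interp_out/env.json`) reports
`yend = 0.0067392`, against the closed form `e^−5 = 0.0067379` — inside the
default `rtol·|y| + atol` band. The emitted C carries its provenance:

```c
/* src/exp_decay.m:4: [t, y] = ode45(rhs, [0 5], y0); */
```

Error cases exit with stable codes: a type error such as a vector-by-vector
`/` exits 4, a call to a nested function from outside its parent exits 5, a
missing file exits 2, a syntax error exits 3.

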