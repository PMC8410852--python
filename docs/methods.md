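# Methods

This note documents the models, numerical procedures and design choices
behind `mat2c`: what the compiler assumes about its input dialect, how the
numerical results it certifies are produced, and what the synthetic corpus
does and does not demonstrate about real models.

## The dialect subset

The supported input language is a restricted MATLAB-compatible dialect
aimed at the style ODE/QSP models are actually written in: scripts, single-
and multi-output functions, nested and file-local subfunctions, anonymous
function handles (needed for ODE right-hand sides), `if`/`elseif`/`else`,
`for`, `while`, `break`/`continue`/`return`, matrix literals (with the
whitespace element-splitting rule: `[1 -2]` is two elements, `[1 - 2]` is
one), colon ranges, `end` in subscripts, logical indexing, struct field
access, and single-quoted strings. Excluded: classes, cell arrays,
`try`/`catch`, `global`, and recursion across or within files (the program
graph is a DAG by construction; a file calling itself is rejected).
Function definitions are always terminated by `end`; this removes the
ambiguity between nested functions and undelimited subfunctions and is the
one place the dialect is stricter than its ancestor. Comments are `%` to
end of line. Statements end at newlines or `;`/`,`; `;` additionally
suppresses display, which is semantic-only here — the interpreter emulates
no output stream.

The grammar is implemented as a hand-written recursive-descent parser; the
tree-shape contract (node kinds, precedence, locations) is what the rest of
the pipeline depends on, not the parsing technology.

## Scope and type analysis

Name resolution follows the dialect's conventions: a local variable shadows
a function of the same name (which is also how the parser's `name(args)`
ambiguity is settled — index if `name` is a variable at that point, call
otherwise); a function nested in `f` is visible only inside `f`; a plain
read of a never-assigned variable is a use-before-definition error.

Types live on a lattice: `unknown` at the bottom, concrete base×shape
values above it, and the fully `dynamic` shape at the top. Inference
evaluates statement-by-statement against a per-point environment and
re-runs whole-program passes until no annotation changes; the lattice is
finite, every update is a join (monotone), and a hard cap of 50 passes
guarantees termination with an explicit failure listing unresolved symbols.
In practice the corpus converges in 2 passes. Control-flow merges join the
branch environments; a join of incompatible concrete shapes promotes to
`dynamic` with a warning rather than erroring, because the dialect permits
resizing at run time. Loop bodies are swept twice per pass so loop-carried
growth (`w(i) = ...` on an initially empty `w`) reaches its fixpoint.
User functions are typed on demand from their return-variable assignments,
memoized per argument signature, with at most 4 shape specializations per
function before widening to dynamic. Scalar/1×1-matrix interchange is free
by construction (a scalar *is* shape (1,1)); vector ↔ n×1/1×n coercions are
the only other polymorphism. Shape checking rejects the quotient `/`
between two 1-D vectors (its elementwise meaning is already taken by `./`)
and inner-dimension mismatches in `*`.

## Interpreter semantics

The reference interpreter is correctness-first and deliberately boring:
every numeric value is a 2-D column-major float64 array (scalars are 1×1),
assignment copies, indexing is 1-based with column-major linearization,
out-of-range *writes* grow the array zero-filled while out-of-range *reads*
raise, and truthiness is "nonempty and all nonzero". `rand`/`randn` use a
seeded PCG64 generator; bitwise agreement with any other environment is
explicitly not promised, so stochastic comparisons must be distributional
(mean ± SD band overlap over repeated runs, provided by
`numcompare.stochastic_bands_overlap`).

ODE calls integrate with scipy's IVP machinery: `ode15s` maps to BDF,
`ode45`/`ode23` to RK45, with results reported on a fixed output grid
(default 200 points across the span) and defaults rtol = 1e-3,
atol = 1e-6. Solver choice defaults to stiff when ambiguous, since the
models this tool targets usually are.

**Delivered-accuracy convention.** Error-per-step control alone lets the
global error overshoot the requested tolerance by a small factor (measured
≈2.7× on exponential decay at rtol 1e-3). Both the interpreter and the
emitted C integrators therefore drive their steppers at 0.1× the requested
tolerances, so "solve at rtol" means "delivered global error near rtol".
This is what the closed-form acceptance band `rtol·|y| + atol` presumes,
and it applies symmetrically to both sides of every comparison.

## Emitted C

Translation keeps the program's own variable structure — no static single
assignment is needed. Variables inferred as real/logical scalars become C
`double`s; everything array-valued or dynamic becomes a growable
column-major `m2c_mat` from the bundled runtime, with copy-on-assignment
preserving value semantics. Struct variables are flattened to one C
variable per field (`p.alpha` → `v_p__alpha`), which covers the
parameter-bag idiom; struct values never escape a scope. Function handles
have no first-class C value: every handle use is resolved statically to its
defining `@(...)` expression or `@name`, either inlined (direct calls) or
compiled to a dedicated right-hand-side function whose captured variables
travel in a context struct (ODE calls). Every translated statement is
preceded by a comment quoting its source line, and a machine-readable
emitted-line → source-line map is written beside the code. Emission is a
pure function of the annotated tree and options: identical inputs give
byte-identical text.

The bundled integrators are self-contained C99: adaptive Cash–Karp RK45
for the nonstiff family, and for the stiff family TR-BDF2 (γ = 2−√2,
L-stable) with damped Newton on a finite-difference Jacobian, partial-pivot
LU, and step-doubling (Richardson) error control. Both use cubic-Hermite
dense output onto the fixed grid and check every state and derivative for
NaN/Inf, halting with the offending variable indices and the current time
(exit code 7, parsed back into a diagnostic by the harness). Matrix
temporaries inside the right-hand side come from an arena that is reset
after every evaluation, so long integrations run in constant memory.
The `load` builtin reads whitespace-delimited numeric text only — the one
documented restriction on that function.

## The comparison statistic

`relative_error(A, B) = |A−B| / (1e-6 + min(|A|, |B|))`, symmetric and
nonnegative; timeseries are resampled to a shared grid by linear
interpolation, the error is averaged across variables per step, and the
verdict compares the maximum per-step mean against the tolerance (default
1e-3). The maximum single-entry error and all (variable, step) offenders
are reported for diagnosis. The floor makes the statistic insensitive to
noise in values ≪ 1e-6 but also means that a variable crossing zero turns
sub-tolerance absolute differences into O(1) relative ones — see the
corpus-design note below.

**Harness tolerances.** The interpreter and the compiled code use
*different* integration methods, so at rtol 1e-3 each side carries its own
~1e-3-scale discretization error and their disagreement would measure
solver difference, not translation fidelity. The equivalence harness
therefore integrates both sides at rtol 1e-5 / atol 1e-9 while judging
agreement at the 1e-3 tolerance; user-facing defaults are unchanged.

## The synthetic corpus

Fixtures are pure functions of (name, params, seed) and each declares how
it is accepted: a closed form, an invariant, a final-environment check, or
a diagnostic code. The ODE fixtures are chosen so trajectories stay
strictly positive — as concentrations do in the models this tool targets —
because the floored statistic is only meaningful away from zero: the
harmonic oscillator oscillates about the equilibrium (3, 3) (still the
harmonic oscillator, with its closed form and 2π periodicity), and the
random linear systems draw Metzler matrices (nonnegative off-diagonal,
strictly dominant negative diagonal), i.e. random positive compartment
systems with the sign structure of mass-transfer models. The Robertson
system uses the classical rate constants (0.04, 1e4, 3e7); its component
sum is a linear first integral that both BDF-family and Runge–Kutta
methods preserve to solver precision, giving a sharp conservation check,
and an explicit method on the same problem exhausts any reasonable
evaluation budget — the stiffness witness. Closed forms come from oracles
independent of any solver; the linear systems use a scaling-and-squaring
truncated-series matrix exponential cross-checked against an independent
implementation in the tests.

The benchmark objective fixtures (Rastrigin, Rosenbrock, Schwefel problem
1.2 — the sum-of-squared-partial-sums variant whose minimum is exactly 0 at
the origin — and the high-conditioned elliptic function) wrap each
objective in a fixed-iteration random-search driver whose
Park–Miller LCG is written *in the dialect itself*: every arithmetic step
is exact in IEEE doubles (the 2^45 intermediate is well under 2^53), so
interpreter and compiled C compute bit-identical streams and the optimizer
*loop* — not its convergence — is what the fixture exercises. Each driver
also evaluates its objective at the known global minimizer, where the
result must be exactly 0 in both environments.

What passing this corpus does **not** show: performance of the generated
code relative to any host environment (never measured here), correctness on
models using language features outside the documented subset, behavior of
`rand`-driven models beyond distributional agreement, and scaling to
hundreds of equations (the corpus is deliberately small so the full
round-trip suite runs in seconds; the generator's parametric `n` exists for
stress tests).

## Numerical details and degenerate inputs

Ranges replicate the dialect's counting rule `n = floor((stop−start)/step
+ ε) + 1` identically in Python and C, so loop trip counts agree exactly.
Empty matrices are 0×0; concatenation with an empty operand is the
identity; reductions of empty arrays return 0 (1 for products). `mod`
takes the sign of the divisor, `rem` the sign of the dividend. `interp1`
requires strictly monotone knots (descending input is flipped) and returns
NaN outside the knot range. Integer-valued subscripts are accepted within
1e-8 of an integer. Newton in TR-BDF2 retries with h/4 on non-convergence
and the step controller clamps growth to 4–5× per step; step-size
underflow aborts with the last successful time. The out-of-bound guard
checks states and derivatives at every evaluation, which localizes an
injected NaN to the first step that touches it.

## Known limitations

Two-subscript indexing only (no N-D arrays); no cell arrays, classes or
`try`/`catch`; `odeset` options beyond `RelTol`/`AbsTol` are ignored;
handles must be statically resolvable for the C backend (a handle chosen
at run time between two candidates cannot be compiled); strings are only
carriers for file names and labels; the emitted C frees no memory outside
the right-hand-side arena, which is harmless for model-simulation
workloads but makes the generated code unsuitable as a long-running
library. An R backend stub is deliberately absent from the acceptance
surface and from this release.
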