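"""Synthetic model corpus: deterministic dialect sources with known expected
behavior, exercising every compiler feature.

Each fixture is a pure function of ``(name, params, seed)`` and declares how
it is accepted: a closed-form solution evaluator, an invariant predicate, a
final-environment predicate, or a diagnostic code it must be rejected with.
The closed forms are computed by oracles independent of the ODE solver (the
linear-system fixture uses a scaling-and-squaring truncated-series matrix
exponential, not the integrator).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .runtime.values import Timeseries

_LCG_M = 2147483647  # Park-Miller modulus; exact in doubles on both targets
_LCG_A = 16807


@dataclass
class FixtureSpec:
    """One generated model: sources, auxiliary data files, expectations."""

    name: str
    params: Dict[str, object]
    seed: int
    sources: Dict[str, str]            # filename -> dialect source text
    entry: str                         # entry filename
    data_files: Dict[str, str] = field(default_factory=dict)
    expected: Dict[str, object] = field(default_factory=dict)
    # expected["kind"]: closed_form | invariant | env | diagnostic

    @property
    def is_executable(self) -> bool:
        return self.expected.get("kind") != "diagnostic"

    @property
    def has_ode(self) -> bool:
        return any("ode45(" in s or "ode15s(" in s or "ode23(" in s
                   for s in self.sources.values())

    def write(self, directory: str) -> str:
        """Write sources and data files; returns the entry path."""
        os.makedirs(directory, exist_ok=True)
        for fname, text in {**self.sources, **self.data_files}.items():
            with open(os.path.join(directory, fname), "w", encoding="utf-8") as fh:
                fh.write(text)
        import json
        with open(os.path.join(directory, "expected.json"), "w", encoding="utf-8") as fh:
            json.dump({"name": self.name, "params": {k: v for k, v in self.params.items()},
                       "seed": self.seed, "expected_kind": self.expected.get("kind")},
                      fh, indent=2)
        return os.path.join(directory, self.entry)


def _fmt(x: float) -> str:
    return f"{float(x):.17g}"


def _matrix_literal(a: np.ndarray) -> str:
    rows = ["  " + " ".join(_fmt(v) for v in row) for row in np.atleast_2d(a)]
    return "[\n" + "\n".join(rows) + "\n]"


# -- closed-form oracles ----------------------------------------------------

def series_expm(a: np.ndarray, tol: float = 1e-16, max_terms: int = 200) -> np.ndarray:
    """Matrix exponential by scaling-and-squaring of the truncated Taylor
    series — a brute-force oracle deliberately independent of any solver."""
    a = np.asarray(a, dtype=float)
    norm = np.linalg.norm(a, ord=np.inf)
    s = max(0, int(math.ceil(math.log2(norm))) + 1) if norm > 0 else 0
    b = a / (2 ** s)
    term = np.eye(a.shape[0])
    total = term.copy()
    for k in range(1, max_terms):
        term = term @ b / k
        total += term
        if np.linalg.norm(term, ord=np.inf) < tol * np.linalg.norm(total, ord=np.inf):
            break
    for _ in range(s):
        total = total @ total
    return total


def _lcg_stream(seed: int, count: int) -> List[float]:
    """The same multiplicative LCG the benchmark sources implement inline."""
    state = float(seed)
    out = []
    for _ in range(count):
        state = math.fmod(state * _LCG_A, _LCG_M)
        out.append(state / _LCG_M)
    return out


# -- generators -------------------------------------------------------------

def _exp_decay(params, seed):
    k = params.get("k", 1.0)
    y0 = params.get("y0", 1.0)
    tf = params.get("tf", 5.0)
    src = (
        f"k = {_fmt(k)};\n"
        f"y0 = {_fmt(y0)};\n"
        "rhs = @(t, y) -k .* y;\n"
        f"[t, y] = ode45(rhs, [0 {_fmt(tf)}], y0);\n"
        "yend = y(end, 1);\n"
    )
    return {"exp_decay.m": src}, "exp_decay.m", {
        "kind": "closed_form", "n_vars": 1, "t_span": (0.0, tf),
        "solution": lambda t: (y0 * np.exp(-k * np.asarray(t))).reshape(-1, 1)}


def _logistic(params, seed):
    r = params.get("r", 1.0)
    K = params.get("K", 1.0)
    y0 = params.get("y0", 0.1)
    tf = params.get("tf", 8.0)
    src = (
        f"r = {_fmt(r)};\n"
        f"K = {_fmt(K)};\n"
        f"y0 = {_fmt(y0)};\n"
        "rhs = @(t, y) r .* y .* (1 - y / K);\n"
        f"[t, y] = ode45(rhs, [0 {_fmt(tf)}], y0);\n"
        "yend = y(end, 1);\n"
    )

    def sol(t):
        t = np.asarray(t, dtype=float)
        return (K / (1 + (K - y0) / y0 * np.exp(-r * t))).reshape(-1, 1)

    return {"logistic.m": src}, "logistic.m", {
        "kind": "closed_form", "n_vars": 1, "t_span": (0.0, tf), "solution": sol}


def _harmonic_oscillator(params, seed):
    # unit-frequency oscillation around the positive equilibrium (3, 3):
    # states stay bounded away from zero, as concentrations do, so the
    # floored relative-error statistic is meaningful at every step.  The
    # right-hand side lives in its own function file referenced by @name.
    a = params.get("a", 1.0)
    tf = params.get("tf", 2 * math.pi)
    rhs_src = (
        "function dy = hosc_rhs(t, y)\n"
        "  dy = [y(2) - 3; -(y(1) - 3)];\n"
        "end\n"
    )
    src = (
        f"a = {_fmt(a)};\n"
        f"[t, y] = ode45(@hosc_rhs, [0 {_fmt(tf)}], [3 + a; 3]);\n"
        "y1end = y(end, 1);\n"
        "y2end = y(end, 2);\n"
    )

    def sol(t):
        t = np.asarray(t, dtype=float)
        return np.column_stack([3 + a * np.cos(t), 3 - a * np.sin(t)])

    return ({"harmonic_oscillator.m": src, "hosc_rhs.m": rhs_src},
            "harmonic_oscillator.m", {
                "kind": "closed_form", "n_vars": 2, "t_span": (0.0, tf),
                "solution": sol})


def _robertson_stiff(params, seed):
    tf = params.get("tf", 1e4)
    # the classical stiff reaction rates
    src = (
        "k1 = 0.04;\n"
        "k2 = 1e4;\n"
        "k3 = 3e7;\n"
        "rhs = @(t, y) [-k1 * y(1) + k2 * y(2) * y(3); "
        "k1 * y(1) - k2 * y(2) * y(3) - k3 * y(2) ^ 2; "
        "k3 * y(2) ^ 2];\n"
        f"[t, y] = ode15s(rhs, [0 {_fmt(tf)}], [1; 0; 0]);\n"
        "mass = sum(y(end, :));\n"
    )
    return {"robertson_stiff.m": src}, "robertson_stiff.m", {
        "kind": "invariant", "n_vars": 3, "t_span": (0.0, tf),
        "invariant": "component_sum", "value": 1.0, "tolerance": 1e-5}


def _linear_ode_system(params, seed):
    # random positive linear (compartment-style) system: Metzler matrix with
    # strictly dominant negative diagonal keeps trajectories positive and
    # decaying, matching the sign structure of mass-transfer QSP models
    n = int(params.get("n", 3))
    tf = params.get("tf", 1.0)
    rng = np.random.Generator(np.random.PCG64(seed))
    A = rng.uniform(0.0, 1.0, size=(n, n))
    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(A, -(A.sum(axis=1) + 1.0))
    y0 = rng.uniform(0.5, 1.5, size=n)
    src = (
        f"A = {_matrix_literal(A)};\n"
        f"y0 = {_matrix_literal(y0.reshape(-1, 1))};\n"
        "rhs = @(t, y) A * y;\n"
        f"[t, y] = ode15s(rhs, [0 {_fmt(tf)}], y0);\n"
        "yend = y(end, :);\n"
    )

    def sol(t):
        t = np.asarray(t, dtype=float).reshape(-1)
        return np.stack([series_expm(A * ti) @ y0 for ti in t])

    return {f"linear_ode_system_{n}.m": src}, f"linear_ode_system_{n}.m", {
        "kind": "closed_form", "n_vars": n, "t_span": (0.0, tf), "solution": sol,
        "matrix": A, "y0": y0}


def _interp1_script(params, seed):
    src = (
        "x = [0 1 2 3];\n"
        "y = [0 2 1 5];\n"
        "xi = 0:0.25:3;\n"
        "yi = interp1(x, y, xi);\n"
        "s = sum(yi);\n"
        "mid = interp1(x, y, 0.5);\n"
    )
    return {"interp1_script.m": src}, "interp1_script.m", {
        "kind": "env", "check": {"mid": 1.0}}


def _setdiff_union(params, seed):
    src = (
        "a = [3 1 4 1 5];\n"
        "b = [1 5 9];\n"
        "d = setdiff(a, b);\n"
        "u = union(a, b);\n"
        "nd = length(d);\n"
        "nu = length(u);\n"
    )
    return {"setdiff_union.m": src}, "setdiff_union.m", {
        "kind": "env", "check": {"nd": 2.0, "nu": 5.0}}


def _load_script(params, seed):
    rng = np.random.Generator(np.random.PCG64(seed))
    mat = rng.integers(1, 10, size=(3, 4)).astype(float)
    data = "\n".join(" ".join(_fmt(v) for v in row) for row in mat) + "\n"
    src = (
        "A = load('fixture_data.txt');\n"
        "r = size(A, 1);\n"
        "c = size(A, 2);\n"
        "total = sum(sum(A));\n"
    )
    return {"load_script.m": src}, "load_script.m", {
        "kind": "env",
        "check": {"r": 3.0, "c": 4.0, "total": float(mat.sum())},
        "data": {"fixture_data.txt": data}}


_OBJECTIVES = {
    "rastrigin": (
        "function f = rastrigin(x)\n"
        "  n = length(x);\n"
        "  f = 10 * n + sum(x .^ 2 - 10 * cos(2 * pi * x));\n"
        "end\n",
        "zeros(1, n)"),
    "rosenbrock": (
        "function f = rosenbrock(x)\n"
        "  f = 0;\n"
        "  for i = 1:(length(x) - 1)\n"
        "    f = f + 100 * (x(i + 1) - x(i) ^ 2) ^ 2 + (1 - x(i)) ^ 2;\n"
        "  end\n"
        "end\n",
        "ones(1, n)"),
    "schwefel": (
        # Schwefel problem 1.2: sum of squared partial sums, minimum 0 at 0
        "function f = schwefel(x)\n"
        "  f = 0;\n"
        "  for i = 1:length(x)\n"
        "    s = sum(x(1:i));\n"
        "    f = f + s ^ 2;\n"
        "  end\n"
        "end\n",
        "zeros(1, n)"),
    "elliptic": (
        "function f = elliptic(x)\n"
        "  n = length(x);\n"
        "  f = 0;\n"
        "  for i = 1:n\n"
        "    f = f + 1e6 ^ ((i - 1) / (n - 1)) * x(i) ^ 2;\n"
        "  end\n"
        "end\n",
        "zeros(1, n)"),
}


def _benchmark(objective: str):
    def gen(params, seed):
        n = int(params.get("n", 4))
        iters = int(params.get("iters", 40))
        fn_src, x0_expr = _OBJECTIVES[objective]
        lcg_seed = (seed % (_LCG_M - 2)) + 1  # LCG state must stay in [1, M-1]
        driver = (
            f"n = {n};\n"
            f"state = {lcg_seed};\n"
            "best = 1e30;\n"
            "xbest = zeros(1, n);\n"
            f"for trial = 1:{iters}\n"
            "  x = zeros(1, n);\n"
            "  for j = 1:n\n"
            f"    state = mod(state * {_LCG_A}, {_LCG_M});\n"
            f"    x(j) = (state / {_LCG_M}) * 8 - 4;\n"
            "  end\n"
            f"  f = {objective}(x);\n"
            "  if f < best\n"
            "    best = f;\n"
            "    xbest = x;\n"
            "  end\n"
            "end\n"
            f"x0 = {x0_expr};\n"
            f"fmin = {objective}(x0);\n"
        )
        return ({f"bench_{objective}.m": driver, f"{objective}.m": fn_src},
                f"bench_{objective}.m",
                {"kind": "env", "check": {"fmin": 0.0}, "exact": ["fmin"]})
    return gen


def _feature_tour(params, seed):
    src = (
        "% broad tour of the supported construct set\n"
        "v = linspace(0, 1, 5);\n"
        "n = length(v);\n"
        "m = numel(v);\n"
        "A = zeros(2, 3);\n"
        "for i = 1:2\n"
        "  for j = 1:3\n"
        "    A(i, j) = i * 10 + j;\n"
        "  end\n"
        "end\n"
        "B = A';\n"
        "r = size(A, 1);\n"
        "c = size(A, 2);\n"
        "total = sum(sum(A));\n"
        "mx = max(v);\n"
        "mn = min(v);\n"
        "clipped = max(v, 0.25);\n"
        "s = 0;\n"
        "k = 0;\n"
        "while 1\n"
        "  k = k + 1;\n"
        "  if k > 10\n"
        "    break\n"
        "  end\n"
        "  if mod(k, 2) == 0\n"
        "    continue\n"
        "  end\n"
        "  s = s + k;\n"
        "end\n"
        "u = [1 -4 9 -16];\n"
        "w = abs(u);\n"
        "mask = u > 0;\n"
        "pos = u(mask);\n"
        "q = sqrt(w) + exp(0) - log(1);\n"
        "t5 = v(end);\n"
        "subv = v(2:end);\n"
        "p.alpha = 2.5;\n"
        "p.beta = -1;\n"
        "combo = p.alpha * s + p.beta;\n"
        "flag = (s > 0) && (total > 0 || k < 0);\n"
        "neg = ~flag;\n"
        "z = floor(2.7) + mod(7, 3);\n"
        "d = u ./ w;\n"
        "e = u .* u;\n"
        "g = u .^ 2;\n"
        "h = 2 ^ 3;\n"
        "rng2 = 10:-2:4;\n"
        "first = rng2(1);\n"
        "msg = 'feature tour';\n"
    )
    return {"feature_tour.m": src}, "feature_tour.m", {
        "kind": "env",
        "check": {"s": 25.0, "total": 72.0, "t5": 1.0, "combo": 61.5,
                  "h": 8.0, "first": 10.0, "z": 3.0},
        "exact": ["s", "total", "h", "first", "z"]}


def _guard_nan(params, seed):
    src = (
        "rhs = @(t, y) 0 .* y + sqrt(1 - t);\n"
        "[t, y] = ode45(rhs, [0 2], 0);\n"
    )
    return {"guard_nan.m": src}, "guard_nan.m", {
        "kind": "diagnostic", "stage": "runtime", "code": "E_OUT_OF_BOUNDS"}


def _vector_quotient(params, seed):
    src = "a = [1 2 3];\nb = [4 5 6];\nc = a / b;\n"
    return {"vector_quotient.m": src}, "vector_quotient.m", {
        "kind": "diagnostic", "stage": "sema", "code": "E_VECTOR_QUOTIENT"}


def _pointwise_quotient(params, seed):
    src = "a = [1 2 3];\nb = [4 5 6];\nc = a ./ b;\ncs = sum(c);\n"
    return {"pointwise_quotient.m": src}, "pointwise_quotient.m", {
        "kind": "env", "check": {"cs": 1.0 / 4 + 2.0 / 5 + 3.0 / 6}}


_NESTED_F = (
    "function y = f(x)\n"
    "  function z = g(u)\n"
    "    z = u * 2;\n"
    "  end\n"
    "  y = g(x) + 1;\n"
    "end\n"
)


def _nested_scope_call(params, seed):
    entry = "r = f(2);\nq = g(3);\n"
    return ({"nested_scope_call.m": entry, "f.m": _NESTED_F},
            "nested_scope_call.m",
            {"kind": "diagnostic", "stage": "sema", "code": "E_SCOPE_CALL"})


def _nested_scope_ok(params, seed):
    entry = "r = f(2);\n"
    return ({"nested_scope_ok.m": entry, "f.m": _NESTED_F},
            "nested_scope_ok.m",
            {"kind": "env", "check": {"r": 5.0}, "exact": ["r"]})


_GENERATORS = {
    "exp_decay": _exp_decay,
    "logistic": _logistic,
    "harmonic_oscillator": _harmonic_oscillator,
    "robertson_stiff": _robertson_stiff,
    "linear_ode_system": _linear_ode_system,
    "interp1_script": _interp1_script,
    "setdiff_union": _setdiff_union,
    "load_script": _load_script,
    "rastrigin": _benchmark("rastrigin"),
    "rosenbrock": _benchmark("rosenbrock"),
    "schwefel": _benchmark("schwefel"),
    "elliptic": _benchmark("elliptic"),
    "feature_tour": _feature_tour,
    "guard_nan": _guard_nan,
    "vector_quotient": _vector_quotient,
    "pointwise_quotient": _pointwise_quotient,
    "nested_scope_call": _nested_scope_call,
    "nested_scope_ok": _nested_scope_ok,
}

BENCHMARK_OBJECTIVES = ("rastrigin", "rosenbrock", "schwefel", "elliptic")

#: fixtures expected to run end to end (interpreter and compiled C)
EXECUTABLE_FIXTURES = (
    "exp_decay", "logistic", "harmonic_oscillator", "robertson_stiff",
    "linear_ode_system", "interp1_script", "setdiff_union", "load_script",
    "rastrigin", "rosenbrock", "schwefel", "elliptic", "feature_tour",
    "pointwise_quotient", "nested_scope_ok",
)

ERROR_FIXTURES = ("vector_quotient", "nested_scope_call", "guard_nan")


def list_fixtures() -> List[str]:
    """Names of every fixture in the corpus."""
    return sorted(_GENERATORS)


def generate_fixture(name: str, params: Optional[Dict[str, object]] = None,
                     seed: int = 0) -> FixtureSpec:
    """Deterministically generate one fixture from (name, params, seed)."""
    if name not in _GENERATORS:
        raise KeyError(f"unknown fixture {name!r}; known: {', '.join(list_fixtures())}")
    params = dict(params or {})
    sources, entry, expected = _GENERATORS[name](params, seed)
    data = expected.pop("data", {})
    return FixtureSpec(name=name, params=params, seed=seed, sources=sources,
                       entry=entry, data_files=data, expected=expected)


def closed_form_eval(spec: FixtureSpec, grid) -> Timeseries:
    """Analytic solution of a closed-form fixture on ``grid``."""
    if spec.expected.get("kind") != "closed_form":
        raise ValueError(f"fixture {spec.name!r} has no closed form")
    grid = np.asarray(grid, dtype=float).reshape(-1)
    states = np.asarray(spec.expected["solution"](grid), dtype=float)
    if states.ndim == 1:
        states = states.reshape(-1, 1)
    names = [f"y{i + 1}" for i in range(states.shape[1])]
    return Timeseries(times=grid, states=states, names=names)
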