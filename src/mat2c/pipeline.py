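"""End-to-end helpers: build, analyze, interpret, translate, compile, compare.

These are the high-level operations the CLI, the test suite and the
acceptance script all share, so every consumer exercises exactly the same
code paths.
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Tuple

import numpy as np

from .codegen import (CodegenOptions, compile_units, emit_c, find_compiler,
                      run_compiled, write_units)
from .diagnostics import CompileError
from .fixtures import FixtureSpec
from .frontend import build_program_from_path, ProgramGraph
from .numcompare import (ComparisonReport, compare_environments,
                         compare_timeseries)
from .runtime import RunOptions, Timeseries, evaluate
from .sema import AnnotatedTree, analyze


def analyze_path(entry_path: str, search_paths=()) -> Tuple[ProgramGraph, AnnotatedTree]:
    program = build_program_from_path(entry_path, search_paths)
    tree = analyze(program)
    return program, tree


def interpret_fixture(spec: FixtureSpec, workdir: str,
                      options: Optional[RunOptions] = None
                      ) -> Tuple[Dict[str, object], List[Timeseries]]:
    entry = spec.write(workdir)
    program, tree = analyze_path(entry)
    if tree.errors:
        raise CompileError(tree.errors)
    return evaluate(program, options or RunOptions())


def translate_fixture(spec: FixtureSpec, workdir: str,
                      opts: Optional[CodegenOptions] = None) -> str:
    """Write, analyze and emit a fixture; returns the build directory."""
    entry = spec.write(workdir)
    program, tree = analyze_path(entry)
    if tree.errors:
        raise CompileError(tree.errors)
    units = emit_c(tree, opts or CodegenOptions())
    build_dir = os.path.join(workdir, "build")
    write_units(units, build_dir)
    return build_dir


def run_fixture_compiled(spec: FixtureSpec, workdir: str,
                         opts: Optional[CodegenOptions] = None,
                         seed: int = 0
                         ) -> Tuple[Dict[str, np.ndarray], List[Timeseries]]:
    build_dir = translate_fixture(spec, workdir, opts)
    exe = compile_units(build_dir)
    outdir = os.path.join(workdir, "out_c")
    return run_compiled(exe, outdir, workdir=workdir, seed=seed)


def flatten_environment(env: Dict[str, object]) -> Dict[str, np.ndarray]:
    """Numeric view of an interpreter environment: arrays/scalars kept,
    struct fields exposed under dotted names, everything else dropped."""
    out: Dict[str, np.ndarray] = {}
    for name, v in env.items():
        if isinstance(v, dict):
            for f, fv in v.items():
                if isinstance(fv, np.ndarray):
                    out[f"{name}.{f}"] = np.asarray(fv, dtype=float)
            continue
        if isinstance(v, np.ndarray):
            out[name] = np.asarray(v, dtype=float)
    return out


#: integration settings for translation-equivalence runs.  Interpreter and
#: compiled code use different ODE methods, so both integrate well below the
#: equivalence tolerance; otherwise the comparison would measure solver
#: disagreement instead of translation fidelity.
EQUIVALENCE_RUN = RunOptions(rtol=1e-5, atol=1e-9)


def roundtrip_reports(spec: FixtureSpec, workdir: str,
                      options: Optional[RunOptions] = None,
                      opts: Optional[CodegenOptions] = None,
                      tolerance: float = 1e-3) -> List[ComparisonReport]:
    """Interpreter vs compiled-C comparison: one report per ODE timeseries,
    plus one for the final environments."""
    options = options or EQUIVALENCE_RUN
    opts = opts or CodegenOptions(rtol=options.rtol, atol=options.atol,
                                  grid_points=options.grid_points)
    env_i, ts_i = interpret_fixture(spec, workdir, options)
    env_c, ts_c = run_fixture_compiled(spec, workdir, opts, seed=options.seed)
    reports: List[ComparisonReport] = []
    if len(ts_i) != len(ts_c):
        raise ValueError(f"{spec.name}: interpreter produced {len(ts_i)} "
                         f"timeseries, compiled produced {len(ts_c)}")
    for a, b in zip(ts_i, ts_c):
        b = Timeseries(times=a.times, states=b.states, names=b.names)
        reports.append(compare_timeseries(a, b, tolerance))
    flat_i = flatten_environment(env_i)
    common = sorted(set(flat_i) & set(env_c))
    if common:
        reports.append(compare_environments(flat_i, env_c, tolerance, names=common))
    return reports


def toolchain_available() -> bool:
    return find_compiler() is not None
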