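"""Compile-and-run harness for emitted C (used by tests and the CLI).

Locates a C toolchain, builds the emitted model against the bundled
runtime, executes it, and reads back the final environment (``env.csv``)
and any timeseries (``ts_*.csv``) in the same containers the interpreter
produces, so both sides feed :mod:`mat2c.numcompare` directly.
"""

from __future__ import annotations

import glob
import os
import shutil
import subprocess
from typing import Dict, List, Optional, Tuple

import numpy as np

from ..diagnostics import (E_OUT_OF_BOUNDS, E_RUNTIME, MatRuntimeError, error)
from ..runtime.values import Timeseries


def find_compiler() -> Optional[str]:
    for cand in ("cc", "gcc", "clang"):
        path = shutil.which(cand)
        if path:
            return path
    return None


def compile_units(build_dir: str, compiler: Optional[str] = None) -> str:
    """Compile ``<model>.c`` + ``m2c_rt.c`` in ``build_dir``; returns the
    executable path."""
    compiler = compiler or find_compiler()
    if compiler is None:
        raise RuntimeError("no C toolchain available")
    sources = sorted(glob.glob(os.path.join(build_dir, "*.c")))
    exe = os.path.join(build_dir, "model_exe")
    cmd = [compiler, "-std=c99", "-O1", "-o", exe] + sources + ["-lm"]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(f"C compilation failed:\n{proc.stderr}")
    return exe


def run_compiled(exe: str, outdir: str, workdir: Optional[str] = None,
                 seed: int = 0, timeout: float = 120.0
                 ) -> Tuple[Dict[str, np.ndarray], List[Timeseries]]:
    """Run the compiled model; returns (environment, timeseries list).

    Exit code 7 (the out-of-bound guard) raises with the variable/time
    report from stderr; other nonzero exits raise a runtime error.
    """
    os.makedirs(outdir, exist_ok=True)
    for old in glob.glob(os.path.join(outdir, "ts_*.csv")):
        os.remove(old)
    proc = subprocess.run([exe, os.path.abspath(outdir), str(seed)],
                          cwd=workdir or os.path.dirname(exe),
                          capture_output=True, text=True, timeout=timeout)
    if proc.returncode == 7:
        raise MatRuntimeError(error(E_OUT_OF_BOUNDS, proc.stderr.strip()))
    if proc.returncode != 0:
        raise MatRuntimeError(error(
            E_RUNTIME,
            f"compiled model exited with {proc.returncode}: {proc.stderr.strip()}"))
    env = read_env_csv(os.path.join(outdir, "env.csv"))
    series = []
    for i in range(1000):
        p = os.path.join(outdir, f"ts_{i}.csv")
        if not os.path.isfile(p):
            break
        series.append(Timeseries.from_csv(p))
    return env, series


def read_env_csv(path: str) -> Dict[str, np.ndarray]:
    """name,rows,cols,values... (column-major) -> dict of 2-D arrays."""
    env: Dict[str, np.ndarray] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln:
                continue
            parts = ln.split(",")
            name, r, c = parts[0], int(parts[1]), int(parts[2])
            vals = np.array([float(x) for x in parts[3:]], dtype=float)
            env[name] = vals.reshape((r, c), order="F") if r * c else \
                np.zeros((r, c))
    return env
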