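"""Translation-equivalence statistics.

Two runs of the same model (reference interpreter vs compiled translation,
or any two environments) are compared with the floored relative error

    err(A, B) = |A - B| / (1e-6 + min(|A|, |B|))

evaluated per variable and per time step on a shared output grid, then
averaged across variables at each step.  The 1e-6 floor keeps the statistic
from exploding when values are extremely small; it is far below the default
relative tolerance of 1e-3 against which the verdict is taken.  The mean
across variables is the verdict statistic; the maximum is reported alongside
for diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .runtime.values import Timeseries

ERROR_FLOOR = 1e-6
DEFAULT_TOLERANCE = 1e-3


def relative_error(a, b):
    """Floored relative error; symmetric, nonnegative, elementwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("relative_error requires finite inputs "
                         "(non-finite values are handled by the out-of-bound guard)")
    out = np.abs(a - b) / (ERROR_FLOOR + np.minimum(np.abs(a), np.abs(b)))
    return float(out) if out.ndim == 0 else out


def resample_to_grid(ts: Timeseries, grid) -> Timeseries:
    """Linear interpolation of every variable onto ``grid`` (exact at
    coincident times); the grid must lie within the series' time range."""
    grid = np.asarray(grid, dtype=float).reshape(-1)
    t = ts.times
    if grid.size and (grid.min() < t[0] - 1e-12 or grid.max() > t[-1] + 1e-12):
        raise ValueError(
            f"grid [{grid.min():g}, {grid.max():g}] outside series range "
            f"[{t[0]:g}, {t[-1]:g}]")
    states = np.column_stack([np.interp(grid, t, ts.states[:, j])
                              for j in range(ts.states.shape[1])]) \
        if ts.states.shape[1] else np.empty((grid.size, 0))
    return Timeseries(times=grid, states=states, names=list(ts.names))


@dataclass
class ComparisonReport:
    """Per-step mean floored relative error across variables plus verdict."""

    per_step_mean_error: np.ndarray
    max_error: float
    n_vars: int
    tolerance: float
    verdict: str                         # "pass" | "fail"
    offenders: List[Tuple[str, int]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"

    @property
    def max_mean_error(self) -> float:
        return float(np.max(self.per_step_mean_error)) \
            if self.per_step_mean_error.size else 0.0

    def to_json(self) -> str:
        return json.dumps({
            "verdict": self.verdict,
            "tolerance": self.tolerance,
            "n_vars": self.n_vars,
            "max_mean_error": self.max_mean_error,
            "max_error": self.max_error,
            "per_step_mean_error": [float(x) for x in self.per_step_mean_error],
            "offenders": [{"variable": v, "step": s} for v, s in self.offenders],
        }, indent=2)

    def one_line(self) -> str:
        return (f"{self.verdict.upper()}: max per-step mean error "
                f"{self.max_mean_error:.3e} vs tolerance {self.tolerance:g} "
                f"({self.n_vars} variables, {self.per_step_mean_error.size} steps)")


def compare_timeseries(a: Timeseries, b: Timeseries,
                       tolerance: float = DEFAULT_TOLERANCE) -> ComparisonReport:
    """Compare two series on a shared grid.

    Per step, the relative error is averaged over all variables; the verdict
    is pass iff the maximum over steps of that mean is below ``tolerance``.
    Individual (variable, step) pairs above tolerance are listed as
    offenders.
    """
    if list(a.names) != list(b.names):
        raise ValueError(f"variable names differ: {a.names} vs {b.names}")
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times,
                                                         rtol=0, atol=1e-9):
        raise ValueError("time grids differ; resample_to_grid both series first")
    err = relative_error(a.states, b.states)        # (n_steps, n_vars)
    per_step = err.mean(axis=1) if err.shape[1] else np.zeros(a.n_steps)
    max_err = float(err.max()) if err.size else 0.0
    offenders = [(a.names[j], int(i)) for i, j in zip(*np.nonzero(err > tolerance))]
    verdict = "pass" if (per_step.size == 0 or per_step.max() < tolerance) else "fail"
    return ComparisonReport(per_step_mean_error=per_step, max_error=max_err,
                            n_vars=len(a.names), tolerance=tolerance,
                            verdict=verdict, offenders=offenders)


def compare_environments(a: dict, b: dict, tolerance: float = DEFAULT_TOLERANCE,
                         names=None) -> ComparisonReport:
    """Compare two final-variable environments (numeric entries only) with
    the same statistic, treating the environment as a single 'step'."""
    import numpy as _np
    keys = names if names is not None else sorted(
        k for k in a if k in b and _looks_numeric(a[k]) and _looks_numeric(b[k]))
    errs, offenders = [], []
    for k in keys:
        va = _np.asarray(a[k], dtype=float).reshape(-1)
        vb = _np.asarray(b[k], dtype=float).reshape(-1)
        if va.shape != vb.shape:
            raise ValueError(f"variable {k!r} has different shapes: "
                             f"{va.shape} vs {vb.shape}")
        e = float(_np.max(relative_error(va, vb))) if va.size else 0.0
        errs.append(e)
        if e > tolerance:
            offenders.append((k, 0))
    per_step = _np.array([_np.mean(errs)]) if errs else _np.zeros(1)
    verdict = "pass" if per_step.max() < tolerance else "fail"
    return ComparisonReport(per_step_mean_error=per_step,
                            max_error=float(max(errs)) if errs else 0.0,
                            n_vars=len(keys), tolerance=tolerance,
                            verdict=verdict, offenders=offenders)


def _looks_numeric(v) -> bool:
    try:
        np.asarray(v, dtype=float)
        return True
    except (TypeError, ValueError):
        return False


def stochastic_bands_overlap(runs_a, runs_b, n_sd: float = 2.0) -> bool:
    """Stochastic-model acceptance: mean +/- n_sd * SD bands of matched
    summary variables over repeated runs must overlap at every timepoint."""
    a = np.asarray(runs_a, dtype=float)
    b = np.asarray(runs_b, dtype=float)
    ma, sa = a.mean(axis=0), a.std(axis=0, ddof=1)
    mb, sb = b.mean(axis=0), b.std(axis=0, ddof=1)
    lo_a, hi_a = ma - n_sd * sa, ma + n_sd * sa
    lo_b, hi_b = mb - n_sd * sb, mb + n_sd * sb
    return bool(np.all((lo_a <= hi_b) & (lo_b <= hi_a)))
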