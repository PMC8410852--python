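"""ODE solving and the out-of-bound guard used by interpreter and tests.

Stiff problems run a BDF-family method, nonstiff an explicit adaptive
Runge-Kutta, both through scipy's IVP machinery with dense output onto a
fixed grid.  When guarding is on, every accepted output state is screened
for NaN/Inf; the first offending step halts the run with a report naming
the variables out of bounds and the current time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from ..diagnostics import (Diagnostic, E_OUT_OF_BOUNDS, E_RUNTIME,
                           MatRuntimeError, error)
from .values import Timeseries

#: internal tolerance scaling: the stepper is driven below the requested
#: tolerance so the *global* error lands near the requested band
TOL_SAFETY = 0.1


@dataclass
class OdeProblem:
    rhs: Callable[[float, np.ndarray], np.ndarray]
    y0: np.ndarray
    t_span: tuple
    rtol: float = 1e-3
    atol: float = 1e-6
    family: str = "stiff"          # "stiff" -> BDF, "nonstiff" -> RK45
    names: Optional[List[str]] = None

    def __post_init__(self):
        self.y0 = np.asarray(self.y0, dtype=float).reshape(-1)
        t0, tf = self.t_span
        if not t0 < tf:
            raise ValueError("t_span must satisfy t0 < tf")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("rtol and atol must be positive")
        if self.family not in ("stiff", "nonstiff"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.names is None:
            self.names = [f"y{i + 1}" for i in range(self.y0.size)]


def detect_out_of_bounds(state: Sequence[float], t: float,
                         names: Sequence[str]) -> Optional[Diagnostic]:
    """NaN/Inf screen for one accepted step; None when all components are
    finite, else a diagnostic naming every offending variable and ``t``."""
    a = np.asarray(state, dtype=float)
    bad = np.flatnonzero(~np.isfinite(a))
    if bad.size == 0:
        return None
    parts = []
    for i in bad:
        label = names[i] if i < len(names) else f"y{i + 1}"
        kind = "NaN" if np.isnan(a[i]) else "Inf"
        parts.append(f"{label}={kind}")
    return error(E_OUT_OF_BOUNDS,
                 f"out-of-bound variable(s) at t={t:g}: {', '.join(parts)}")


def solve_ode(problem: OdeProblem, output_grid: np.ndarray,
              guard: bool = True) -> Timeseries:
    """Integrate onto a fixed output grid (dense output between steps)."""
    grid = np.asarray(output_grid, dtype=float).reshape(-1)
    t0, tf = problem.t_span
    if grid[0] < t0 - 1e-12 or grid[-1] > tf + 1e-12:
        raise ValueError("output grid must lie within t_span")
    method = "BDF" if problem.family == "stiff" else "RK45"

    class _Halt(Exception):
        def __init__(self, diag):
            self.diag = diag

    def rhs(t, y):
        if guard:
            diag = detect_out_of_bounds(y, float(t), problem.names)
            if diag is not None:
                raise _Halt(diag)
        dy = np.asarray(problem.rhs(t, y), dtype=float).reshape(-1)
        if guard:
            diag = detect_out_of_bounds(dy, float(t), problem.names)
            if diag is not None:
                raise _Halt(diag)
        return dy

    # error-per-step control typically lets global error overshoot the
    # requested tolerance by a small factor; an internal safety factor keeps
    # the delivered accuracy near the tolerance the caller asked for
    try:
        sol = solve_ivp(rhs, (t0, tf), problem.y0, method=method, t_eval=grid,
                        rtol=TOL_SAFETY * problem.rtol,
                        atol=TOL_SAFETY * problem.atol, dense_output=False)
    except _Halt as halt:
        raise MatRuntimeError(halt.diag) from None
    states = sol.y.T if sol.y.size else np.empty((0, problem.y0.size))
    if guard:
        for i in range(states.shape[0]):
            diag = detect_out_of_bounds(states[i], float(sol.t[i]), problem.names)
            if diag is not None:
                raise MatRuntimeError(diag)
    if not sol.success:
        raise MatRuntimeError(error(
            E_RUNTIME,
            f"integrator failure: {sol.message} "
            f"(last successful time t={sol.t[-1] if sol.t.size else t0:g})"))
    return Timeseries(times=sol.t, states=states, names=list(problem.names))
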