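"""Dynamic value model of the dialect and the Timeseries container.

All numeric values are 2-D, column-major, float64 (logicals: bool) arrays —
a scalar is a 1x1 matrix, exactly the polymorphism the dialect grants.
Assignment has value semantics (arrays are copied), 1-based indexing is
linear column-major in the one-subscript form, writing past the end grows
an array zero-filled, and reading past the end is an error.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from ..diagnostics import (E_RUNTIME, MatRuntimeError, SourceLocation, error)


def as_matrix(v) -> np.ndarray:
    """Coerce a scalar/sequence/array to the canonical 2-D Fortran-order array."""
    if isinstance(v, np.ndarray):
        a = v
    else:
        a = np.asarray(v, dtype=float)
    if a.dtype == bool:
        a = a.astype(bool)
    else:
        a = a.astype(float, copy=False)
    if a.ndim == 0:
        a = a.reshape(1, 1)
    elif a.ndim == 1:
        a = a.reshape(1, -1)  # bare sequences read as row vectors
    elif a.ndim > 2:
        raise MatRuntimeError(error(E_RUNTIME, "arrays of rank > 2 are unsupported"))
    return np.asfortranarray(a)


def is_numeric(v) -> bool:
    return isinstance(v, np.ndarray)


def to_scalar(v, loc: Optional[SourceLocation] = None) -> float:
    a = as_matrix(v)
    if a.size != 1:
        raise MatRuntimeError(error(
            E_RUNTIME, f"expected a scalar, got shape {a.shape}", loc))
    return float(a.flat[0])


def truthy(v) -> bool:
    """Dialect truth: nonempty and all elements nonzero."""
    a = as_matrix(v)
    return a.size > 0 and bool(np.all(a != 0))


@dataclass
class MFunction:
    """A function value: named user function, anonymous closure, or builtin."""

    kind: str                      # "named" | "anonymous" | "builtin"
    name: str = "<anonymous>"
    node: Optional[object] = None  # function_def or anonymous_function Node
    closure: Optional[Dict[str, object]] = None
    fn: Optional[Callable] = None  # builtin implementation

    def __repr__(self):
        return f"@{self.name}"


@dataclass
class Timeseries:
    """Output grid x state matrix with variable labels."""

    times: np.ndarray              # (n,) strictly increasing
    states: np.ndarray             # (n, n_vars)
    names: List[str]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim == 1:
            self.states = self.states.reshape(-1, 1)
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("states rows must align with times")
        if len(self.names) != self.states.shape[1]:
            raise ValueError("one name per state column required")

    @property
    def n_steps(self) -> int:
        return self.times.shape[0]

    def to_csv(self, path_or_buf) -> None:
        close = False
        if isinstance(path_or_buf, (str, bytes)):
            fh = open(path_or_buf, "w", encoding="utf-8")
            close = True
        else:
            fh = path_or_buf
        try:
            fh.write("t," + ",".join(self.names) + "\n")
            for i in range(self.n_steps):
                row = [repr(float(self.times[i]))]
                row += [repr(float(x)) for x in self.states[i]]
                fh.write(",".join(row) + "\n")
        finally:
            if close:
                fh.close()

    @classmethod
    def from_csv(cls, path_or_buf) -> "Timeseries":
        if isinstance(path_or_buf, (str, bytes)):
            with open(path_or_buf, "r", encoding="utf-8") as fh:
                text = fh.read()
        else:
            text = path_or_buf.read()
        lines = [ln for ln in text.strip().split("\n") if ln]
        header = lines[0].split(",")
        if header[0] != "t":
            raise ValueError("timeseries CSV must start with a 't' column")
        data = np.loadtxt(io.StringIO("\n".join(lines[1:])), delimiter=",", ndmin=2)
        return cls(times=data[:, 0], states=data[:, 1:], names=header[1:])


@dataclass
class RunOptions:
    """Interpreter/integration options shared across the pipeline."""

    rtol: float = 1e-3
    atol: float = 1e-6
    grid_points: int = 200
    seed: int = 0
    guard_out_of_bounds: bool = True
    load_dirs: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("rtol and atol must be positive")
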