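"""Builtin function library of the dialect, shared by interpreter and tests.

Semantics follow the source dialect: column-major linearization, 1-based
indices, ``sum``/``min``/``max`` reducing vectors to scalars and matrices
column-wise, ``interp1`` returning NaN outside the knot range, ``mod``
taking the sign of the divisor.  The complex builtins (``interp1``,
``setdiff``, ``union``, ``load``) are exposed as module-level functions so
the equivalence tests can exercise them directly.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np

from ..diagnostics import E_IO, E_RUNTIME, MatRuntimeError, error
from .values import as_matrix, to_scalar


def builtin_interp1(x, y, xq):
    """Piecewise-linear interpolation; queries outside [min x, max x] -> NaN."""
    xa = as_matrix(x).reshape(-1, order="F").astype(float)
    ya = as_matrix(y).reshape(-1, order="F").astype(float)
    if xa.size != ya.size:
        raise MatRuntimeError(error(E_RUNTIME, "interp1: x and y lengths differ"))
    d = np.diff(xa)
    if xa.size < 2 or not (np.all(d > 0) or np.all(d < 0)):
        raise MatRuntimeError(error(E_RUNTIME, "interp1: x must be strictly monotone"))
    if np.all(d < 0):
        xa, ya = xa[::-1], ya[::-1]
    q = as_matrix(xq)
    flat = q.reshape(-1, order="F").astype(float)
    out = np.interp(flat, xa, ya)
    out[(flat < xa[0]) | (flat > xa[-1])] = np.nan
    return as_matrix(out.reshape(q.shape, order="F"))


def builtin_setdiff(a, b):
    """Sorted unique elements of ``a`` not present in ``b`` (row vector)."""
    av = as_matrix(a).reshape(-1, order="F")
    bv = as_matrix(b).reshape(-1, order="F")
    return as_matrix(np.setdiff1d(av, bv).reshape(1, -1))


def builtin_union(a, b):
    """Sorted unique elements of the union of ``a`` and ``b`` (row vector)."""
    av = as_matrix(a).reshape(-1, order="F")
    bv = as_matrix(b).reshape(-1, order="F")
    return as_matrix(np.union1d(av, bv).reshape(1, -1))


def builtin_load(path: str, search_dirs: Sequence[str] = ()):
    """Whitespace-delimited numeric text file -> matrix (row/column layout
    preserved).  Ragged rows are a format error."""
    candidates = [path] + [os.path.join(d, path) for d in search_dirs]
    found: Optional[str] = next((p for p in candidates if os.path.isfile(p)), None)
    if found is None:
        raise MatRuntimeError(error(E_IO, f"load: file not found: {path}"))
    rows = []
    with open(found, "r", encoding="utf-8") as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln:
                continue
            try:
                rows.append([float(tok) for tok in ln.split()])
            except ValueError:
                raise MatRuntimeError(error(
                    E_IO, f"load: non-numeric data in {path}: {ln!r}")) from None
    if not rows:
        raise MatRuntimeError(error(E_IO, f"load: empty file: {path}"))
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise MatRuntimeError(error(E_IO, f"load: ragged rows in {path}"))
    return as_matrix(np.array(rows, dtype=float))


# -- reductions and elementwise wrappers -----------------------------------

def _reduce(a, fn):
    """Vector -> scalar; matrix -> row vector of column reductions."""
    m = as_matrix(a)
    if m.size == 0:
        return as_matrix(0.0)
    if 1 in m.shape:
        return as_matrix(fn(m.reshape(-1)))
    return as_matrix(fn(m, axis=0).reshape(1, -1))


def mat_sum(a):
    return _reduce(a, np.sum)


def mat_prod(a):
    return _reduce(a, np.prod)


def mat_min(a, b=None):
    if b is None:
        return _reduce(a, np.min)
    return as_matrix(np.minimum(as_matrix(a), as_matrix(b)))


def mat_max(a, b=None):
    if b is None:
        return _reduce(a, np.max)
    return as_matrix(np.maximum(as_matrix(a), as_matrix(b)))


def mat_size(a, dim=None):
    m = as_matrix(a)
    if dim is None:
        return as_matrix([[float(m.shape[0]), float(m.shape[1])]])
    d = int(to_scalar(dim))
    if d not in (1, 2):
        raise MatRuntimeError(error(E_RUNTIME, f"size: bad dimension {d}"))
    return as_matrix(float(m.shape[d - 1]))


def mat_length(a):
    m = as_matrix(a)
    return as_matrix(0.0 if m.size == 0 else float(max(m.shape)))


def mat_linspace(a, b, n=100):
    return as_matrix(np.linspace(to_scalar(a), to_scalar(b),
                                 int(to_scalar(n))).reshape(1, -1))


def mat_norm(a):
    return as_matrix(float(np.linalg.norm(as_matrix(a).reshape(-1))))


def mat_unique(a):
    return as_matrix(np.unique(as_matrix(a).reshape(-1, order="F")).reshape(1, -1))


def mat_sort(a):
    m = as_matrix(a)
    if 1 in m.shape:
        return as_matrix(np.sort(m.reshape(-1, order="F")).reshape(m.shape))
    return as_matrix(np.sort(m, axis=0))


def mat_find(a):
    m = as_matrix(a)
    idx = np.flatnonzero(m.reshape(-1, order="F") != 0) + 1.0
    if m.shape[0] == 1 and m.shape[1] > 1:
        return as_matrix(idx.reshape(1, -1))
    return as_matrix(idx.reshape(-1, 1))


def mat_repmat(a, r, c):
    return as_matrix(np.tile(as_matrix(a), (int(to_scalar(r)), int(to_scalar(c)))))
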