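"""Type lattice for the middle end.

A type is a base kind plus a shape.  Shapes are ``(rows, cols)`` pairs where
a dimension is an ``int`` when statically known and ``None`` when dynamic; a
fully unknown shape (rank/orientation not determined) is the distinguished
``DYNAMIC`` shape.  The lattice is ordered by information content:

    unknown  ⊑  concrete base with dynamic shape  ⊑  concrete shape

with ``scalar = matrix(1,1)`` by construction, so the 1x1-matrix/scalar
polymorphism the dialect permits is a non-event here.  Joining two types
with incompatible bases is a type error, never silently ``unknown``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple


class Base(Enum):
    REAL = "real"
    LOGICAL = "logical"
    STRING = "string"
    STRUCT = "struct"
    FUNC_HANDLE = "function_handle"
    UNKNOWN = "unknown"


_DYN = ("dyn",)  # sentinel for fully dynamic shape


@dataclass(frozen=True)
class Shape:
    """(rows, cols) with None for a dynamic dimension; or fully dynamic."""

    rows: Optional[int] = 1
    cols: Optional[int] = 1
    dynamic: bool = False  # rank/orientation unknown

    @staticmethod
    def scalar() -> "Shape":
        return Shape(1, 1)

    @staticmethod
    def vector(n: Optional[int], column: bool = True) -> "Shape":
        return Shape(n, 1) if column else Shape(1, n)

    @staticmethod
    def matrix(r: Optional[int], c: Optional[int]) -> "Shape":
        return Shape(r, c)

    @staticmethod
    def dyn() -> "Shape":
        return Shape(None, None, dynamic=True)

    @property
    def is_scalar(self) -> bool:
        return not self.dynamic and self.rows == 1 and self.cols == 1

    @property
    def is_vector(self) -> bool:
        if self.dynamic or self.is_scalar:
            return False
        return self.rows == 1 or self.cols == 1

    @property
    def maybe_scalar(self) -> bool:
        """True when a scalar value is not excluded by this shape."""
        if self.dynamic:
            return True
        return (self.rows in (1, None)) and (self.cols in (1, None))

    @property
    def known(self) -> bool:
        return not self.dynamic and self.rows is not None and self.cols is not None

    def numel(self) -> Optional[int]:
        if self.known:
            return self.rows * self.cols
        return None

    def transposed(self) -> "Shape":
        if self.dynamic:
            return self
        return Shape(self.cols, self.rows)

    def __str__(self) -> str:
        if self.dynamic:
            return "dynamic"
        if self.is_scalar:
            return "scalar"
        r = "?" if self.rows is None else str(self.rows)
        c = "?" if self.cols is None else str(self.cols)
        if self.cols == 1:
            return f"vector({r})"
        if self.rows == 1:
            return f"rowvec({c})"
        return f"matrix({r},{c})"


@dataclass(frozen=True)
class Type:
    base: Base
    shape: Shape = Shape.scalar()

    @property
    def is_unknown(self) -> bool:
        return self.base is Base.UNKNOWN

    @property
    def is_numeric(self) -> bool:
        return self.base in (Base.REAL, Base.LOGICAL)

    def __str__(self) -> str:
        if self.is_unknown:
            return "unknown"
        if self.base in (Base.STRING, Base.STRUCT, Base.FUNC_HANDLE):
            return self.base.value
        return f"{self.base.value} {self.shape}"


UNKNOWN = Type(Base.UNKNOWN)
REAL_SCALAR = Type(Base.REAL)
LOGICAL_SCALAR = Type(Base.LOGICAL)
STRING = Type(Base.STRING)
STRUCT = Type(Base.STRUCT)
FUNC_HANDLE = Type(Base.FUNC_HANDLE)


def real(shape: Shape) -> Type:
    return Type(Base.REAL, shape)


class BaseConflict(Exception):
    def __init__(self, a: Type, b: Type):
        self.a, self.b = a, b
        super().__init__(f"cannot unify {a} with {b}")


def _join_dim(a: Optional[int], b: Optional[int]) -> Optional[int]:
    if a == b:
        return a
    return None


def join_shape(a: Shape, b: Shape) -> Tuple[Shape, bool]:
    """Join two shapes; second element is True when concrete shapes
    conflicted and the result was promoted to dynamic (merge warning)."""
    if a == b:
        return a, False
    if a.dynamic or b.dynamic:
        return Shape.dyn(), False
    # compatible orientations: join dimension-wise
    if (a.rows == b.rows and a.rows is not None) or \
            (a.cols == b.cols and a.cols is not None) or \
            a.rows is None or b.rows is None or a.cols is None or b.cols is None:
        return Shape(_join_dim(a.rows, b.rows), _join_dim(a.cols, b.cols)), False
    if a.is_scalar or b.is_scalar:
        return Shape.dyn(), True
    if a.transposed() == b:  # row vs column vector of the same length
        return Shape.dyn(), True
    return Shape.dyn(), True


def join(a: Type, b: Type) -> Tuple[Type, bool]:
    """Lattice join; raises :class:`BaseConflict` on incompatible bases.
    LOGICAL joined with REAL widens to REAL (logicals are 0/1 numerics)."""
    if a.is_unknown:
        return b, False
    if b.is_unknown:
        return a, False
    if a.base is not b.base:
        bases = {a.base, b.base}
        if bases == {Base.REAL, Base.LOGICAL}:
            s, warned = join_shape(a.shape, b.shape)
            return Type(Base.REAL, s), warned
        raise BaseConflict(a, b)
    if a.base in (Base.STRING, Base.STRUCT, Base.FUNC_HANDLE):
        return a, False
    s, warned = join_shape(a.shape, b.shape)
    return Type(a.base, s), warned


def le(a: Type, b: Type) -> bool:
    """Partial order: a ⊑ b (b is at least as informative/above a)."""
    if a.is_unknown:
        return True
    if b.is_unknown:
        return False
    try:
        j, _ = join(a, b)
    except BaseConflict:
        return False
    return j == b
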