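"""Diagnostics: structured errors and warnings with stable codes and source locations.

Every user-facing failure in the pipeline (lexical, syntactic, scope, type,
runtime) is expressed as a :class:`Diagnostic` with a short machine tag that
stays stable across releases, so tests and downstream tooling can match on
codes rather than message text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Optional


class Severity(Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class SourceLocation:
    """1-based line/column position inside a named source unit."""

    unit: str
    line: int
    column: int

    def __str__(self) -> str:
        return f"{self.unit}:{self.line}:{self.column}"


# Stable diagnostic codes.
E_LEX = "E_LEX"                          # illegal character / unterminated string
E_SYNTAX = "E_SYNTAX"                    # parse error
E_MISSING_UNIT = "E_MISSING_UNIT"        # unresolved function file
E_CYCLIC_UNITS = "E_CYCLIC_UNITS"        # cyclic file dependency
E_UNDEFINED = "E_UNDEFINED"              # use before definition
E_SCOPE_CALL = "E_SCOPE_CALL"            # nested function called outside its parent
E_VECTOR_QUOTIENT = "E_VECTOR_QUOTIENT"  # v / v between 1-D vectors
E_SHAPE = "E_SHAPE"                      # incompatible operand shapes
E_BASE_CONFLICT = "E_BASE_CONFLICT"      # join of incompatible base kinds
E_NO_FIXPOINT = "E_NO_FIXPOINT"          # inference did not converge in pass cap
E_UNKNOWN_BUILTIN = "E_UNKNOWN_BUILTIN"  # builtin not in the codegen table
E_UNSUPPORTED = "E_UNSUPPORTED"          # construct outside the documented subset
E_RUNTIME = "E_RUNTIME"                  # interpreter runtime error
E_OUT_OF_BOUNDS = "E_OUT_OF_BOUNDS"      # NaN/Inf state during integration
E_IO = "E_IO"                            # missing file, unreadable input
W_SHAPE_MERGE = "W_SHAPE_MERGE"          # control-flow merge promoted to dynamic


@dataclass
class Diagnostic:
    severity: Severity
    code: str
    message: str
    loc: Optional[SourceLocation] = None

    def __str__(self) -> str:
        where = f" at {self.loc}" if self.loc else ""
        return f"{self.severity.value}[{self.code}]{where}: {self.message}"

    def to_json(self) -> dict:
        d = {"severity": self.severity.value, "code": self.code, "message": self.message}
        if self.loc:
            d["loc"] = {"unit": self.loc.unit, "line": self.loc.line, "column": self.loc.column}
        return d


def error(code: str, message: str, loc: Optional[SourceLocation] = None) -> Diagnostic:
    return Diagnostic(Severity.ERROR, code, message, loc)


def warning(code: str, message: str, loc: Optional[SourceLocation] = None) -> Diagnostic:
    return Diagnostic(Severity.WARNING, code, message, loc)


class CompileError(Exception):
    """Raised when a pipeline stage cannot proceed; carries its diagnostics."""

    def __init__(self, diagnostics):
        if isinstance(diagnostics, Diagnostic):
            diagnostics = [diagnostics]
        self.diagnostics = list(diagnostics)
        super().__init__("; ".join(str(d) for d in self.diagnostics))

    @property
    def first(self) -> Diagnostic:
        return self.diagnostics[0]


class MatRuntimeError(CompileError):
    """Runtime error raised by the reference interpreter."""


def render_json(diags) -> str:
    return json.dumps([d.to_json() for d in diags], indent=2)
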