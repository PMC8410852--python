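"""Syntax tree node definitions shared by the parser, analyses and backends."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional

from ..diagnostics import SourceLocation

# Node kinds.  The tree is deliberately small: one flexible node class with a
# `kind` tag, ordered children and a handful of payload slots (name/value/op),
# which keeps pattern matching in the analyses simple.
KINDS = {
    "script", "function_def", "assignment", "if", "elseif_branch", "else_branch",
    "for", "while", "break", "continue", "return", "call", "index", "range",
    "binary_op", "unary_op", "transpose", "matrix_literal", "matrix_row",
    "number", "string", "identifier", "anonymous_function", "func_handle",
    "field_access", "end_marker", "colon_all", "block", "expr_stmt",
}


@dataclass
class Node:
    kind: str
    children: List["Node"] = field(default_factory=list)
    loc: Optional[SourceLocation] = None
    # payload slots (used depending on kind)
    name: Optional[str] = None      # identifier / field / function name
    value: Optional[object] = None  # number or string literal value
    op: Optional[str] = None        # operator lexeme
    params: Optional[List[str]] = None   # function_def / anonymous_function inputs
    outs: Optional[List[str]] = None     # function_def outputs
    subfunctions: Optional[List["Node"]] = None  # nested defs owned by a function_def

    def __post_init__(self):
        assert self.kind in KINDS, self.kind

    def iter_nodes(self):
        """Pre-order traversal of this subtree, including nested functions."""
        yield self
        for c in self.children:
            yield from c.iter_nodes()
        if self.subfunctions:
            for f in self.subfunctions:
                yield from f.iter_nodes()

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        for slot in ("name", "value", "op", "params", "outs"):
            v = getattr(self, slot)
            if v is not None:
                d[slot] = v
        if self.loc:
            d["loc"] = [self.loc.line, self.loc.column]
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        if self.subfunctions:
            d["subfunctions"] = [f.to_dict() for f in self.subfunctions]
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def structurally_equal(self, other: "Node") -> bool:
        """Equality on kind, payload and children; locations are ignored."""
        if self.kind != other.kind:
            return False
        for slot in ("name", "value", "op", "params", "outs"):
            if getattr(self, slot) != getattr(other, slot):
                return False
        mine = self.subfunctions or []
        theirs = other.subfunctions or []
        if len(self.children) != len(other.children) or len(mine) != len(theirs):
            return False
        return all(a.structurally_equal(b) for a, b in zip(self.children, other.children)) and \
            all(a.structurally_equal(b) for a, b in zip(mine, theirs))
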