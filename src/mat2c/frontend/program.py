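"""Program graph: resolve cross-file function references into a DAG of ASTs.

A build starts from one entry script.  Every name that is used as a function
but not defined in the using unit is resolved, in order, against (1) the
unit's own subfunctions, (2) ``<name>.m`` on the search paths, (3) the
builtin table.  File-level cycles (including a file calling itself) violate
the DAG invariant and are rejected.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from ..diagnostics import (CompileError, E_CYCLIC_UNITS, E_IO, E_MISSING_UNIT,
                           SourceLocation, error)
from .astnodes import Node
from .lexer import SourceUnit
from .parser import parse_source

#: names resolvable without a function file (kept in sync with the runtime
#: and codegen builtin tables via a coverage test)
BUILTIN_NAMES = frozenset({
    "zeros", "ones", "eye", "size", "length", "numel", "abs", "min", "max",
    "sum", "prod", "exp", "log", "log10", "sqrt", "mod", "rem", "floor",
    "ceil", "round", "sin", "cos", "tan", "pi", "linspace", "interp1",
    "setdiff", "union", "unique", "sort", "load", "disp", "fprintf",
    "ode45", "ode23", "ode15s", "odeset", "rand", "randn", "isempty",
    "any", "all", "norm", "dot", "repmat", "find",
})


@dataclass
class ProgramGraph:
    units: Dict[str, Node]
    entry: str
    call_edges: Set[Tuple[str, str]] = field(default_factory=set)
    sources: Dict[str, SourceUnit] = field(default_factory=dict)

    @property
    def entry_node(self) -> Node:
        return self.units[self.entry]


def _function_uses(root: Node) -> List[Tuple[Node, bool]]:
    """(node, call_position) pairs for identifiers that may name a function:
    call-position bases and handles (call_position=True, must resolve) plus
    bare identifier reads (call_position=False, may be variables; unresolved
    ones are left for scope analysis).  Assignment targets are excluded."""
    assigned: Set[str] = set()
    uses: List[Tuple[Node, bool]] = []

    def walk(n: Node, in_lhs: bool = False):
        if n.kind == "assignment":
            lhs, rhs = n.children
            walk(rhs)
            if lhs.kind == "identifier":
                assigned.add(lhs.name)
            elif lhs.kind == "matrix_literal":
                for el in lhs.children[0].children:
                    if el.kind == "identifier":
                        assigned.add(el.name)
                    else:
                        walk(el, in_lhs=True)
            else:
                walk(lhs, in_lhs=True)
            return
        if n.kind == "for":
            assigned.add(n.name)
        if n.kind == "call":
            base = n.children[0]
            if base.kind == "identifier":
                uses.append((base, True))
                for a in n.children[1:]:
                    walk(a)
                return
        if n.kind == "identifier" and not in_lhs:
            uses.append((n, False))
        if n.kind == "func_handle":
            uses.append((n, True))
        if n.kind == "index" and in_lhs:
            # indexed write: base is a variable, subscripts are reads
            for a in n.children[1:]:
                walk(a)
            return
        if n.kind == "call" and in_lhs:
            if n.children[0].kind == "identifier":
                assigned.add(n.children[0].name)
            for a in n.children[1:]:
                walk(a)
            return
        for c in n.children:
            walk(c)
        for f in n.subfunctions or []:
            walk(f)

    walk(root)
    anon_params: Set[str] = set()
    for n in root.iter_nodes():
        if n.kind in ("anonymous_function", "function_def") and n.params:
            anon_params.update(n.params)
        if n.kind == "function_def" and n.outs:
            anon_params.update(n.outs)
    return [(u, c) for u, c in uses
            if u.name not in assigned and u.name not in anon_params]


def _local_function_names(root: Node) -> Set[str]:
    names = set()
    for n in root.iter_nodes():
        if n.kind == "function_def":
            names.add(n.name)
            for f in n.subfunctions or []:
                names.add(f.name)
    return names


def _find_unit(name: str, search_paths: Sequence[str]) -> Optional[str]:
    for d in search_paths:
        p = os.path.join(d, name + ".m")
        if os.path.isfile(p):
            return p
    return None


def build_program(entry: SourceUnit, search_paths: Sequence[str] = ()) -> ProgramGraph:
    """Parse the entry unit and transitively resolve called function files."""
    entry_name = _unit_name(entry.path)
    units: Dict[str, Node] = {}
    sources: Dict[str, SourceUnit] = {}
    edges: Set[Tuple[str, str]] = set()
    stack: List[str] = []

    def resolve(unit: SourceUnit, name: str):
        if name in stack:
            cycle = " -> ".join(stack[stack.index(name):] + [name])
            raise CompileError(error(E_CYCLIC_UNITS,
                                     f"cyclic file dependency: {cycle}"))
        if name in units:
            return
        stack.append(name)
        root = parse_source(unit)
        units[name] = root
        sources[name] = unit
        local = _local_function_names(root) | ({name} if root.kind == "function_def" else set())
        for use, call_position in _function_uses(root):
            target = use.name
            if target in local and target != name:
                continue
            if target == name:
                raise CompileError(error(
                    E_CYCLIC_UNITS,
                    f"unit {name!r} calls itself; file-level recursion is not supported",
                    use.loc))
            if target in units or target in stack:
                if (name, target) not in edges and target in stack:
                    cycle = " -> ".join(stack[stack.index(target):] + [target])
                    raise CompileError(error(E_CYCLIC_UNITS,
                                             f"cyclic file dependency: {cycle}", use.loc))
                if target in units:
                    edges.add((name, target))
                continue
            path = _find_unit(target, search_paths)
            if path is not None:
                with open(path, "r", encoding="utf-8") as fh:
                    text = fh.read()
                resolve(SourceUnit(path=path, text=text), target)
                edges.add((name, target))
            elif target in BUILTIN_NAMES or not call_position:
                # unresolved bare reads are left for scope analysis
                continue
            elif any(n.kind == "function_def" and n.name == target
                     for u in units.values() for n in u.iter_nodes()):
                # defined somewhere, but possibly out of scope (e.g. nested
                # in another function) -- scope analysis owns that diagnosis
                continue
            else:
                raise CompileError(error(
                    E_MISSING_UNIT,
                    f"cannot resolve function {target!r}: "
                    f"no {target}.m on the search path and not a builtin",
                    use.loc))
        stack.pop()

    resolve(entry, entry_name)
    return ProgramGraph(units=units, entry=entry_name, call_edges=edges, sources=sources)


def build_program_from_path(entry_path: str,
                            search_paths: Sequence[str] = ()) -> ProgramGraph:
    if not os.path.isfile(entry_path):
        raise CompileError(error(E_IO, f"entry file not found: {entry_path}"))
    with open(entry_path, "r", encoding="utf-8") as fh:
        text = fh.read()
    unit = SourceUnit(path=entry_path, text=text, is_entry=True)
    paths = list(search_paths) or [os.path.dirname(entry_path) or "."]
    if os.path.dirname(entry_path) not in paths:
        paths.append(os.path.dirname(entry_path) or ".")
    return build_program(unit, paths)


def _unit_name(path: str) -> str:
    base = os.path.basename(path)
    return base[:-2] if base.endswith(".m") else base
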