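"""Environment checking: bind every identifier use to a definition.

Each unit (script or function) owns a :class:`Scope`.  Functions do not see
their caller's variables; a function ``g`` defined inside ``f`` is callable
from ``f`` (and from g's sibling subfunctions) but from nowhere outside
``f`` — calling it elsewhere is a scope error, and a plain variable read
with no prior assignment is a use-before-definition error.

Resolution also settles the call-vs-index ambiguity of ``name(args)``:
when ``name`` is bound to a variable at that point the node is rewritten to
an ``index`` node; otherwise it stays a ``call``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from ..diagnostics import (Diagnostic, E_SCOPE_CALL, E_UNDEFINED, error)
from ..frontend.astnodes import Node
from ..frontend.program import BUILTIN_NAMES, ProgramGraph

# binding kinds attached to identifier / call-base nodes
VAR = "var"
FUNC = "func"
BUILTIN = "builtin"


@dataclass
class Scope:
    """Variable bindings of one script or function body."""

    owner: Node
    name: str
    parent: Optional["Scope"] = None  # enclosing *function table* chain only
    bindings: Dict[str, Node] = field(default_factory=dict)  # name -> def site
    functions: Dict[str, "FunctionEntry"] = field(default_factory=dict)

    def lookup_function(self, name: str) -> Optional["FunctionEntry"]:
        s: Optional[Scope] = self
        while s is not None:
            if name in s.functions:
                return s.functions[name]
            s = s.parent
        return None


@dataclass
class FunctionEntry:
    node: Node
    owner_scope: "Scope"
    unit: str


def _collect_functions(program: ProgramGraph) -> Dict[str, Scope]:
    """Build the scope skeleton: one scope per script/function, with the
    function-visibility chain (nested subfunctions visible only inside
    their parent)."""
    unit_scopes: Dict[str, Scope] = {}
    top = Scope(owner=program.entry_node, name="<program>")
    # cross-file units are globally callable
    for uname, root in program.units.items():
        top.functions.setdefault(
            uname, FunctionEntry(root, top, uname)) if root.kind == "function_def" else None

    def attach(fnode: Node, parent: Scope, unit: str) -> Scope:
        s = Scope(owner=fnode, name=fnode.name or "<script>", parent=parent)
        for sub in fnode.subfunctions or []:
            s.functions[sub.name] = FunctionEntry(sub, s, unit)
        for sub in fnode.subfunctions or []:
            attach(sub, s, unit)
        fnode._scope = s  # type: ignore[attr-defined]
        return s

    for uname, root in program.units.items():
        unit_scopes[uname] = attach(root, top, uname)
    return unit_scopes


def resolve_scopes(program: ProgramGraph) -> Tuple[Dict[str, Scope], List[Diagnostic]]:
    """Bind identifier uses across the whole program.

    Returns the per-unit scopes and the diagnostics.  Binding results are
    attached to nodes as ``node._binding = (kind, payload)``.
    """
    diags: List[Diagnostic] = []
    unit_scopes = _collect_functions(program)

    def resolve_body(scope: Scope, stmts: List[Node], defined: set):
        for st in stmts:
            resolve_stmt(scope, st, defined)

    def bind_read(scope: Scope, n: Node, defined: set, call_position: bool):
        name = n.name
        if name in defined:
            n._binding = (VAR, scope)  # type: ignore[attr-defined]
            if n.kind == "identifier":
                return VAR
            return VAR
        fe = scope.lookup_function(name)
        if fe is not None:
            n._binding = (FUNC, fe)  # type: ignore[attr-defined]
            return FUNC
        if name in BUILTIN_NAMES:
            n._binding = (BUILTIN, name)  # type: ignore[attr-defined]
            return BUILTIN
        # not visible here -- distinguish "exists somewhere nested" for the
        # clearer scope-error message
        hidden = _find_anywhere(program, name)
        if hidden is not None and call_position:
            diags.append(error(
                E_SCOPE_CALL,
                f"function {name!r} is defined inside {hidden!r} and is only "
                f"available there; any call outside it is undefined",
                n.loc))
        elif call_position:
            diags.append(error(E_UNDEFINED, f"call to undefined function {name!r}", n.loc))
        else:
            diags.append(error(
                E_UNDEFINED, f"use of variable {name!r} before definition", n.loc))
        n._binding = (VAR, scope)  # type: ignore[attr-defined]
        return None

    def resolve_expr(scope: Scope, n: Node, defined: set):
        k = n.kind
        if k == "identifier":
            bind_read(scope, n, defined, call_position=False)
            return
        if k == "func_handle":
            bind_read(scope, n, defined, call_position=True)
            return
        if k == "call":
            base = n.children[0]
            if base.kind == "identifier":
                kind = bind_read(scope, base, defined, call_position=base.name not in defined)
                if kind == VAR:
                    n.kind = "index"
            else:
                resolve_expr(scope, base, defined)
            for a in n.children[1:]:
                resolve_expr(scope, a, defined)
            return
        if k == "anonymous_function":
            inner = set(defined) | set(n.params or [])
            resolve_expr(scope, n.children[0], inner)
            return
        for c in n.children:
            resolve_expr(scope, c, defined)

    def resolve_lvalue(scope: Scope, lhs: Node, defined: set):
        """Resolve subscript reads of an lvalue, then mark targets defined."""
        targets = []
        if lhs.kind == "matrix_literal":
            elements = lhs.children[0].children
        else:
            elements = [lhs]
        for el in elements:
            if el.kind == "identifier":
                targets.append(el.name)
                el._binding = (VAR, scope)  # type: ignore[attr-defined]
            elif el.kind in ("call", "index"):
                base = el.children[0]
                # indexed write: base must already exist as a variable or is
                # created by growth; subscripts are ordinary reads
                if base.kind == "identifier":
                    el.kind = "index"
                    base._binding = (VAR, scope)  # type: ignore[attr-defined]
                    targets.append(base.name)
                for a in el.children[1:]:
                    resolve_expr(scope, a, defined)
            elif el.kind == "field_access":
                base = el.children[0]
                if base.kind == "identifier":
                    base._binding = (VAR, scope)  # type: ignore[attr-defined]
                    targets.append(base.name)
                else:
                    resolve_expr(scope, base, defined)
        for t in targets:
            defined.add(t)
            scope.bindings.setdefault(t, lhs)

    def resolve_stmt(scope: Scope, st: Node, defined: set):
        k = st.kind
        if k == "assignment":
            lhs, rhs = st.children
            resolve_expr(scope, rhs, defined)
            resolve_lvalue(scope, lhs, defined)
            return
        if k == "expr_stmt":
            resolve_expr(scope, st.children[0], defined)
            return
        if k == "if":
            resolve_expr(scope, st.children[0], defined)
            resolve_body(scope, st.children[1].children, defined)
            for br in st.children[2:]:
                if br.kind == "elseif_branch":
                    resolve_expr(scope, br.children[0], defined)
                    resolve_body(scope, br.children[1].children, defined)
                else:
                    resolve_body(scope, br.children[0].children, defined)
            return
        if k == "for":
            resolve_expr(scope, st.children[0], defined)
            defined.add(st.name)
            scope.bindings.setdefault(st.name, st)
            resolve_body(scope, st.children[1].children, defined)
            return
        if k == "while":
            # loop-carried variables must exist before entry; first resolve
            # the body once to collect assignments made on iteration one
            resolve_expr(scope, st.children[0], defined)
            resolve_body(scope, st.children[1].children, defined)
            return
        # break/continue/return carry nothing

    def resolve_function(fnode: Node):
        scope: Scope = fnode._scope  # type: ignore[attr-defined]
        defined = set(fnode.params or [])
        resolve_body(scope, fnode.children, defined)
        for out in fnode.outs or []:
            if out not in defined:
                diags.append(error(
                    E_UNDEFINED,
                    f"output {out!r} of function {fnode.name!r} is never assigned",
                    fnode.loc))
        for sub in fnode.subfunctions or []:
            resolve_function(sub)

    for uname, root in program.units.items():
        if root.kind == "function_def":
            resolve_function(root)
        else:
            scope = unit_scopes[uname]
            resolve_body(scope, root.children, set())
    return unit_scopes, diags


def _find_anywhere(program: ProgramGraph, name: str) -> Optional[str]:
    """Name of the function that owns a nested definition of `name`, if any."""
    for root in program.units.values():
        for n in root.iter_nodes():
            if n.kind == "function_def":
                for sub in n.subfunctions or []:
                    if sub.name == name:
                        return n.name
    return None
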