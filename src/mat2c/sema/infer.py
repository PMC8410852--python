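"""Multi-pass fixpoint type/shape inference producing the annotated tree.

The walker evaluates expression types against a per-point environment,
re-running whole-program passes until no annotation changes (monotone
ascent of a finite lattice; hard cap ``MAX_PASSES``).  Control-flow merges
join the branch environments; a join of incompatible concrete shapes
promotes to the dynamic shape with a warning, matching the dialect's
permission to resize matrices at run time.  User functions are typed from
their return-variable assignments, specialized per distinct argument
signature (bounded), and memoized.

Operator/operand compatibility is validated by :func:`check_types` against
the dialect's shape algebra; the canonical rejected case is the quotient
``/`` between two 1-D vectors, whose elementwise meaning is already taken
by ``./``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from ..diagnostics import (CompileError, Diagnostic, E_BASE_CONFLICT,
                           E_NO_FIXPOINT, E_SHAPE, E_UNSUPPORTED,
                           E_VECTOR_QUOTIENT, W_SHAPE_MERGE, error, warning)
from ..frontend.astnodes import Node
from ..frontend.program import ProgramGraph
from .scopes import BUILTIN, FUNC, VAR, Scope, resolve_scopes
from .types import (UNKNOWN, Base, BaseConflict, Shape, Type, join, le, real)

MAX_PASSES = 50
MAX_SPECIALIZATIONS = 4

_ELEMENTWISE = {"+", "-", ".*", "./", ".^", "&", "|"}
_COMPARISON = {"==", "~=", "<", "<=", ">", ">="}


@dataclass
class AnnotatedTree:
    """Program graph plus per-node types and scopes (the compiler's IR)."""

    program: ProgramGraph
    types: Dict[int, Type] = field(default_factory=dict)
    scopes: Dict[str, Scope] = field(default_factory=dict)
    diagnostics: List[Diagnostic] = field(default_factory=list)
    var_types: Dict[str, Dict[str, Type]] = field(default_factory=dict)
    specializations: Dict[int, list] = field(default_factory=dict)
    passes: int = 0

    def type_of(self, node: Node) -> Type:
        return self.types.get(id(node), UNKNOWN)

    @property
    def errors(self) -> List[Diagnostic]:
        from ..diagnostics import Severity
        return [d for d in self.diagnostics if d.severity is Severity.ERROR]


def _lit(n: Node) -> Optional[float]:
    """Constant-fold literal numbers (with unary sign) for shape arguments."""
    if n.kind == "number":
        return float(n.value)
    if n.kind == "unary_op" and n.op in "+-" and n.children[0].kind == "number":
        v = float(n.children[0].value)
        return -v if n.op == "-" else v
    return None


def _lit_dim(n: Node) -> Optional[int]:
    v = _lit(n)
    if v is not None and v == int(v) and v >= 0:
        return int(v)
    return None


class Inferencer:
    def __init__(self, program: ProgramGraph):
        self.program = program
        self.tree = AnnotatedTree(program)
        self.diags = self.tree.diagnostics
        self._fn_cache: Dict[Tuple[int, tuple], List[Type]] = {}
        self._fn_inflight: set = set()
        self._anon_sites: Dict[int, Node] = {}
        self._warned_merge: set = set()

    # -- public ---------------------------------------------------------
    def run(self) -> AnnotatedTree:
        scopes, sdiags = resolve_scopes(self.program)
        self.tree.scopes = scopes
        self.diags.extend(sdiags)
        if any(d.code in ("E_UNDEFINED", "E_SCOPE_CALL") for d in sdiags):
            return self.tree
        for pass_no in range(1, MAX_PASSES + 1):
            self.tree.passes = pass_no
            before = dict(self.tree.types)
            self._fn_cache.clear()
            env: Dict[str, Type] = {}
            entry = self.program.entry_node
            if entry.kind == "script":
                self.infer_block(entry.children, env, self.tree.scopes[self.program.entry])
            else:  # entry is a function file: type it with dynamic reals
                args = [real(Shape.dyn())] * len(entry.params or [])
                self.call_function(entry, args, entry.loc)
            self.tree.var_types[self.program.entry] = env
            if self.tree.types == before and pass_no > 1:
                break
        else:
            unknowns = sorted({
                n.name for root in self.program.units.values()
                for n in root.iter_nodes()
                if n.kind == "identifier" and self.tree.type_of(n).is_unknown and n.name
            })
            self.diags.append(error(
                E_NO_FIXPOINT,
                "type inference did not converge within "
                f"{MAX_PASSES} passes; unresolved: {', '.join(unknowns) or '<none>'}"))
        return self.tree

    # -- annotation helpers ----------------------------------------------
    def note(self, node: Node, t: Type) -> Type:
        old = self.tree.types.get(id(node))
        if old is not None and old != t and not t.is_unknown:
            # monotone: never descend; join with previous annotation
            try:
                t, _ = join(old, t)
            except BaseConflict:
                pass
        self.tree.types[id(node)] = t
        return t

    # -- statements -------------------------------------------------------
    def infer_block(self, stmts: List[Node], env: Dict[str, Type], scope: Scope):
        for st in stmts:
            self.infer_stmt(st, env, scope)

    def infer_stmt(self, st: Node, env: Dict[str, Type], scope: Scope):
        k = st.kind
        if k == "assignment":
            lhs, rhs = st.children
            self.assign(lhs, rhs, env, scope)
        elif k == "expr_stmt":
            self.infer_expr(st.children[0], env, scope)
        elif k == "if":
            self.infer_expr(st.children[0], env, scope)
            branches = [st.children[1].children]
            has_else = False
            for br in st.children[2:]:
                if br.kind == "elseif_branch":
                    self.infer_expr(br.children[0], env, scope)
                    branches.append(br.children[1].children)
                else:
                    branches.append(br.children[0].children)
                    has_else = True
            outs = []
            for body in branches:
                benv = dict(env)
                self.infer_block(body, benv, scope)
                outs.append(benv)
            if not has_else:
                outs.append(dict(env))
            merged: Dict[str, Type] = {}
            for benv in outs:
                for name, t in benv.items():
                    if name in merged:
                        merged[name] = self._merge(merged[name], t, st)
                    else:
                        merged[name] = t
            env.clear()
            env.update(merged)
        elif k == "for":
            it = self.infer_expr(st.children[0], env, scope)
            env[st.name] = self._loop_var_type(it)
            # two sweeps reach the loop-carried fixpoint for shape growth
            for _ in range(2):
                self.infer_block(st.children[1].children, env, scope)
        elif k == "while":
            for _ in range(2):
                self.infer_expr(st.children[0], env, scope)
                self.infer_block(st.children[1].children, env, scope)
        # break/continue/return: nothing to infer

    @staticmethod
    def _loop_var_type(it: Type) -> Type:
        if it.is_numeric and not it.shape.is_scalar:
            # iterate over columns: scalar for ranges/row vectors
            if it.shape.rows in (1, None) or it.shape.dynamic:
                return real(Shape.scalar())
            return real(Shape.vector(it.shape.rows))
        return real(Shape.scalar())

    def _merge(self, a: Type, b: Type, at: Node) -> Type:
        try:
            t, warned = join(a, b)
        except BaseConflict:
            self.diags.append(error(
                E_BASE_CONFLICT,
                f"variable takes incompatible types on different paths: {a} vs {b}",
                at.loc))
            return real(Shape.dyn())
        if warned and id(at) not in self._warned_merge:
            self._warned_merge.add(id(at))
            self.diags.append(warning(
                W_SHAPE_MERGE,
                f"conflicting shapes {a.shape} vs {b.shape} at control-flow merge; "
                "promoted to dynamic",
                at.loc))
        return t

    def assign(self, lhs: Node, rhs: Node, env: Dict[str, Type], scope: Scope):
        rt = self.infer_expr(rhs, env, scope)
        if lhs.kind == "identifier":
            env[lhs.name] = rt
            self.note(lhs, rt)
        elif lhs.kind == "matrix_literal":  # multi-output call
            outs = getattr(rhs, "_out_types", None) or [rt]
            els = lhs.children[0].children
            for i, el in enumerate(els):
                t = outs[i] if i < len(outs) else real(Shape.dyn())
                if el.kind == "identifier":
                    env[el.name] = t
                    self.note(el, t)
                else:
                    self._indexed_write(el, t, env, scope)
            self.note(lhs, outs[0] if outs else UNKNOWN)
        elif lhs.kind in ("index", "call"):
            self._indexed_write(lhs, rt, env, scope)
        elif lhs.kind == "field_access":
            base = lhs.children[0]
            if base.kind == "identifier":
                env[base.name] = Type(Base.STRUCT)
                self.note(base, Type(Base.STRUCT))
            self.note(lhs, rt)

    def _indexed_write(self, lhs: Node, rt, env: Dict[str, Type], scope: Scope):
        base = lhs.children[0]
        for a in lhs.children[1:]:
            if a.kind != "colon_all":
                self.infer_expr(a, env, scope)
        if base.kind != "identifier":
            return
        old = env.get(base.name, UNKNOWN)
        nsub = len(lhs.children) - 1
        if old.is_unknown:
            # created by growth: a(i)=v makes a vector, a(i,j)=v a matrix
            shape = Shape.vector(None, column=False) if nsub == 1 else Shape(None, None)
            new = real(shape)
        elif old.is_numeric:
            # writing may grow: keep base, dims become dynamic unless the
            # subscripts are literal and within the known extent
            dims = [_lit_dim(a) for a in lhs.children[1:]]
            s = old.shape
            if s.known and nsub == 2 and dims[0] and dims[1] and \
                    dims[0] <= s.rows and dims[1] <= s.cols:
                new = old
            elif s.known and nsub == 1 and dims[0] and s.numel() and dims[0] <= s.numel():
                new = old
            else:
                if s.dynamic:
                    new = old
                elif nsub == 1:
                    new = real(Shape(s.rows if s.rows == 1 else None,
                                     s.cols if s.cols == 1 else None))
                else:
                    new = real(Shape(None, None))
        else:
            new = old
        env[base.name] = new
        self.note(base, new)
        self.note(lhs, rt if isinstance(rt, Type) else real(Shape.dyn()))

    # -- expressions ------------------------------------------------------
    def infer_expr(self, n: Node, env: Dict[str, Type], scope: Scope):
        k = n.kind
        if k == "number":
            return self.note(n, real(Shape.scalar()))
        if k == "string":
            return self.note(n, Type(Base.STRING))
        if k == "identifier":
            binding = getattr(n, "_binding", (VAR, None))
            if binding[0] == VAR:
                return self.note(n, env.get(n.name, UNKNOWN))
            if binding[0] == BUILTIN:
                return self.note(n, self.builtin_result(n.name, [], [], n, env, scope))
            if binding[0] == FUNC:
                outs = self.call_function(binding[1].node, [], n.loc)
                return self.note(n, outs[0] if outs else UNKNOWN)
            return UNKNOWN
        if k == "func_handle":
            return self.note(n, Type(Base.FUNC_HANDLE))
        if k == "anonymous_function":
            return self.note(n, Type(Base.FUNC_HANDLE))
        if k == "unary_op":
            t = self.infer_expr(n.children[0], env, scope)
            if n.op == "~":
                shape = t.shape if t.is_numeric else Shape.scalar()
                return self.note(n, Type(Base.LOGICAL, shape))
            return self.note(n, t if t.is_numeric else real(Shape.dyn()))
        if k == "transpose":
            t = self.infer_expr(n.children[0], env, scope)
            if t.is_numeric:
                return self.note(n, Type(t.base, t.shape.transposed()))
            return self.note(n, t)
        if k == "binary_op":
            a = self.infer_expr(n.children[0], env, scope)
            b = self.infer_expr(n.children[1], env, scope)
            return self.note(n, self.binop_type(n, a, b))
        if k == "range":
            for c in n.children:
                self.infer_expr(c, env, scope)
            lits = [_lit(c) for c in n.children]
            if all(v is not None for v in lits):
                if len(lits) == 2:
                    start, step, stop = lits[0], 1.0, lits[1]
                else:
                    start, step, stop = lits
                count = int((stop - start) / step + 1e-9) + 1 if step != 0 else 0
                count = max(count, 0)
                return self.note(n, real(Shape.vector(count, column=False)))
            return self.note(n, real(Shape.vector(None, column=False)))
        if k == "matrix_literal":
            return self.note(n, self._matrix_literal_type(n, env, scope))
        if k == "field_access":
            self.infer_expr(n.children[0], env, scope)
            return self.note(n, real(Shape.dyn()))
        if k in ("index", "call"):
            return self.note(n, self._call_or_index(n, env, scope))
        if k == "colon_all":
            return self.note(n, real(Shape.vector(None)))
        if k == "end_marker":
            return self.note(n, real(Shape.scalar()))
        raise CompileError(error(E_UNSUPPORTED, f"cannot type node kind {k}", n.loc))

    def _matrix_literal_type(self, n: Node, env, scope) -> Type:
        if not n.children:
            return real(Shape.matrix(0, 0))
        row_shapes = []
        base = Base.REAL
        for row in n.children:
            cols: Optional[int] = 0
            rows: Optional[int] = 1
            for el in row.children:
                t = self.infer_expr(el, env, scope)
                if not t.is_numeric:
                    return real(Shape.dyn())
                s = t.shape
                if s.dynamic or s.cols is None:
                    cols = None
                elif cols is not None:
                    cols += s.cols
                if s.dynamic or s.rows is None:
                    rows = None
                elif rows == 1 and s.rows > 1:
                    rows = s.rows
            row_shapes.append((rows, cols))
        total_rows: Optional[int] = 0
        ncols = row_shapes[0][1]
        for r, c in row_shapes:
            if r is None or total_rows is None:
                total_rows = None
            else:
                total_rows += r
            if c != ncols:
                ncols = None
        return Type(base, Shape(total_rows, ncols))

    def _call_or_index(self, n: Node, env, scope) -> Type:
        base = n.children[0]
        args = n.children[1:]
        if n.kind == "index" or (base.kind == "identifier" and
                                 getattr(base, "_binding", (None,))[0] == VAR):
            n.kind = "index"
            bt = self.note(base, env.get(base.name, UNKNOWN)) \
                if base.kind == "identifier" else self.infer_expr(base, env, scope)
            if bt.base is Base.FUNC_HANDLE:
                n.kind = "call"  # calling a handle-valued variable
                arg_ts = [self.infer_expr(a, env, scope) for a in args]
                return self._call_handle(base, arg_ts, env, scope, n)
            return self._index_type(n, bt, args, env, scope)
        if base.kind == "identifier":
            kind, payload = getattr(base, "_binding", (None, None))
            arg_ts = [self.infer_expr(a, env, scope) if a.kind != "colon_all"
                      else real(Shape.vector(None)) for a in args]
            if kind == BUILTIN:
                return self.builtin_result(payload, args, arg_ts, n, env, scope)
            if kind == FUNC:
                outs = self.call_function(payload.node, arg_ts, n.loc)
                n._out_types = outs  # type: ignore[attr-defined]
                return outs[0] if outs else UNKNOWN
        # calling the value of an arbitrary expression
        self.infer_expr(base, env, scope)
        for a in args:
            self.infer_expr(a, env, scope)
        return real(Shape.dyn())

    def _call_handle(self, base: Node, arg_ts: List[Type], env, scope, site: Node) -> Type:
        target = self._handle_target(base, env, scope)
        if target is None:
            return real(Shape.dyn())
        if target.kind == "anonymous_function":
            inner = dict(env)
            for p, t in zip(target.params or [], arg_ts):
                inner[p] = t
            return self.infer_expr(target.children[0], inner, scope)
        outs = self.call_function(target, arg_ts, site.loc)
        return outs[0] if outs else real(Shape.dyn())

    def _handle_target(self, base: Node, env, scope) -> Optional[Node]:
        """Static target of a handle-valued variable: its unique defining
        handle literal, recorded during scope resolution walks."""
        defsite = getattr(base, "_handle_def", None)
        if defsite is not None:
            return defsite
        # search the enclosing unit for `name = @...` assignments
        owner = scope.owner
        found = None
        for node in owner.iter_nodes():
            if node.kind == "assignment" and node.children[0].kind == "identifier" \
                    and node.children[0].name == base.name:
                rhs = node.children[1]
                if rhs.kind == "anonymous_function":
                    found = rhs if found is None else found
                elif rhs.kind == "func_handle":
                    fe = scope.lookup_function(rhs.name)
                    if fe is not None:
                        found = fe.node if found is None else found
        base._handle_def = found  # type: ignore[attr-defined]
        return found

    def _index_type(self, n: Node, bt: Type, args: List[Node], env, scope) -> Type:
        sub_ts = []
        for a in args:
            if a.kind == "colon_all":
                sub_ts.append(None)
                self.note(a, real(Shape.vector(None)))
            else:
                sub_ts.append(self.infer_expr(a, env, scope))
        if not bt.is_numeric:
            return real(Shape.dyn())
        s = bt.shape
        if len(args) == 1:
            st = sub_ts[0]
            if st is None:  # A(:) -> column vector
                return real(Shape.vector(s.numel()))
            if st.base is Base.LOGICAL:
                return real(Shape.vector(None, column=s.rows != 1))
            if st.shape.is_scalar:
                return real(Shape.scalar())
            # vector subscript keeps the subscript's orientation
            return real(st.shape)
        if len(args) == 2:
            def dim_len(sub, extent):
                if sub is None:
                    return extent
                if sub.shape.is_scalar:
                    return 1
                return sub.shape.numel()
            r = dim_len(sub_ts[0], s.rows if not s.dynamic else None)
            c = dim_len(sub_ts[1], s.cols if not s.dynamic else None)
            return real(Shape(r, c))
        return real(Shape.dyn())

    # -- operators --------------------------------------------------------
    def binop_type(self, n: Node, a: Type, b: Type) -> Type:
        op = n.op
        if a.is_unknown or b.is_unknown:
            return UNKNOWN
        if not (a.is_numeric and b.is_numeric):
            if op in _COMPARISON and a.base is Base.STRING and b.base is Base.STRING:
                return Type(Base.LOGICAL, Shape.scalar())
            return real(Shape.dyn())
        out_base = Base.LOGICAL if (op in _COMPARISON or op in ("&", "|", "&&", "||", "~")) \
            else Base.REAL
        sa, sb = a.shape, b.shape
        if op in ("&&", "||"):
            return Type(Base.LOGICAL, Shape.scalar())
        if op in _ELEMENTWISE or op in _COMPARISON:
            return Type(out_base, self._broadcast(sa, sb))
        if op == "*":
            if sa.is_scalar or sb.is_scalar:
                return real(sb if sa.is_scalar else sa)
            if sa.dynamic or sb.dynamic:
                return real(Shape.dyn())
            return real(Shape(sa.rows, sb.cols))
        if op == "/":
            if sb.is_scalar:
                return real(sa)
            if sb.maybe_scalar or sa.is_scalar:
                return real(Shape.dyn())
            return real(Shape.dyn())  # flagged by check_types
        if op == "^":
            return real(Shape.scalar() if sa.is_scalar and sb.is_scalar else Shape.dyn())
        return real(Shape.dyn())

    @staticmethod
    def _broadcast(sa: Shape, sb: Shape) -> Shape:
        if sa.is_scalar:
            return sb
        if sb.is_scalar:
            return sa
        if sa == sb:
            return sa
        if sa.dynamic or sb.dynamic:
            return Shape.dyn()
        return Shape(sa.rows if sa.rows == sb.rows else None,
                     sa.cols if sa.cols == sb.cols else None)

    # -- functions --------------------------------------------------------
    def call_function(self, fnode: Node, arg_ts: List[Type], loc) -> List[Type]:
        key = (id(fnode), tuple(str(t) for t in arg_ts))
        if key in self._fn_cache:
            return self._fn_cache[key]
        if key in self._fn_inflight:  # recursion guard (rejected upstream)
            return [real(Shape.dyn())]
        sigs = self.tree.specializations.setdefault(id(fnode), [])
        if key not in sigs:
            sigs.append(key)
            if len(sigs) > MAX_SPECIALIZATIONS:
                self.diags.append(warning(
                    W_SHAPE_MERGE,
                    f"function {fnode.name!r} exceeded {MAX_SPECIALIZATIONS} "
                    "specializations; widening to dynamic", loc))
                result = [real(Shape.dyn()) for _ in fnode.outs or [UNKNOWN]]
                self._fn_cache[key] = result
                return result
        self._fn_inflight.add(key)
        try:
            env: Dict[str, Type] = {}
            for p, t in zip(fnode.params or [], arg_ts):
                env[p] = t
            scope: Scope = fnode._scope  # type: ignore[attr-defined]
            self.infer_block(fnode.children, env, scope)
            outs = [env.get(o, real(Shape.dyn())) for o in (fnode.outs or [])]
            self.note(fnode, outs[0] if outs else UNKNOWN)
            self.tree.var_types[f"{fnode.name}{key[1]}"] = env
            self._fn_cache[key] = outs
            return outs
        finally:
            self._fn_inflight.discard(key)

    def _infer_rhs_handle(self, h: Node, n_state, env, scope):
        """Type the body of an ODE right-hand-side handle under its call
        signature (scalar time, state column vector)."""
        sig = [real(Shape.scalar()), real(Shape.vector(n_state))]
        if h.kind == "anonymous_function":
            inner = dict(env)
            for p, t in zip(h.params or [], sig):
                inner[p] = t
            self.infer_expr(h.children[0], inner, scope)
            return
        target = None
        if h.kind == "func_handle":
            fe = scope.lookup_function(h.name)
            target = fe.node if fe else None
        elif h.kind == "identifier":
            target = self._handle_target(h, env, scope)
        if target is None:
            return
        if target.kind == "anonymous_function":
            inner = dict(env)
            for p, t in zip(target.params or [], sig):
                inner[p] = t
            self.infer_expr(target.children[0], inner, scope)
        else:
            self.call_function(target, sig, h.loc)

    # -- builtins ---------------------------------------------------------
    def builtin_result(self, name: str, args: List[Node], arg_ts: List[Type],
                       site: Node, env, scope) -> Type:
        S = Shape
        if name == "pi":
            return real(S.scalar())
        if name in ("zeros", "ones", "eye", "rand", "randn"):
            dims = [_lit_dim(a) for a in args]
            if len(args) == 0:
                return real(S.scalar())
            if len(args) == 1:
                d = dims[0]
                return real(S(d, d))
            return real(S(dims[0], dims[1]))
        if name == "size":
            if len(args) == 2:
                return real(S.scalar())
            return real(S.vector(2, column=False))
        if name in ("length", "numel", "norm", "dot", "isempty"):
            base = Base.LOGICAL if name == "isempty" else Base.REAL
            return Type(base, S.scalar())
        if name in ("abs", "exp", "log", "log10", "sqrt", "sin", "cos", "tan",
                    "floor", "ceil", "round"):
            t = arg_ts[0] if arg_ts else UNKNOWN
            return real(t.shape) if t.is_numeric else real(S.dyn())
        if name in ("mod", "rem"):
            if len(arg_ts) == 2 and arg_ts[0].is_numeric and arg_ts[1].is_numeric:
                return real(self._broadcast(arg_ts[0].shape, arg_ts[1].shape))
            return real(S.dyn())
        if name in ("min", "max"):
            if len(arg_ts) >= 2:
                return real(self._broadcast(arg_ts[0].shape, arg_ts[1].shape))
            t = arg_ts[0] if arg_ts else UNKNOWN
            if t.is_numeric and not t.shape.dynamic:
                if t.shape.is_scalar or t.shape.is_vector:
                    return real(S.scalar())
                return real(S.vector(t.shape.cols, column=False))
            return real(S.dyn())
        if name in ("sum", "prod"):
            t = arg_ts[0] if arg_ts else UNKNOWN
            if t.is_numeric and not t.shape.dynamic:
                if t.shape.is_scalar or t.shape.is_vector:
                    return real(S.scalar())
                return real(S.vector(t.shape.cols, column=False))
            return real(S.dyn())
        if name in ("any", "all"):
            return Type(Base.LOGICAL, S.scalar())
        if name == "linspace":
            d = _lit_dim(args[2]) if len(args) == 3 else 100
            return real(S.vector(d, column=False))
        if name == "interp1":
            t = arg_ts[2] if len(arg_ts) > 2 else UNKNOWN
            return real(t.shape) if t.is_numeric else real(S.dyn())
        if name in ("setdiff", "union", "unique", "sort", "find"):
            return real(S.vector(None, column=False))
        if name == "load":
            return real(S(None, None))
        if name == "repmat":
            return real(S(None, None))
        if name in ("disp", "fprintf"):
            return UNKNOWN
        if name == "odeset":
            return Type(Base.STRUCT)
        if name in ("ode45", "ode23", "ode15s"):
            n_state = None
            if len(arg_ts) >= 3 and arg_ts[2].is_numeric:
                n_state = arg_ts[2].shape.numel()
            if args:
                self._infer_rhs_handle(args[0], n_state, env, scope)
            outs = [real(S.vector(None)), real(S(None, n_state))]
            site._out_types = outs  # type: ignore[attr-defined]
            return outs[0]
        return real(S.dyn())


def infer_types(program: ProgramGraph) -> AnnotatedTree:
    """Run scope resolution plus fixpoint inference over a program."""
    return Inferencer(program).run()


def check_types(tree: AnnotatedTree) -> List[Diagnostic]:
    """Validate operator/operand pairings against the dialect shape algebra."""
    diags: List[Diagnostic] = []
    for root in tree.program.units.values():
        for n in root.iter_nodes():
            if n.kind != "binary_op":
                continue
            a, b = (tree.type_of(c) for c in n.children)
            if not (a.is_numeric and b.is_numeric):
                continue
            sa, sb = a.shape, b.shape
            if n.op == "/":
                if sa.is_vector and sb.is_vector:
                    diags.append(error(
                        E_VECTOR_QUOTIENT,
                        "quotient '/' between two 1-dimensional vectors is an "
                        "undefined operation; the point-wise quotient is './'",
                        n.loc))
                elif not sb.maybe_scalar:
                    diags.append(error(
                        E_SHAPE, f"'/' requires a scalar divisor; got {sb}", n.loc))
            elif n.op in _ELEMENTWISE or n.op in _COMPARISON:
                if sa.known and sb.known and not sa.is_scalar and not sb.is_scalar \
                        and sa != sb:
                    diags.append(error(
                        E_SHAPE,
                        f"elementwise '{n.op}' on incompatible shapes {sa} and {sb}",
                        n.loc))
            elif n.op == "*":
                if sa.known and sb.known and not sa.is_scalar and not sb.is_scalar \
                        and sa.cols != sb.rows:
                    diags.append(error(
                        E_SHAPE,
                        f"matrix product inner dimensions disagree: {sa} * {sb}",
                        n.loc))
            elif n.op == "^":
                if not (sa.maybe_scalar and sb.maybe_scalar):
                    diags.append(error(
                        E_SHAPE, "'^' is supported for scalars only; use '.^'", n.loc))
    return diags


def analyze(program: ProgramGraph) -> AnnotatedTree:
    """resolve scopes, infer, then check; diagnostics accumulate on the tree."""
    tree = infer_types(program)
    if not tree.errors:
        tree.diagnostics.extend(check_types(tree))
    return tree
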