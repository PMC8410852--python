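"""Reference interpreter: the semantic oracle every translation is checked
against.

A straightforward tree walker over the scope-resolved program.  It is
correctness-first: numeric values are canonical 2-D column-major arrays,
assignment copies, indexing is 1-based (linear indexing column-major),
out-of-range reads raise while out-of-range writes grow zero-filled.
``ode45``/``ode23``/``ode15s`` calls integrate through :mod:`.ode` onto the
fixed output grid from :class:`RunOptions` and record a
:class:`Timeseries` per solve.
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Tuple

import numpy as np

from ..diagnostics import (E_RUNTIME, MatRuntimeError, SourceLocation, error)
from ..frontend.astnodes import Node
from ..frontend.program import ProgramGraph
from ..sema.scopes import BUILTIN, FUNC, VAR
from . import builtins as bi
from .ode import OdeProblem, solve_ode
from .values import (MFunction, RunOptions, Timeseries, as_matrix, is_numeric,
                     to_scalar, truthy)


class _Break(Exception):
    pass


class _Continue(Exception):
    pass


class _Return(Exception):
    pass


def _copy(v):
    return v.copy() if isinstance(v, np.ndarray) else v


def _fail(msg: str, loc: Optional[SourceLocation] = None):
    raise MatRuntimeError(error(E_RUNTIME, msg, loc))


class Interpreter:
    def __init__(self, program: ProgramGraph, options: Optional[RunOptions] = None):
        self.program = program
        self.options = options or RunOptions()
        self.timeseries: List[Timeseries] = []
        self.rng = np.random.Generator(np.random.PCG64(self.options.seed))
        entry_src = program.sources.get(program.entry)
        dirs = list(self.options.load_dirs)
        if entry_src is not None:
            d = os.path.dirname(entry_src.path)
            if d and d not in dirs:
                dirs.append(d)
        self.load_dirs = dirs or ["."]

    # -- entry ----------------------------------------------------------
    def run(self) -> Tuple[Dict[str, object], List[Timeseries]]:
        root = self.program.entry_node
        env: Dict[str, object] = {}
        if root.kind != "script":
            _fail("entry unit must be a script")
        try:
            self.exec_block(root.children, env)
        except _Return:
            pass
        return env, self.timeseries

    # -- statements ------------------------------------------------------
    def exec_block(self, stmts: List[Node], env: Dict[str, object]):
        for st in stmts:
            self.exec_stmt(st, env)

    def exec_stmt(self, st: Node, env: Dict[str, object]):
        k = st.kind
        if k == "assignment":
            lhs, rhs = st.children
            if lhs.kind == "matrix_literal":
                targets = lhs.children[0].children
                vals = self.eval_multi(rhs, env, n_out=len(targets))
                for tgt, v in zip(targets, vals):
                    self.store(tgt, _copy(v), env)
            else:
                self.store(lhs, _copy(self.eval(rhs, env)), env)
        elif k == "expr_stmt":
            self.eval(st.children[0], env)
        elif k == "if":
            if truthy(self.eval(st.children[0], env)):
                self.exec_block(st.children[1].children, env)
                return
            for br in st.children[2:]:
                if br.kind == "elseif_branch":
                    if truthy(self.eval(br.children[0], env)):
                        self.exec_block(br.children[1].children, env)
                        return
                else:
                    self.exec_block(br.children[0].children, env)
                    return
        elif k == "for":
            seq = as_matrix(self.eval(st.children[0], env))
            cols = [seq[:, j] for j in range(seq.shape[1])]
            for col in cols:
                env[st.name] = as_matrix(col if col.size > 1 else float(col[0]))
                if col.size > 1:
                    env[st.name] = as_matrix(col.reshape(-1, 1))
                try:
                    self.exec_block(st.children[1].children, env)
                except _Break:
                    break
                except _Continue:
                    continue
        elif k == "while":
            while truthy(self.eval(st.children[0], env)):
                try:
                    self.exec_block(st.children[1].children, env)
                except _Break:
                    break
                except _Continue:
                    continue
        elif k == "break":
            raise _Break()
        elif k == "continue":
            raise _Continue()
        elif k == "return":
            raise _Return()
        else:  # pragma: no cover - parser produces no other statement kinds
            _fail(f"unsupported statement {k}", st.loc)

    # -- lvalues ----------------------------------------------------------
    def store(self, lhs: Node, val, env: Dict[str, object]):
        if lhs.kind == "identifier":
            env[lhs.name] = val
            return
        if lhs.kind in ("index", "call"):
            base = lhs.children[0]
            if base.kind != "identifier":
                _fail("invalid indexed assignment target", lhs.loc)
            cur = env.get(base.name)
            cur = as_matrix(cur) if cur is not None else np.zeros((0, 0), order="F")
            env[base.name] = self.indexed_write(cur, lhs.children[1:], val, env, lhs.loc)
            return
        if lhs.kind == "field_access":
            base = lhs.children[0]
            if base.kind != "identifier":
                _fail("invalid field assignment target", lhs.loc)
            s = env.get(base.name)
            if not isinstance(s, dict):
                s = {}
            else:
                s = dict(s)
            s[lhs.name] = val
            env[base.name] = s
            return
        _fail("invalid assignment target", lhs.loc)

    def indexed_write(self, cur: np.ndarray, subs: List[Node], val,
                      env, loc) -> np.ndarray:
        v = as_matrix(val)
        if len(subs) == 1:
            idx = self.subscript(subs[0], cur, env, dim=None, loc=loc)
            if isinstance(idx, slice):
                idx = np.arange(1, cur.size + 1)
            idx = np.asarray(idx, dtype=int).reshape(-1)
            need = int(idx.max()) if idx.size else 0
            if idx.size and idx.min() < 1:
                _fail("index must be a positive integer", loc)
            if cur.size == 0:
                grown = np.zeros((1, need), order="F")  # new arrays grow as rows
            elif cur.shape[0] == 1:
                grown = np.zeros((1, max(need, cur.shape[1])), order="F")
                grown[0, :cur.shape[1]] = cur[0]
            elif cur.shape[1] == 1:
                grown = np.zeros((max(need, cur.shape[0]), 1), order="F")
                grown[:cur.shape[0], 0] = cur[:, 0]
            else:
                if need > cur.size:
                    _fail("linear index out of range for matrix write", loc)
                grown = cur.copy(order="F")
            flat = grown.reshape(-1, order="F").copy()
            src = v.reshape(-1, order="F")
            if src.size == 1:
                flat[idx - 1] = src[0]
            elif src.size == idx.size:
                flat[idx - 1] = src
            else:
                _fail("shape mismatch in indexed assignment", loc)
            return as_matrix(flat.reshape(grown.shape, order="F"))
        if len(subs) == 2:
            ri = self.subscript(subs[0], cur, env, dim=0, loc=loc)
            ci = self.subscript(subs[1], cur, env, dim=1, loc=loc)
            if isinstance(ri, slice):
                ri = np.arange(1, max(cur.shape[0], v.shape[0]) + 1)
            if isinstance(ci, slice):
                ci = np.arange(1, max(cur.shape[1], v.shape[1]) + 1)
            ri = np.asarray(ri, dtype=int).reshape(-1)
            ci = np.asarray(ci, dtype=int).reshape(-1)
            if (ri.size and ri.min() < 1) or (ci.size and ci.min() < 1):
                _fail("index must be a positive integer", loc)
            nr = max(cur.shape[0], int(ri.max()) if ri.size else 0)
            nc = max(cur.shape[1], int(ci.max()) if ci.size else 0)
            grown = np.zeros((nr, nc), order="F")
            grown[:cur.shape[0], :cur.shape[1]] = cur
            src = v
            if src.size == 1:
                for r in ri:
                    for c in ci:
                        grown[r - 1, c - 1] = src.flat[0]
            elif src.size == ri.size * ci.size:
                block = src.reshape(ri.size, ci.size, order="F") \
                    if src.shape != (ri.size, ci.size) else src
                for a, r in enumerate(ri):
                    for b, c in enumerate(ci):
                        grown[r - 1, c - 1] = block[a, b]
            else:
                _fail("shape mismatch in indexed assignment", loc)
            return as_matrix(grown)
        _fail("more than two subscripts are unsupported", loc)

    # -- expressions -------------------------------------------------------
    def eval(self, n: Node, env: Dict[str, object]):
        out = self.eval_multi(n, env, n_out=1)
        return out[0]

    def eval_multi(self, n: Node, env: Dict[str, object], n_out: int) -> List[object]:
        k = n.kind
        if k == "number":
            return [as_matrix(float(n.value))]
        if k == "string":
            return [str(n.value)]
        if k == "identifier":
            return [self.eval_identifier(n, env, n_out)]
        if k == "func_handle":
            return [self.make_handle(n, env)]
        if k == "anonymous_function":
            return [MFunction(kind="anonymous", node=n, closure=dict(env))]
        if k == "unary_op":
            v = self.eval(n.children[0], env)
            if n.op == "-":
                return [as_matrix(-as_matrix(v))]
            if n.op == "+":
                return [as_matrix(v)]
            return [as_matrix(as_matrix(v) == 0)]
        if k == "transpose":
            return [as_matrix(as_matrix(self.eval(n.children[0], env)).T)]
        if k == "binary_op":
            return [self.eval_binop(n, env)]
        if k == "range":
            return [self.eval_range(n, env)]
        if k == "matrix_literal":
            return [self.eval_matrix_literal(n, env)]
        if k == "field_access":
            base = self.eval(n.children[0], env)
            if not isinstance(base, dict) or n.name not in base:
                _fail(f"reference to missing field {n.name!r}", n.loc)
            return [_copy(base[n.name])]
        if k == "index":
            base = n.children[0]
            bv = self.eval(base, env)
            if isinstance(bv, MFunction):
                args = [self.eval(a, env) for a in n.children[1:]]
                return self.call_handle(bv, args, n_out, n.loc)
            return [self.index_read(as_matrix(bv), n.children[1:], env, n.loc)]
        if k == "call":
            return self.eval_call(n, env, n_out)
        _fail(f"cannot evaluate node kind {k}", n.loc)

    def eval_identifier(self, n: Node, env, n_out: int):
        kind, payload = getattr(n, "_binding", (VAR, None))
        if kind == VAR:
            if n.name not in env:
                _fail(f"variable {n.name!r} used before definition", n.loc)
            return env[n.name]
        if kind == BUILTIN:
            return self.call_builtin(payload, [], n_out, n.loc, env)[0]
        if kind == FUNC:
            return self.call_function(payload.node, [], n_out, n.loc)[0]
        _fail(f"unbound identifier {n.name!r}", n.loc)

    def make_handle(self, n: Node, env) -> MFunction:
        kind, payload = getattr(n, "_binding", (None, None))
        if kind == FUNC:
            return MFunction(kind="named", name=n.name, node=payload.node)
        if kind == BUILTIN:
            return MFunction(kind="builtin", name=n.name)
        _fail(f"cannot take a handle to {n.name!r}", n.loc)

    def eval_binop(self, n: Node, env):
        op = n.op
        if op in ("&&", "||"):
            a = truthy(self.eval(n.children[0], env))
            if op == "&&":
                res = a and truthy(self.eval(n.children[1], env))
            else:
                res = a or truthy(self.eval(n.children[1], env))
            return as_matrix(bool(res))
        av = self.eval(n.children[0], env)
        bv = self.eval(n.children[1], env)
        if isinstance(av, str) and isinstance(bv, str) and op in ("==", "~="):
            eq = av == bv
            return as_matrix(eq if op == "==" else not eq)
        a, b = as_matrix(av), as_matrix(bv)
        try:
            if op == "+":
                return as_matrix(a + b)
            if op == "-":
                return as_matrix(a - b)
            if op == ".*":
                return as_matrix(a * b)
            if op == "./":
                return as_matrix(self._div(a, b))
            if op == ".^":
                return as_matrix(np.power(a, b))
            if op == "*":
                if a.size == 1 or b.size == 1:
                    return as_matrix(a * b)
                if a.shape[1] != b.shape[0]:
                    _fail(f"matrix product inner dimensions disagree: "
                          f"{a.shape} * {b.shape}", n.loc)
                return as_matrix(a @ b)
            if op == "/":
                if b.size != 1:
                    _fail("'/' requires a scalar divisor (vector or matrix "
                          "denominators are undefined; use './')", n.loc)
                return as_matrix(self._div(a, b))
            if op == "^":
                if a.size != 1 or b.size != 1:
                    _fail("'^' is defined for scalars only; use '.^'", n.loc)
                return as_matrix(float(a.flat[0]) ** float(b.flat[0]))
            if op in ("==", "~=", "<", "<=", ">", ">="):
                fn = {"==": np.equal, "~=": np.not_equal, "<": np.less,
                      "<=": np.less_equal, ">": np.greater, ">=": np.greater_equal}[op]
                return as_matrix(fn(a, b))
            if op == "&":
                return as_matrix((a != 0) & (b != 0))
            if op == "|":
                return as_matrix((a != 0) | (b != 0))
        except ValueError as exc:
            _fail(f"shape mismatch in '{op}': {exc}", n.loc)
        _fail(f"unsupported operator {op}", n.loc)

    @staticmethod
    def _div(a, b):
        with np.errstate(divide="ignore", invalid="ignore"):
            return a / b

    def eval_range(self, n: Node, env):
        parts = [to_scalar(self.eval(c, env), n.loc) for c in n.children]
        if len(parts) == 2:
            start, step, stop = parts[0], 1.0, parts[1]
        else:
            start, step, stop = parts
        if step == 0:
            return as_matrix(np.zeros((1, 0)))
        count = int(np.floor((stop - start) / step + 1e-10))
        if count < 0:
            return as_matrix(np.zeros((1, 0)))
        return as_matrix((start + step * np.arange(count + 1)).reshape(1, -1))

    def eval_matrix_literal(self, n: Node, env):
        if not n.children:
            return as_matrix(np.zeros((0, 0)))
        rows = []
        for row in n.children:
            parts = [as_matrix(self.eval(el, env)) for el in row.children]
            parts = [p for p in parts if p.size or p.shape[0]]
            try:
                rows.append(np.hstack(parts) if parts else np.zeros((1, 0)))
            except ValueError:
                _fail("inconsistent row heights in matrix literal", n.loc)
        try:
            return as_matrix(np.vstack(rows))
        except ValueError:
            _fail("inconsistent column counts in matrix literal", n.loc)

    # -- indexing ----------------------------------------------------------
    def subscript(self, sub: Node, base: np.ndarray, env, dim, loc):
        """Evaluate one subscript to a 1-based integer index array or a
        full slice.  `dim` is 0/1 for two-subscript forms, None for linear."""
        if sub.kind == "colon_all":
            return slice(None)
        extent = base.size if dim is None else base.shape[dim]
        if self._contains_end(sub):
            env = dict(env)
            env["__end__"] = as_matrix(float(extent))
        v = self.eval(self._rewrite_end(sub), env)
        a = as_matrix(v)
        if a.dtype == bool:
            if a.size != extent:
                _fail("logical index does not match extent", loc)
            return np.flatnonzero(a.reshape(-1, order="F")) + 1
        idx = a.reshape(-1, order="F")
        if idx.size and not np.allclose(idx, np.round(idx)):
            _fail("subscripts must be integers or logicals", loc)
        return np.round(idx).astype(int)

    @staticmethod
    def _contains_end(n: Node) -> bool:
        return any(c.kind == "end_marker" for c in n.iter_nodes())

    _END_CACHE: dict = {}

    def _rewrite_end(self, n: Node) -> Node:
        """Replace end markers with a read of the __end__ pseudo-variable."""
        if not self._contains_end(n):
            return n
        key = id(n)
        if key in self._END_CACHE:
            return self._END_CACHE[key]
        import copy as _copymod

        def rw(m: Node) -> Node:
            if m.kind == "end_marker":
                repl = Node("identifier", loc=m.loc, name="__end__")
                repl._binding = (VAR, None)  # type: ignore[attr-defined]
                return repl
            m2 = _copymod.copy(m)
            m2.children = [rw(c) for c in m.children]
            return m2

        out = rw(n)
        self._END_CACHE[key] = out
        return out

    def index_read(self, base: np.ndarray, subs: List[Node], env, loc):
        if len(subs) == 1:
            idx = self.subscript(subs[0], base, env, dim=None, loc=loc)
            flat = base.reshape(-1, order="F")
            if isinstance(idx, slice):
                return as_matrix(flat.reshape(-1, 1))
            if idx.size and (idx.min() < 1 or idx.max() > base.size):
                _fail(f"index out of range: {int(idx.max()) if idx.size else 0} "
                      f"of {base.size} elements", loc)
            out = flat[idx - 1]
            if out.size == 1:
                return as_matrix(float(out[0]))
            # orientation follows the indexed array for vector bases
            if base.shape[0] == 1:
                return as_matrix(out.reshape(1, -1))
            if base.shape[1] == 1:
                return as_matrix(out.reshape(-1, 1))
            return as_matrix(out.reshape(1, -1))
        if len(subs) == 2:
            ri = self.subscript(subs[0], base, env, dim=0, loc=loc)
            ci = self.subscript(subs[1], base, env, dim=1, loc=loc)
            if isinstance(ri, slice):
                ri = np.arange(1, base.shape[0] + 1)
            if isinstance(ci, slice):
                ci = np.arange(1, base.shape[1] + 1)
            if (ri.size and (ri.min() < 1 or ri.max() > base.shape[0])) or \
                    (ci.size and (ci.min() < 1 or ci.max() > base.shape[1])):
                _fail(f"subscript out of range for shape {base.shape}", loc)
            out = base[np.ix_(ri - 1, ci - 1)]
            if out.size == 1:
                return as_matrix(float(out.flat[0]))
            return as_matrix(out)
        _fail("more than two subscripts are unsupported", loc)

    # -- calls -------------------------------------------------------------
    def eval_call(self, n: Node, env, n_out: int) -> List[object]:
        base = n.children[0]
        args_nodes = n.children[1:]
        if base.kind == "identifier":
            kind, payload = getattr(base, "_binding", (None, None))
            if kind == VAR:
                bv = env.get(base.name)
                if isinstance(bv, MFunction):
                    args = [self.eval(a, env) for a in args_nodes]
                    return self.call_handle(bv, args, n_out, n.loc)
                return [self.index_read(as_matrix(bv), args_nodes, env, n.loc)]
            if kind == BUILTIN:
                return self.dispatch_builtin(payload, args_nodes, env, n_out, n.loc)
            if kind == FUNC:
                args = [_copy(self.eval(a, env)) for a in args_nodes]
                return self.call_function(payload.node, args, n_out, n.loc)
        bv = self.eval(base, env)
        if isinstance(bv, MFunction):
            args = [self.eval(a, env) for a in args_nodes]
            return self.call_handle(bv, args, n_out, n.loc)
        return [self.index_read(as_matrix(bv), args_nodes, env, n.loc)]

    def call_handle(self, fn: MFunction, args, n_out: int, loc) -> List[object]:
        if fn.kind == "builtin":
            return self.call_builtin(fn.name, args, n_out, loc, {})
        if fn.kind == "named":
            return self.call_function(fn.node, [_copy(a) for a in args], n_out, loc)
        node = fn.node
        inner = dict(fn.closure or {})
        params = node.params or []
        if len(args) < len(params):
            _fail(f"anonymous function expects {len(params)} arguments", loc)
        for p, a in zip(params, args):
            inner[p] = _copy(a)
        return [self.eval(node.children[0], inner)]

    def call_function(self, fnode: Node, args, n_out: int, loc) -> List[object]:
        params = fnode.params or []
        if len(args) > len(params):
            _fail(f"function {fnode.name!r} takes {len(params)} arguments", loc)
        env: Dict[str, object] = dict(zip(params, args))
        try:
            self.exec_block(fnode.children, env)
        except _Return:
            pass
        outs = []
        for o in fnode.outs or []:
            if o not in env:
                _fail(f"output {o!r} of {fnode.name!r} not assigned", loc)
            outs.append(_copy(env[o]))
        if not outs:
            outs = [as_matrix(0.0)]
        return outs

    # -- builtins ------------------------------------------------------------
    def dispatch_builtin(self, name: str, arg_nodes: List[Node], env,
                         n_out: int, loc) -> List[object]:
        if name in ("ode45", "ode23", "ode15s"):
            return self.run_ode(name, arg_nodes, env, loc)
        args = [self.eval(a, env) for a in arg_nodes]
        return self.call_builtin(name, args, n_out, loc, env)

    def call_builtin(self, name: str, args, n_out: int, loc, env) -> List[object]:
        A = as_matrix
        try:
            if name == "pi":
                return [A(np.pi)]
            if name in ("zeros", "ones", "eye", "rand", "randn"):
                dims = [int(to_scalar(a, loc)) for a in args] or [1]
                r, c = (dims[0], dims[0]) if len(dims) == 1 else dims[:2]
                if name == "zeros":
                    return [A(np.zeros((r, c)))]
                if name == "ones":
                    return [A(np.ones((r, c)))]
                if name == "eye":
                    return [A(np.eye(r, c))]
                if name == "rand":
                    return [A(self.rng.random((r, c)))]
                return [A(self.rng.standard_normal((r, c)))]
            if name == "size":
                if n_out >= 2 and len(args) == 1:
                    m = A(args[0])
                    return [A(float(m.shape[0])), A(float(m.shape[1]))]
                return [bi.mat_size(*args)]
            if name == "length":
                return [bi.mat_length(args[0])]
            if name == "numel":
                return [A(float(A(args[0]).size))]
            if name in ("abs", "exp", "log", "log10", "sqrt", "sin", "cos",
                        "tan", "floor", "ceil", "round"):
                fn = {"abs": np.abs, "exp": np.exp, "log": np.log,
                      "log10": np.log10, "sqrt": np.sqrt, "sin": np.sin,
                      "cos": np.cos, "tan": np.tan, "floor": np.floor,
                      "ceil": np.ceil, "round": np.round}[name]
                with np.errstate(divide="ignore", invalid="ignore"):
                    return [A(fn(A(args[0])))]
            if name == "mod":
                return [A(np.mod(A(args[0]), A(args[1])))]
            if name == "rem":
                return [A(np.fmod(A(args[0]), A(args[1])))]
            if name == "min":
                return [bi.mat_min(*args)]
            if name == "max":
                return [bi.mat_max(*args)]
            if name == "sum":
                return [bi.mat_sum(args[0])]
            if name == "prod":
                return [bi.mat_prod(args[0])]
            if name == "any":
                return [A(bool(np.any(A(args[0]) != 0)))]
            if name == "all":
                return [A(bool(np.all(A(args[0]) != 0)))]
            if name == "isempty":
                return [A(A(args[0]).size == 0)]
            if name == "linspace":
                return [bi.mat_linspace(*args)]
            if name == "interp1":
                return [bi.builtin_interp1(*args)]
            if name == "setdiff":
                return [bi.builtin_setdiff(*args)]
            if name == "union":
                return [bi.builtin_union(*args)]
            if name == "unique":
                return [bi.mat_unique(args[0])]
            if name == "sort":
                return [bi.mat_sort(args[0])]
            if name == "find":
                return [bi.mat_find(args[0])]
            if name == "repmat":
                return [bi.mat_repmat(*args)]
            if name == "norm":
                return [bi.mat_norm(args[0])]
            if name == "dot":
                a = A(args[0]).reshape(-1, order="F")
                b = A(args[1]).reshape(-1, order="F")
                return [A(float(np.dot(a, b)))]
            if name == "load":
                if not isinstance(args[0], str):
                    _fail("load expects a file name string", loc)
                return [bi.builtin_load(args[0], self.load_dirs)]
            if name in ("disp", "fprintf"):
                return [A(0.0)]
            if name == "odeset":
                opts: Dict[str, object] = {}
                for i in range(0, len(args) - 1, 2):
                    if isinstance(args[i], str):
                        opts[args[i].lower()] = args[i + 1]
                return [opts]
        except TypeError as exc:
            _fail(f"bad arguments to builtin {name!r}: {exc}", loc)
        _fail(f"builtin {name!r} is not implemented", loc)

    def run_ode(self, solver: str, arg_nodes: List[Node], env, loc) -> List[object]:
        if len(arg_nodes) < 3:
            _fail(f"{solver} expects (rhs, tspan, y0)", loc)
        handle = self.eval(arg_nodes[0], env)
        if not isinstance(handle, MFunction):
            _fail(f"{solver}: first argument must be a function handle", loc)
        tspan = as_matrix(self.eval(arg_nodes[1], env)).reshape(-1, order="F")
        y0 = as_matrix(self.eval(arg_nodes[2], env)).reshape(-1, order="F")
        rtol, atol = self.options.rtol, self.options.atol
        if len(arg_nodes) >= 4:
            opts = self.eval(arg_nodes[3], env)
            if isinstance(opts, dict):
                if "reltol" in opts:
                    rtol = to_scalar(opts["reltol"], loc)
                if "abstol" in opts:
                    atol = to_scalar(opts["abstol"], loc)
        family = "stiff" if solver == "ode15s" else "nonstiff"

        def rhs(t, y):
            out = self.call_handle(
                handle, [as_matrix(float(t)), as_matrix(y.reshape(-1, 1))], 1, loc)[0]
            return as_matrix(out).reshape(-1, order="F")

        problem = OdeProblem(rhs=rhs, y0=y0, t_span=(float(tspan[0]), float(tspan[-1])),
                             rtol=rtol, atol=atol, family=family)
        grid = np.linspace(problem.t_span[0], problem.t_span[1],
                           self.options.grid_points)
        ts = solve_ode(problem, grid, guard=self.options.guard_out_of_bounds)
        self.timeseries.append(ts)
        return [as_matrix(ts.times.reshape(-1, 1)), as_matrix(ts.states)]


def evaluate(program: ProgramGraph,
             options: Optional[RunOptions] = None
             ) -> Tuple[Dict[str, object], List[Timeseries]]:
    """Execute the entry script; returns (final environment, timeseries list).

    The program must already be scope-resolved (run :func:`mat2c.sema.analyze`
    first); identifier bindings recorded there drive name resolution here.
    """
    return Interpreter(program, options).run()
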