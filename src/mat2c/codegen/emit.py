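"""C99 back end: translate an annotated tree to compilable C text.

Translation strategy:

* every dialect value is either a plain C ``double`` (variables inferred as
  real/logical scalars) or an ``m2c_mat`` (everything array-valued or
  dynamic), with 1-based subscripts translated to the runtime's accessors
  and column-major layout throughout;
* struct variables are flattened to one C variable per field
  (``p.alpha`` -> ``v_p__alpha``), which covers the parameter-bag style of
  the dialect subset;
* each ``[t, y] = odeXX(rhs, tspan, y0)`` statement becomes a dedicated
  right-hand-side C function (captured variables passed via a context
  struct) wired to the bundled integrator, plus a timeseries dump;
* every translated statement is preceded by a comment quoting its source
  line, and the emitted-line -> source-line map is returned alongside.

Assignments into matrix variables copy (`m2c_copy`), preserving the
dialect's value semantics without requiring static single assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from ..diagnostics import (CompileError, E_UNSUPPORTED, SourceLocation, error)
from ..frontend.astnodes import Node
from ..sema.infer import AnnotatedTree
from ..sema.scopes import BUILTIN, FUNC, VAR
from ..sema.types import Base, Type
from .builtins import map_builtin
from .c_runtime import RUNTIME_C, RUNTIME_H

_ODE_SOLVERS = {"ode45": 0, "ode23": 0, "ode15s": 1}

_BIN_TAGS = {"+": "M2C_ADD", "-": "M2C_SUB", ".*": "M2C_MUL", "./": "M2C_DIV",
             ".^": "M2C_POW", "*": "M2C_MATMUL", "/": "M2C_SDIV",
             "==": "M2C_EQ", "~=": "M2C_NE", "<": "M2C_LT", "<=": "M2C_LE",
             ">": "M2C_GT", ">=": "M2C_GE", "&": "M2C_AND", "|": "M2C_OR"}

_D_OPS = {"+": "({} + {})", "-": "({} - {})", "*": "({} * {})", "/": "({} / {})",
          ".*": "({} * {})", "./": "({} / {})",
          "^": "pow({}, {})", ".^": "pow({}, {})",
          "==": "(({} == {}) ? 1.0 : 0.0)", "~=": "(({} != {}) ? 1.0 : 0.0)",
          "<": "(({} < {}) ? 1.0 : 0.0)", "<=": "(({} <= {}) ? 1.0 : 0.0)",
          ">": "(({} > {}) ? 1.0 : 0.0)", ">=": "(({} >= {}) ? 1.0 : 0.0)",
          "&": "((({} != 0.0) && ({} != 0.0)) ? 1.0 : 0.0)",
          "|": "((({} != 0.0) || ({} != 0.0)) ? 1.0 : 0.0)",
          "&&": "((({} != 0.0) && ({} != 0.0)) ? 1.0 : 0.0)",
          "||": "((({} != 0.0) || ({} != 0.0)) ? 1.0 : 0.0)"}


@dataclass
class CodegenOptions:
    rtol: float = 1e-3
    atol: float = 1e-6
    grid_points: int = 200
    guard_out_of_bounds: bool = True

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("rtol and atol must be positive")


@dataclass
class EmittedUnit:
    dialect: str                    # "c99_source" | "c99_header"
    name: str
    text: str
    line_map: Dict[int, Tuple[str, int]] = field(default_factory=dict)


def _cnum(v: float) -> str:
    s = f"{float(v):.17g}"
    if "." not in s and "e" not in s and "n" not in s and "i" not in s:
        s += ".0"
    return s


def _comment_escape(s: str) -> str:
    return s.replace("*/", "* /")


class _Unsupported(CompileError):
    pass


def _unsup(msg: str, loc: Optional[SourceLocation] = None):
    raise _Unsupported(error(E_UNSUPPORTED, msg, loc))


class CEmitter:
    def __init__(self, tree: AnnotatedTree, opts: Optional[CodegenOptions] = None):
        self.tree = tree
        self.program = tree.program
        self.opts = opts or CodegenOptions()
        self.lines: List[str] = []
        self.line_map: Dict[int, Tuple[str, int]] = {}
        self.indent = 0
        self.prelude: List[str] = []
        self.tmp_n = 0
        self.fn_names: Dict[int, str] = {}
        self.fn_nodes: List[Node] = []
        self.rhs_units: List[str] = []      # emitted rhs wrapper text blocks
        self.rhs_protos: List[str] = []
        self.rhs_n = 0
        self.cur_unit = ""
        self.symtab: Dict[str, str] = {}
        self.overrides: Dict[str, Tuple[str, str]] = {}
        self.end_ctx: List[Tuple[str, int, int]] = []
        self.in_function: Optional[Node] = None
        self._collect_functions()

    # ------------------------------------------------------------------
    def _collect_functions(self):
        def walk(fnode: Node, prefix: str):
            name = f"{prefix}{fnode.name}"
            self.fn_names[id(fnode)] = f"mf_{name}"
            self.fn_nodes.append(fnode)
            for sub in fnode.subfunctions or []:
                walk(sub, f"{name}__")

        for uname, root in self.program.units.items():
            if root.kind == "function_def":
                walk(root, "")
            else:
                for sub in root.subfunctions or []:
                    walk(sub, "")

    # -- variable classification ---------------------------------------
    @staticmethod
    def _class_of(t: Type) -> str:
        if t.base in (Base.REAL, Base.LOGICAL):
            return "d" if t.shape.is_scalar else "m"
        if t.base is Base.STRING:
            return "s"
        if t.base is Base.FUNC_HANDLE:
            return "h"
        if t.base is Base.STRUCT:
            return "x"
        return "m"

    def _env_for(self, key_prefix: str, exact: Optional[str] = None):
        from ..sema.types import join, BaseConflict, UNKNOWN
        merged: Dict[str, Type] = {}
        for key, env in self.tree.var_types.items():
            if exact is not None:
                if key != exact:
                    continue
            elif not key.startswith(key_prefix + "("):
                continue
            for name, t in env.items():
                if name in merged:
                    try:
                        merged[name], _ = join(merged[name], t)
                    except BaseConflict:
                        merged[name] = UNKNOWN
                else:
                    merged[name] = t
        return merged

    def _struct_fields(self, root: Node) -> Dict[str, Dict[str, str]]:
        """var -> {field -> class} discovered from field accesses."""
        out: Dict[str, Dict[str, str]] = {}
        for n in root.iter_nodes():
            if n.kind == "function_def" and n is not root:
                continue
            if n.kind == "field_access" and n.children[0].kind == "identifier":
                var = n.children[0].name
                t = self.tree.type_of(n)
                cls = self._class_of(t) if not t.is_unknown else "m"
                cur = out.setdefault(var, {})
                if n.name not in cur or cur[n.name] == "m":
                    if cls in ("d", "m"):
                        cur[n.name] = cls
        return out

    # -- emission helpers ------------------------------------------------
    def w(self, line: str, src: Optional[Tuple[str, int]] = None):
        self.lines.append("    " * self.indent + line)
        if src is not None:
            self.line_map[len(self.lines)] = src

    def flush_prelude(self):
        for ln in self.prelude:
            self.lines.append("    " * self.indent + ln)
        self.prelude = []

    def tmp(self, ctype: str, init: Optional[str] = None) -> str:
        self.tmp_n += 1
        name = f"__t{self.tmp_n}"
        self.prelude.append(f"{ctype} {name}{' = ' + init if init else ''};")
        return name

    @staticmethod
    def to_d(code: str, cls: str) -> str:
        if cls == "d":
            return code
        if cls == "m":
            return f"m2c_item({code})"
        raise _Unsupported(error(E_UNSUPPORTED, f"expected numeric value, got {cls!r}"))

    @staticmethod
    def to_m(code: str, cls: str) -> str:
        if cls == "m":
            return code
        if cls == "d":
            return f"m2c_scal({code})"
        raise _Unsupported(error(E_UNSUPPORTED, f"expected numeric value, got {cls!r}"))

    def var_class(self, name: str) -> str:
        return self.symtab.get(name, "m")

    # -- top level --------------------------------------------------------
    def emit(self) -> List[EmittedUnit]:
        if self.tree.errors:
            raise CompileError(self.tree.errors)
        model = self.program.entry
        header = self._emit_header(model)
        self._emit_source(model)
        src_text = "\n".join(self.lines) + "\n"
        return [
            EmittedUnit("c99_header", f"{model}.h", header),
            EmittedUnit("c99_source", f"{model}.c", src_text, dict(self.line_map)),
        ]

    def _emit_header(self, model: str) -> str:
        lines = [
            f"#ifndef M2C_MODEL_{model.upper()}_H",
            f"#define M2C_MODEL_{model.upper()}_H",
            '#include "m2c_rt.h"',
            "",
            "void model_main(void);",
        ]
        for fnode in self.fn_nodes:
            lines.append(self._fn_signature(fnode) + ";")
        lines += ["", "#endif"]
        return "\n".join(lines) + "\n"

    def _fn_signature(self, fnode: Node) -> str:
        cname = self.fn_names[id(fnode)]
        parts = [f"m2c_mat v_{p}" for p in (fnode.params or [])]
        parts += [f"m2c_mat *out_{o}" for o in (fnode.outs or [])]
        return f"void {cname}({', '.join(parts) or 'void'})"

    def _emit_source(self, model: str):
        w = self.w
        w(f'#include "{model}.h"')
        w("#include <math.h>")
        w("#include <stdlib.h>")
        w("")
        w(f"#define M2C_RTOL {_cnum(self.opts.rtol)}")
        w(f"#define M2C_ATOL {_cnum(self.opts.atol)}")
        w(f"#define M2C_GRID {self.opts.grid_points}")
        w("")
        w("static int m2c_ts_counter = 0;")
        proto_anchor = len(self.lines)   # rhs wrapper prototypes inserted here
        w("")
        for fnode in self.fn_nodes:
            self._emit_function(fnode)
        body_anchor = len(self.lines)    # rhs wrapper bodies inserted here
        self._emit_model_main()
        self._emit_c_main()
        # splice in the ODE right-hand-side wrappers collected while walking
        wrappers = []
        for block in self.rhs_units:
            wrappers.extend(block.split("\n"))
        pre = self.lines[:body_anchor]
        post = self.lines[body_anchor:]
        shift_at = body_anchor
        self.lines = pre + wrappers + post
        self.line_map = {(k + len(wrappers) if k > shift_at else k): v
                         for k, v in self.line_map.items()}
        protos = self.rhs_protos
        self.lines = self.lines[:proto_anchor] + protos + self.lines[proto_anchor:]
        self.line_map = {(k + len(protos) if k > proto_anchor else k): v
                         for k, v in self.line_map.items()}

    def _emit_c_main(self):
        w = self.w
        w("")
        w("int main(int argc, char **argv) {")
        self.indent += 1
        w("m2c_outdir = (argc > 1) ? argv[1] : \".\";")
        w("if (argc > 2) m2c_seed((unsigned long)atol(argv[2]));")
        w("m2c_env_open(m2c_outdir);")
        w("model_main();")
        w("m2c_env_close();")
        w("return 0;")
        self.indent -= 1
        w("}")

    # -- functions ---------------------------------------------------------
    def _source_line(self, loc: Optional[SourceLocation]) -> Optional[Tuple[str, str, int]]:
        if loc is None:
            return None
        src = None
        for uname, unit in self.program.sources.items():
            if unit.path == loc.unit:
                src = unit
                break
        if src is None:
            return None
        lines = src.text.replace("\r\n", "\n").split("\n")
        if 1 <= loc.line <= len(lines):
            return (loc.unit, lines[loc.line - 1].strip(), loc.line)
        return None

    def stmt_comment(self, st: Node):
        info = self._source_line(st.loc)
        if info:
            unit, text, lineno = info
            self.w(f"/* {unit}:{lineno}: {_comment_escape(text)} */",
                   src=(unit, lineno))

    def _emit_function(self, fnode: Node):
        env = self._env_for(fnode.name)
        saved = (self.symtab, self.in_function, self.overrides)
        struct_fields = self._struct_fields(fnode)
        self.symtab = self._build_symtab(env, struct_fields)
        for p in fnode.params or []:
            self.symtab[p] = "m"          # uniform mat calling convention
        self.in_function = fnode
        self.overrides = {}
        self.w(self._fn_signature(fnode) + " {")
        self.indent += 1
        self._declare_locals(exclude=set(fnode.params or []))
        for st in fnode.children:
            self.emit_stmt(st)
        if self._has_return(fnode.children):
            self.w("m2c_done: ;")
        for o in fnode.outs or []:
            cls = self.var_class(o)
            self.w(f"*out_{o} = {self.to_m('v_' + o, cls)};")
        self.indent -= 1
        self.w("}")
        self.w("")
        self.symtab, self.in_function, self.overrides = saved

    @staticmethod
    def _has_return(stmts) -> bool:
        def walk(ns):
            for s in ns:
                if s.kind == "return":
                    return True
                if walk(s.children):
                    return True
            return False
        return walk(stmts)

    def _build_symtab(self, env, struct_fields) -> Dict[str, str]:
        tab: Dict[str, str] = {}
        for name, t in env.items():
            tab[name] = self._class_of(t)
        for var, fields in struct_fields.items():
            tab[var] = "x"
            for f, cls in fields.items():
                tab[f"{var}__{f}"] = cls
        return tab

    def _declare_locals(self, exclude=frozenset()):
        for name, cls in self.symtab.items():
            if name in exclude or name.startswith("__"):
                continue
            if cls == "d":
                self.w(f"double v_{name} = 0.0;")
            elif cls == "m":
                self.w(f"m2c_mat v_{name} = m2c_empty();")
            elif cls == "s":
                self.w(f"const char *v_{name} = \"\";")
            # "h" (handles) and "x" (struct bags) have no C storage

    def _emit_model_main(self):
        root = self.program.entry_node
        env = self.tree.var_types.get(self.program.entry, {})
        struct_fields = self._struct_fields(root)
        self.symtab = self._build_symtab(env, struct_fields)
        self.in_function = None
        self.overrides = {}
        self.w("void model_main(void) {")
        self.indent += 1
        self._declare_locals()
        for st in root.children:
            self.emit_stmt(st)
        if self._has_return(root.children):
            self.w("m2c_done: ;")
        for name, cls in self.symtab.items():
            if name.startswith("__"):
                continue
            if cls == "d":
                self.w(f'm2c_env_write_scalar("{name}", v_{name});')
            elif cls == "m":
                self.w(f'm2c_env_write("{name}", v_{name});')
            elif cls == "x":
                continue
        # flattened struct fields are written under dotted names
        for name, cls in self.symtab.items():
            if "__" in name and not name.startswith("__") and cls in ("d", "m"):
                var, fieldname = name.split("__", 1)
                if self.symtab.get(var) == "x":
                    dotted = f"{var}.{fieldname}"
                    if cls == "d":
                        self.w(f'm2c_env_write_scalar("{dotted}", v_{name});')
                    else:
                        self.w(f'm2c_env_write("{dotted}", v_{name});')
        self.indent -= 1
        self.w("}")

    # -- statements ---------------------------------------------------------
    def emit_stmt(self, st: Node):
        k = st.kind
        if k == "assignment":
            self.stmt_comment(st)
            self._emit_assignment(st)
        elif k == "expr_stmt":
            self.stmt_comment(st)
            code, cls = self.emit_expr(st.children[0])
            self.flush_prelude()
            if cls == "m":
                self.w(f"(void)({code}).rows;")
            else:
                self.w(f"(void)({code});")
        elif k == "if":
            self.stmt_comment(st)
            self._emit_if(st)
        elif k == "for":
            self.stmt_comment(st)
            self._emit_for(st)
        elif k == "while":
            self.stmt_comment(st)
            self._emit_while(st)
        elif k == "break":
            self.stmt_comment(st)
            self.w("break;")
        elif k == "continue":
            self.stmt_comment(st)
            self.w("continue;")
        elif k == "return":
            self.stmt_comment(st)
            self.w("goto m2c_done;")
        else:
            _unsup(f"statement kind {k} not supported by the C backend", st.loc)

    def _emit_assignment(self, st: Node):
        lhs, rhs = st.children
        # ODE special form
        if rhs.kind == "call" and rhs.children[0].kind == "identifier":
            binding = getattr(rhs.children[0], "_binding", (None, None))
            if binding[0] == BUILTIN and rhs.children[0].name in _ODE_SOLVERS:
                self._emit_ode(st, lhs, rhs)
                return
        if lhs.kind == "matrix_literal":
            self._emit_multi_assign(lhs, rhs)
            return
        # handle-typed variables exist only statically
        if lhs.kind == "identifier" and self.var_class(lhs.name) == "h":
            self.flush_prelude()
            return
        if lhs.kind == "identifier" and self.var_class(lhs.name) == "x":
            self.flush_prelude()
            return
        code, cls = self.emit_expr(rhs)
        self.flush_prelude()
        self._store(lhs, code, cls)

    def _store(self, lhs: Node, code: str, cls: str):
        if lhs.kind == "identifier":
            tcls = self.var_class(lhs.name)
            if tcls == "d":
                self.w(f"v_{lhs.name} = {self.to_d(code, cls)};")
            elif tcls == "s":
                self.w(f"v_{lhs.name} = {code};")
            elif tcls == "m":
                self.w(f"v_{lhs.name} = m2c_copy({self.to_m(code, cls)});")
            return
        if lhs.kind == "field_access" and lhs.children[0].kind == "identifier":
            flat = f"{lhs.children[0].name}__{lhs.name}"
            tcls = self.var_class(flat)
            if tcls == "d":
                self.w(f"v_{flat} = {self.to_d(code, cls)};")
            else:
                self.w(f"v_{flat} = m2c_copy({self.to_m(code, cls)});")
            return
        if lhs.kind in ("index", "call"):
            base = lhs.children[0]
            if base.kind != "identifier":
                _unsup("indexed assignment target must be a variable", lhs.loc)
            subs = lhs.children[1:]
            target = f"v_{base.name}"
            sub_parts = []
            scalar_ok = cls == "d" and len(subs) <= 2
            for i, sub in enumerate(subs):
                if sub.kind == "colon_all":
                    sub_parts.append(("m2c_colon_all()", "m"))
                    scalar_ok = False
                else:
                    dim = 0 if len(subs) == 1 else i
                    self.end_ctx.append((target, dim, len(subs)))
                    sc, scls = self.emit_expr(sub)
                    self.end_ctx.pop()
                    sub_parts.append((sc, scls))
                    if scls != "d":
                        scalar_ok = False
            if scalar_ok and len(subs) == 1:
                self.w(f"m2c_set1(&{target}, {sub_parts[0][0]}, {code});")
            elif scalar_ok and len(subs) == 2:
                self.w(f"m2c_set2(&{target}, {sub_parts[0][0]}, "
                       f"{sub_parts[1][0]}, {code});")
            elif len(subs) == 1:
                self.w(f"m2c_seti1(&{target}, "
                       f"{self.to_m(*sub_parts[0])}, {self.to_m(code, cls)});")
            elif len(subs) == 2:
                self.w(f"m2c_seti2(&{target}, {self.to_m(*sub_parts[0])}, "
                       f"{self.to_m(*sub_parts[1])}, {self.to_m(code, cls)});")
            else:
                _unsup("more than two subscripts are unsupported", lhs.loc)
            return
        _unsup("unsupported assignment target", lhs.loc)

    def _emit_multi_assign(self, lhs: Node, rhs: Node):
        targets = lhs.children[0].children
        if rhs.kind == "call" and rhs.children[0].kind == "identifier":
            binding = getattr(rhs.children[0], "_binding", (None, None))
            if binding[0] == FUNC:
                fnode = binding[1].node
                args = [self.to_m(*self.emit_expr(a)) for a in rhs.children[1:]]
                outs = [self.tmp("m2c_mat") for _ in fnode.outs or []]
                self.flush_prelude()
                call_args = args + [f"&{o}" for o in outs]
                self.w(f"{self.fn_names[id(fnode)]}({', '.join(call_args)});")
                for tgt, o in zip(targets, outs):
                    self._store(tgt, o, "m")
                return
            if binding[0] == BUILTIN and rhs.children[0].name == "size":
                arg = self.to_m(*self.emit_expr(rhs.children[1]))
                t = self.tmp("m2c_mat", f"m2c_size({arg})")
                self.flush_prelude()
                self._store(targets[0], f"m2c_get1({t}, 1.0)", "d")
                if len(targets) > 1:
                    self._store(targets[1], f"m2c_get1({t}, 2.0)", "d")
                return
        _unsup("multi-output assignment is supported for user functions, "
               "size, and ODE solvers", lhs.loc)

    # -- control flow -------------------------------------------------------
    def _cond(self, n: Node) -> str:
        code, cls = self.emit_expr(n)
        if cls == "m":
            return f"m2c_truth({code})"
        return f"({code} != 0.0)"

    def _emit_if(self, st: Node):
        cond = self._cond(st.children[0])
        self.flush_prelude()
        self.w(f"if ({cond}) {{")
        self.indent += 1
        for s in st.children[1].children:
            self.emit_stmt(s)
        self.indent -= 1
        nest = 0  # elseif chains emit as nested else { if ... } blocks so
        #           condition preludes run only when earlier branches failed
        for br in st.children[2:]:
            if br.kind == "elseif_branch":
                self.w("} else {")
                self.indent += 1
                nest += 1
                cond = self._cond(br.children[0])
                self.flush_prelude()
                self.w(f"if ({cond}) {{")
                self.indent += 1
                for s in br.children[1].children:
                    self.emit_stmt(s)
                self.indent -= 1
            else:
                self.w("} else {")
                self.indent += 1
                for s in br.children[0].children:
                    self.emit_stmt(s)
                self.indent -= 1
        self.w("}")
        for _ in range(nest):
            self.indent -= 1
            self.w("}")

    def _emit_for(self, st: Node):
        it = st.children[0]
        var = st.name
        vcls = self.var_class(var)
        self.w("{")
        self.indent += 1
        if it.kind == "range":
            parts = [self.to_d(*self.emit_expr(c)) for c in it.children]
            if len(parts) == 2:
                a, s, b = parts[0], "1.0", parts[1]
            else:
                a, s, b = parts
            ta = self.tmp("double", a)
            tsv = self.tmp("double", s)
            tb = self.tmp("double", b)
            tn = self.tmp("int", f"m2c_range_count({ta}, {tsv}, {tb})")
            tk = self.tmp("int", "0")
            self.flush_prelude()
            self.w(f"for ({tk} = 0; {tk} < {tn}; {tk}++) {{")
            self.indent += 1
            if vcls == "d":
                self.w(f"v_{var} = {ta} + {tsv} * {tk};")
            else:
                self.w(f"v_{var} = m2c_scal({ta} + {tsv} * {tk});")
        else:
            seq_code = self.to_m(*self.emit_expr(it))
            tseq = self.tmp("m2c_mat", seq_code)
            tk = self.tmp("int", "0")
            self.flush_prelude()
            self.w(f"for ({tk} = 0; {tk} < {tseq}.cols; {tk}++) {{")
            self.indent += 1
            if vcls == "d":
                self.w(f"v_{var} = m2c_get1({tseq}, (double)({tk} + 1));")
            else:
                self.w(f"v_{var} = m2c_index2({tseq}, m2c_colon_all(), "
                       f"m2c_scal((double)({tk} + 1)));")
        for s in st.children[1].children:
            self.emit_stmt(s)
        self.indent -= 1
        self.w("}")
        self.indent -= 1
        self.w("}")

    def _emit_while(self, st: Node):
        self.w("for (;;) {")
        self.indent += 1
        cond = self._cond(st.children[0])
        self.flush_prelude()
        self.w(f"if (!{cond}) break;")
        for s in st.children[1].children:
            self.emit_stmt(s)
        self.indent -= 1
        self.w("}")

    # -- ODE ------------------------------------------------------------------
    def _handle_target(self, n: Node) -> Tuple[str, Optional[Node]]:
        """Resolve the static target of an ODE handle argument.

        Returns ("anon", node) or ("named", function_def node)."""
        if n.kind == "anonymous_function":
            return "anon", n
        if n.kind == "func_handle":
            kind, payload = getattr(n, "_binding", (None, None))
            if kind == FUNC:
                return "named", payload.node
            _unsup(f"cannot resolve handle @{n.name}", n.loc)
        if n.kind == "identifier":
            target = getattr(n, "_handle_def", None)
            if target is None:
                owner = self.in_function or self.program.entry_node
                for node in owner.iter_nodes():
                    if node.kind == "assignment" and \
                            node.children[0].kind == "identifier" and \
                            node.children[0].name == n.name:
                        rhs = node.children[1]
                        if rhs.kind == "anonymous_function":
                            target = rhs
                            break
                        if rhs.kind == "func_handle":
                            k2, p2 = getattr(rhs, "_binding", (None, None))
                            if k2 == FUNC:
                                target = p2.node
                                break
            if target is None:
                _unsup(f"cannot statically resolve ODE handle {n.name!r}", n.loc)
            if target.kind == "anonymous_function":
                return "anon", target
            return "named", target
        _unsup("unsupported ODE right-hand-side argument", n.loc)

    def _free_idents(self, body: Node, params) -> List[str]:
        seen, out = set(params or []), []
        for m in body.iter_nodes():
            if m.kind == "identifier":
                kind, _ = getattr(m, "_binding", (None, None))
                if kind == VAR and m.name not in seen:
                    seen.add(m.name)
                    out.append(m.name)
        return out

    def _emit_ode(self, st: Node, lhs: Node, rhs: Node):
        solver = rhs.children[0].name
        stiff = _ODE_SOLVERS[solver]
        args = rhs.children[1:]
        if len(args) < 3:
            _unsup(f"{solver} requires (rhs, tspan, y0)", rhs.loc)
        mode, target = self._handle_target(args[0])
        self.rhs_n += 1
        rid = self.rhs_n
        captured: List[Tuple[str, str]] = []
        if mode == "anon":
            for name in self._free_idents(target.children[0], target.params):
                cls = self.var_class(name)
                if cls in ("d", "m"):
                    captured.append((name, cls))
        self._emit_rhs_wrapper(rid, mode, target, captured)
        tspan = self.to_m(*self.emit_expr(args[1]))
        y0 = self.to_m(*self.emit_expr(args[2]))
        self.flush_prelude()
        self.w("{")
        self.indent += 1
        self.w(f"m2c_mat __tspan = {tspan};")
        self.w(f"m2c_mat __y0 = {y0};")
        self.w(f"m2c_ctx_{rid} __ctx;")
        self.w("m2c_mat __t_out, __y_out;")
        self.w("__ctx.n = (int)m2c_numel(__y0);")
        for name, cls in captured:
            self.w(f"__ctx.v_{name} = v_{name};")
        self.w(f"m2c_ode_solve({stiff}, m2c_rhs_{rid}, &__ctx, "
               f"m2c_get1(__tspan, 1.0), m2c_get1(__tspan, m2c_numel(__tspan)), "
               f"__y0, M2C_RTOL, M2C_ATOL, M2C_GRID, &__t_out, &__y_out);")
        targets = lhs.children[0].children if lhs.kind == "matrix_literal" else [lhs]
        if len(targets) >= 1:
            self._store(targets[0], "__t_out", "m")
        if len(targets) >= 2:
            self._store(targets[1], "__y_out", "m")
        self.w("m2c_dump_timeseries(m2c_outdir, m2c_ts_counter++, __t_out, __y_out);")
        self.indent -= 1
        self.w("}")

    def _emit_rhs_wrapper(self, rid: int, mode: str, target: Node,
                          captured: List[Tuple[str, str]]):
        ctx_fields = ["    int n;"]
        for name, cls in captured:
            ctype = "double" if cls == "d" else "m2c_mat"
            ctx_fields.append(f"    {ctype} v_{name};")
        struct = f"typedef struct {{\n" + "\n".join(ctx_fields) + f"\n}} m2c_ctx_{rid};"
        proto = f"static void m2c_rhs_{rid}(double t, const double *y, " \
                f"double *dy, void *ctxp);"
        self.rhs_protos.append(struct)
        self.rhs_protos.append(proto)
        body: List[str] = []
        body.append(f"static void m2c_rhs_{rid}(double t, const double *y, "
                    f"double *dy, void *ctxp) {{")
        body.append(f"    m2c_ctx_{rid} *ctx = (m2c_ctx_{rid} *)ctxp;")
        body.append("    int __i;")
        body.append("    m2c_mat __r;")
        body.append("    (void)t;")
        if mode == "anon":
            params = target.params or []
            saved = (self.overrides, self.lines, self.indent,
                     self.prelude, self.line_map)
            self.overrides = dict(self.overrides)
            if len(params) >= 1:
                self.overrides[params[0]] = ("t", "d")
            if len(params) >= 2:
                self.overrides[params[1]] = ("__ym", "m")
            for name, cls in captured:
                self.overrides[name] = (f"ctx->v_{name}", cls)
            self.lines = []
            self.indent = 1
            self.prelude = []
            self.line_map = {}
            code, cls = self.emit_expr(target.children[0])
            self.flush_prelude()
            inner = self.lines
            self.overrides, self.lines, self.indent, self.prelude, self.line_map = saved
            body.append("    m2c_mat __ym = m2c_wrap((double *)y, ctx->n, 1);")
            body.extend(inner)
            body.append(f"    __r = {self.to_m(code, cls)};")
        else:
            cname = self.fn_names[id(target)]
            body.append("    m2c_mat __ym = m2c_wrap((double *)y, ctx->n, 1);")
            body.append(f"    {cname}(m2c_scal(t), __ym, &__r);")
        body.append("    if ((int)m2c_numel(__r) != ctx->n) "
                    "m2c_fail(\"rhs returned wrong length\");")
        body.append("    for (__i = 0; __i < ctx->n; __i++) dy[__i] = __r.data[__i];")
        body.append("}")
        body.append("")
        self.rhs_units.append("\n".join(body))

    # -- expressions -----------------------------------------------------------
    def emit_expr(self, n: Node) -> Tuple[str, str]:
        k = n.kind
        if k == "number":
            return _cnum(n.value), "d"
        if k == "string":
            esc = str(n.value).replace("\\", "\\\\").replace('"', '\\"')
            return f'"{esc}"', "s"
        if k == "identifier":
            if n.name in self.overrides:
                return self.overrides[n.name]
            kind, payload = getattr(n, "_binding", (VAR, None))
            if kind == VAR:
                cls = self.var_class(n.name)
                if cls in ("h", "x"):
                    _unsup(f"variable {n.name!r} has no runtime value in C", n.loc)
                return f"v_{n.name}", cls
            if kind == BUILTIN:
                call = map_builtin(n.name, [], n.loc)
                return call.render([]), call.result_class
            if kind == FUNC:
                return self._emit_user_call(payload.node, [], n)
            _unsup(f"unbound identifier {n.name!r}", n.loc)
        if k == "unary_op":
            code, cls = self.emit_expr(n.children[0])
            if n.op == "+":
                return code, cls
            if n.op == "-":
                return (f"(-{code})", "d") if cls == "d" else (f"m2c_neg({code})", "m")
            if cls == "d":
                return f"(({code} == 0.0) ? 1.0 : 0.0)", "d"
            return f"m2c_not({code})", "m"
        if k == "transpose":
            return f"m2c_transpose({self.to_m(*self.emit_expr(n.children[0]))})", "m"
        if k == "binary_op":
            return self._emit_binop(n)
        if k == "range":
            parts = [self.to_d(*self.emit_expr(c)) for c in n.children]
            if len(parts) == 2:
                a, s, b = parts[0], "1.0", parts[1]
            else:
                a, s, b = parts
            return f"m2c_range({a}, {s}, {b})", "m"
        if k == "matrix_literal":
            return self._emit_matrix_literal(n)
        if k == "field_access":
            base = n.children[0]
            if base.kind == "identifier":
                flat = f"{base.name}__{n.name}"
                cls = self.var_class(flat)
                return f"v_{flat}", cls if cls in ("d", "m", "s") else "m"
            _unsup("field access on non-variable", n.loc)
        if k == "index":
            return self._emit_index(n)
        if k == "call":
            return self._emit_call(n)
        if k == "end_marker":
            if not self.end_ctx:
                _unsup("'end' outside a subscript", n.loc)
            base, dim, nsubs = self.end_ctx[-1]
            return f"m2c_end({base}, {dim}, {nsubs})", "d"
        if k == "colon_all":
            return "m2c_colon_all()", "m"
        if k in ("anonymous_function", "func_handle"):
            _unsup("function handles have no first-class C value; they are "
                   "resolved statically at call sites", n.loc)
        _unsup(f"expression kind {k} not supported by the C backend", n.loc)

    def _emit_binop(self, n: Node) -> Tuple[str, str]:
        a_code, a_cls = self.emit_expr(n.children[0])
        b_code, b_cls = self.emit_expr(n.children[1])
        op = n.op
        if a_cls == "d" and b_cls == "d":
            return _D_OPS[op].format(a_code, b_code), "d"
        if op in ("&&", "||"):
            ta = f"m2c_truth({a_code})" if a_cls == "m" else f"({a_code} != 0.0)"
            tb = f"m2c_truth({b_code})" if b_cls == "m" else f"({b_code} != 0.0)"
            c_op = "&&" if op == "&&" else "||"
            return f"(({ta} {c_op} {tb}) ? 1.0 : 0.0)", "d"
        if op == "^":
            return f"pow({self.to_d(a_code, a_cls)}, {self.to_d(b_code, b_cls)})", "d"
        tag = _BIN_TAGS.get(op)
        if tag is None:
            _unsup(f"operator {op!r} not supported by the C backend", n.loc)
        return (f"m2c_bin({tag}, {self.to_m(a_code, a_cls)}, "
                f"{self.to_m(b_code, b_cls)})"), "m"

    def _emit_matrix_literal(self, n: Node) -> Tuple[str, str]:
        if not n.children:
            return "m2c_empty()", "m"
        row_codes = []
        for row in n.children:
            parts = [self.to_m(*self.emit_expr(el)) for el in row.children]
            code = parts[0]
            for p in parts[1:]:
                code = f"m2c_hcat2({code}, {p})"
            row_codes.append(code)
        out = row_codes[0]
        for rc in row_codes[1:]:
            out = f"m2c_vcat2({out}, {rc})"
        return out, "m"

    def _emit_index(self, n: Node) -> Tuple[str, str]:
        import re
        base = n.children[0]
        code, cls = self.emit_expr(base)
        if cls == "d":
            code, cls = f"m2c_scal({code})", "m"
        if not re.fullmatch(r"(ctx->)?[A-Za-z_][A-Za-z0-9_]*", code):
            code = self.tmp("m2c_mat", code)
        subs = n.children[1:]
        sub_parts: List[Tuple[str, str]] = []
        all_scalar = True
        for i, sub in enumerate(subs):
            if sub.kind == "colon_all":
                sub_parts.append(("m2c_colon_all()", "m"))
                all_scalar = False
                continue
            dim = 0 if len(subs) == 1 else i
            self.end_ctx.append((code, dim, len(subs)))
            sc, scls = self.emit_expr(sub)
            self.end_ctx.pop()
            sub_parts.append((sc, scls))
            if scls != "d":
                all_scalar = False
        if len(subs) == 1:
            if all_scalar:
                return f"m2c_get1({code}, {sub_parts[0][0]})", "d"
            return f"m2c_index1({code}, {self.to_m(*sub_parts[0])})", "m"
        if len(subs) == 2:
            if all_scalar:
                return (f"m2c_get2({code}, {sub_parts[0][0]}, "
                        f"{sub_parts[1][0]})"), "d"
            return (f"m2c_index2({code}, {self.to_m(*sub_parts[0])}, "
                    f"{self.to_m(*sub_parts[1])})"), "m"
        _unsup("more than two subscripts are unsupported", n.loc)

    def _emit_call(self, n: Node) -> Tuple[str, str]:
        base = n.children[0]
        args = n.children[1:]
        if base.kind != "identifier":
            _unsup("calls through arbitrary expressions are unsupported", n.loc)
        kind, payload = getattr(base, "_binding", (None, None))
        if kind == BUILTIN:
            pairs = [self.emit_expr(a) for a in args]
            call = map_builtin(base.name, [c for _, c in pairs], n.loc)
            out = call.render(pairs)
            if call.result_class in ("d", "void"):
                return out, "d"
            t = self.tree.type_of(n)
            if t.is_numeric and t.shape.is_scalar:
                return f"m2c_item({out})", "d"
            return out, "m"
        if kind == FUNC:
            return self._emit_user_call(payload.node, args, n)
        if kind == VAR:
            cls = self.var_class(base.name)
            if cls == "h":
                mode, target = self._handle_target(base)
                if mode == "named":
                    return self._emit_user_call(target, args, n)
                return self._emit_anon_call(target, args, n)
            # plain indexing (call nodes that sema left as variable reads)
            return self._emit_index(n)
        _unsup(f"cannot translate call to {base.name!r}", n.loc)

    def _emit_user_call(self, fnode: Node, args, site: Node) -> Tuple[str, str]:
        rendered = [self.to_m(*self.emit_expr(a)) for a in args]
        outs = fnode.outs or []
        o = self.tmp("m2c_mat")
        extra = [self.tmp("m2c_mat") for _ in outs[1:]]
        call_args = rendered + [f"&{o}"] + [f"&{e}" for e in extra]
        if not outs:
            call_args = rendered + [f"&{o}"]
            _unsup(f"function {fnode.name!r} has no outputs but is used as a value",
                   site.loc)
        self.prelude.append(f"{self.fn_names[id(fnode)]}({', '.join(call_args)});")
        t = self.tree.type_of(site)
        if t.is_numeric and t.shape.is_scalar:
            return f"m2c_item({o})", "d"
        return o, "m"

    def _emit_anon_call(self, target: Node, args, site: Node) -> Tuple[str, str]:
        params = target.params or []
        saved = dict(self.overrides)
        for p, a in zip(params, args):
            code, cls = self.emit_expr(a)
            if cls == "d":
                t = self.tmp("double", code)
            else:
                t = self.tmp("m2c_mat", code)
            self.overrides[p] = (t, cls)
        code, cls = self.emit_expr(target.children[0])
        self.overrides = saved
        return code, cls


def emit_c(tree: AnnotatedTree,
           opts: Optional[CodegenOptions] = None) -> List[EmittedUnit]:
    """Translate a fully annotated, error-free tree to C text units.

    Returns the model header and source; the runtime support units are
    appended by :func:`write_units` when writing to disk.  Emission is a
    pure function of (tree, opts): identical inputs yield identical text.
    """
    return CEmitter(tree, opts).emit()


def runtime_units() -> List[EmittedUnit]:
    return [
        EmittedUnit("c99_header", "m2c_rt.h", RUNTIME_H),
        EmittedUnit("c99_source", "m2c_rt.c", RUNTIME_C),
    ]


def write_units(units: List[EmittedUnit], outdir: str,
                include_runtime: bool = True) -> List[str]:
    """Write emitted units (plus the runtime library and line map) to disk."""
    import json
    import os
    os.makedirs(outdir, exist_ok=True)
    all_units = list(units) + (runtime_units() if include_runtime else [])
    written = []
    for u in all_units:
        path = os.path.join(outdir, u.name)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(u.text)
        written.append(path)
    lm = {}
    for u in units:
        if u.line_map:
            lm[u.name] = {str(k): {"unit": v[0], "line": v[1]}
                          for k, v in sorted(u.line_map.items())}
    with open(os.path.join(outdir, "line_map.json"), "w", encoding="utf-8") as fh:
        json.dump(lm, fh, indent=2)
    written.append(os.path.join(outdir, "line_map.json"))
    return written
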