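"""Pretty-printer: render a syntax tree back to dialect source.

Used by the round-trip property (print, re-parse, compare structurally) and
for diagnostics.  Output is fully parenthesized only where precedence
requires it; matrix literals are printed with explicit commas/semicolons so
the whitespace-splitting rule never has to fire on re-parse.
"""

from __future__ import annotations

from .astnodes import Node

_PREC = {
    "||": 1, "&&": 2, "|": 3, "&": 4,
    "==": 5, "~=": 5, "<": 5, "<=": 5, ">": 5, ">=": 5,
    "range": 6,
    "+": 7, "-": 7,
    "*": 8, "/": 8, ".*": 8, "./": 8,
    "unary": 9,
    "^": 10, ".^": 10,
}


def _num(v: float) -> str:
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(v)


def expr_to_source(n: Node, parent_prec: int = 0) -> str:
    k = n.kind
    if k == "number":
        s = _num(n.value)
    elif k == "string":
        s = "'" + str(n.value).replace("'", "''") + "'"
    elif k == "identifier":
        s = n.name
    elif k == "end_marker":
        s = "end"
    elif k == "colon_all":
        s = ":"
    elif k == "binary_op":
        p = _PREC[n.op]
        s = f"{expr_to_source(n.children[0], p)} {n.op} {expr_to_source(n.children[1], p + 1)}"
        if p < parent_prec:
            s = f"({s})"
        return s
    elif k == "unary_op":
        p = _PREC["unary"]
        s = f"{n.op}{expr_to_source(n.children[0], p)}"
        if p < parent_prec:
            s = f"({s})"
        return s
    elif k == "range":
        p = _PREC["range"]
        s = ":".join(expr_to_source(c, p + 1) for c in n.children)
        if p < parent_prec:
            s = f"({s})"
        return s
    elif k == "transpose":
        s = expr_to_source(n.children[0], 11) + "'"
    elif k == "call" or k == "index":
        base = expr_to_source(n.children[0], 11)
        s = base + "(" + ", ".join(expr_to_source(a) for a in n.children[1:]) + ")"
    elif k == "field_access":
        s = expr_to_source(n.children[0], 11) + "." + n.name
    elif k == "matrix_literal":
        rows = [", ".join(expr_to_source(e) for e in row.children) for row in n.children]
        s = "[" + "; ".join(rows) + "]"
    elif k == "anonymous_function":
        s = "@(" + ", ".join(n.params) + ") " + expr_to_source(n.children[0])
    elif k == "func_handle":
        s = "@" + n.name
    else:  # pragma: no cover - defensive
        raise ValueError(f"not an expression node: {k}")
    if parent_prec >= 11 and k in ("number",) and s.startswith("-"):
        s = f"({s})"
    return s


def _stmts(stmts, indent):
    pad = "  " * indent
    out = []
    for s in stmts:
        out.append(pad + stmt_to_source(s, indent))
    return "\n".join(out)


def stmt_to_source(n: Node, indent: int = 0) -> str:
    k = n.kind
    pad = "  " * indent
    if k == "assignment":
        return f"{expr_to_source(n.children[0])} = {expr_to_source(n.children[1])};"
    if k == "expr_stmt":
        return expr_to_source(n.children[0]) + ";"
    if k in ("break", "continue", "return"):
        return f"{k};"
    if k == "if":
        cond, then = n.children[0], n.children[1]
        parts = [f"if {expr_to_source(cond)}", _stmts(then.children, indent + 1)]
        for br in n.children[2:]:
            if br.kind == "elseif_branch":
                parts.append(f"{pad}elseif {expr_to_source(br.children[0])}")
                parts.append(_stmts(br.children[1].children, indent + 1))
            else:
                parts.append(f"{pad}else")
                parts.append(_stmts(br.children[0].children, indent + 1))
        parts.append(pad + "end")
        return "\n".join(p for p in parts if p != "")
    if k == "for":
        body = _stmts(n.children[1].children, indent + 1)
        head = f"for {n.name} = {expr_to_source(n.children[0])}"
        return "\n".join(p for p in (head, body, pad + "end") if p != "")
    if k == "while":
        body = _stmts(n.children[1].children, indent + 1)
        head = f"while {expr_to_source(n.children[0])}"
        return "\n".join(p for p in (head, body, pad + "end") if p != "")
    raise ValueError(f"not a statement node: {k}")  # pragma: no cover


def to_source(n: Node) -> str:
    """Render a script or function_def root back to source text."""
    if n.kind == "script":
        return _stmts(n.children, 0) + "\n"
    if n.kind == "function_def":
        head = "function "
        if n.outs:
            head += (n.outs[0] if len(n.outs) == 1 else "[" + ", ".join(n.outs) + "]") + " = "
        head += n.name + "(" + ", ".join(n.params or []) + ")"
        parts = [head]
        if n.subfunctions:
            for f in n.subfunctions:
                parts.append(_indent_block(to_source(f).rstrip("\n"), 1))
        body = _stmts(n.children, 1)
        if body:
            parts.append(body)
        parts.append("end")
        return "\n".join(parts) + "\n"
    raise ValueError(f"not a root node: {n.kind}")


def _indent_block(text: str, indent: int) -> str:
    pad = "  " * indent
    return "\n".join(pad + line if line else line for line in text.split("\n"))
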