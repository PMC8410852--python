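"""Recursive-descent parser for the supported dialect subset.

Grammar outline (statements end at newline or ``;``/``,``; all blocks are
closed by ``end``, including function definitions):

    unit        := function_def+ | statement*
    function_def:= 'function' [outs '='] name ['(' params ')'] stmts 'end'
    statement   := assignment | expression | if | for | while
                 | 'break' | 'continue' | 'return'
    assignment  := lvalue '=' expr      (lvalue: name, index, field, [l1, l2])

Expression precedence, loosest to tightest:
``||``, ``&&``, ``|``, ``&``, comparison, ``:`` range, additive,
multiplicative, unary ``+ - ~``, power ``^ .^``, postfix (call/index,
field access, transpose).

Inside square brackets, whitespace separates elements the way the source
dialect does: ``[1 -2]`` is two elements while ``[1 - 2]`` and ``[1-2]``
are one.  Inside subscripts, ``end`` and bare ``:`` are legal primaries.
"""

from __future__ import annotations

from typing import List, Optional

from ..diagnostics import CompileError, E_SYNTAX, SourceLocation, error
from .astnodes import Node
from .lexer import SourceUnit, Token, TokenKind, tokenize

_COMPARISON = ("==", "~=", "<", "<=", ">", ">=")
_ADDITIVE = ("+", "-")
_MULTIPLICATIVE = ("*", "/", ".*", "./")
_POWER = ("^", ".^")


class Parser:
    def __init__(self, tokens: List[Token], unit_name: str):
        self.toks = [t for t in tokens if t.kind is not TokenKind.COMMENT]
        self.pos = 0
        self.unit = unit_name
        self.subscript_depth = 0
        self.matrix_depth = 0

    # -- token helpers -------------------------------------------------
    def peek(self, ahead: int = 0) -> Token:
        return self.toks[min(self.pos + ahead, len(self.toks) - 1)]

    def next(self) -> Token:
        t = self.toks[self.pos]
        if t.kind is not TokenKind.EOF:
            self.pos += 1
        return t

    def loc(self, tok: Optional[Token] = None) -> SourceLocation:
        t = tok or self.peek()
        return SourceLocation(self.unit, t.line, t.column)

    def fail(self, msg: str, tok: Optional[Token] = None):
        t = tok or self.peek()
        shown = t.lexeme if t.kind is not TokenKind.EOF else "end of input"
        raise CompileError(error(E_SYNTAX, f"{msg} (found {shown!r})", self.loc(t)))

    def at(self, kind: TokenKind, lexeme: Optional[str] = None) -> bool:
        t = self.peek()
        return t.kind is kind and (lexeme is None or t.lexeme == lexeme)

    def at_keyword(self, *words: str) -> bool:
        t = self.peek()
        return t.kind is TokenKind.KEYWORD and t.lexeme in words

    def expect(self, kind: TokenKind, lexeme: Optional[str] = None) -> Token:
        if not self.at(kind, lexeme):
            want = lexeme or kind.value
            self.fail(f"expected {want!r}")
        return self.next()

    def skip_terminators(self):
        while self.peek().kind is TokenKind.NEWLINE or \
                self.at(TokenKind.PUNCTUATION, ";") or self.at(TokenKind.PUNCTUATION, ","):
            self.next()

    def skip_newlines(self):
        while self.peek().kind is TokenKind.NEWLINE:
            self.next()

    # -- unit ----------------------------------------------------------
    def parse_unit(self) -> Node:
        self.skip_terminators()
        if self.at_keyword("function"):
            main = self.parse_function_def()
            extras = []
            self.skip_terminators()
            while self.at_keyword("function"):
                extras.append(self.parse_function_def())
                self.skip_terminators()
            if self.peek().kind is not TokenKind.EOF:
                self.fail("unexpected token after function definitions")
            if extras:  # file-local subfunctions, visible within this unit
                main.subfunctions = (main.subfunctions or []) + extras
            return main
        root = Node("script", loc=self.loc())
        root.children = self.parse_statements(until_eof=True)
        return root

    def parse_function_def(self) -> Node:
        start = self.expect(TokenKind.KEYWORD, "function")
        outs: List[str] = []
        # forms: function name(...), function out = name(...), function [a,b] = name(...)
        if self.at(TokenKind.PUNCTUATION, "["):
            self.next()
            while not self.at(TokenKind.PUNCTUATION, "]"):
                outs.append(self.expect(TokenKind.IDENTIFIER).lexeme)
                if self.at(TokenKind.PUNCTUATION, ","):
                    self.next()
            self.next()
            self.expect(TokenKind.OPERATOR, "=")
            name = self.expect(TokenKind.IDENTIFIER).lexeme
        else:
            first = self.expect(TokenKind.IDENTIFIER).lexeme
            if self.at(TokenKind.OPERATOR, "="):
                self.next()
                outs = [first]
                name = self.expect(TokenKind.IDENTIFIER).lexeme
            else:
                name = first
        params: List[str] = []
        if self.at(TokenKind.PUNCTUATION, "("):
            self.next()
            while not self.at(TokenKind.PUNCTUATION, ")"):
                params.append(self.expect(TokenKind.IDENTIFIER).lexeme)
                if self.at(TokenKind.PUNCTUATION, ","):
                    self.next()
            self.next()
        body, nested = self.parse_block(allow_functions=True)
        self.expect(TokenKind.KEYWORD, "end")
        node = Node("function_def", children=body, loc=self.loc(start),
                    name=name, params=params, outs=outs)
        if nested:
            node.subfunctions = nested
        return node

    # -- statements ----------------------------------------------------
    def parse_block(self, stop=("end",), allow_functions=False):
        """Statements until one of the ``stop`` keywords (not consumed)."""
        stmts: List[Node] = []
        nested: List[Node] = []
        self.skip_terminators()
        while True:
            t = self.peek()
            if t.kind is TokenKind.EOF:
                self.fail("unexpected end of input, block not closed by 'end'", t)
            if t.kind is TokenKind.KEYWORD and t.lexeme in stop:
                return stmts, nested
            if t.kind is TokenKind.KEYWORD and t.lexeme == "function":
                if not allow_functions:
                    self.fail("function definition not allowed here", t)
                nested.append(self.parse_function_def())
                self.skip_terminators()
                continue
            stmts.append(self.parse_statement())
            self.skip_terminators()

    def parse_statements(self, until_eof: bool) -> List[Node]:
        stmts: List[Node] = []
        self.skip_terminators()
        while self.peek().kind is not TokenKind.EOF:
            if self.at_keyword("function"):
                self.fail("function definitions are not allowed inside a script")
            stmts.append(self.parse_statement())
            self.skip_terminators()
        return stmts

    def parse_statement(self) -> Node:
        t = self.peek()
        if t.kind is TokenKind.KEYWORD:
            if t.lexeme == "if":
                return self.parse_if()
            if t.lexeme == "for":
                return self.parse_for()
            if t.lexeme == "while":
                return self.parse_while()
            if t.lexeme in ("break", "continue", "return"):
                self.next()
                return Node(t.lexeme, loc=self.loc(t))
            self.fail("unexpected keyword")
        expr = self.parse_expr()
        if self.at(TokenKind.OPERATOR, "="):
            eq = self.next()
            self._check_lvalue(expr)
            rhs = self.parse_expr()
            return Node("assignment", children=[expr, rhs], loc=expr.loc or self.loc(eq))
        return Node("expr_stmt", children=[expr], loc=expr.loc)

    def _check_lvalue(self, n: Node):
        if n.kind in ("identifier", "call", "index", "field_access"):
            return
        if n.kind == "matrix_literal":
            if len(n.children) != 1:
                self.fail("invalid left-hand side of assignment", None)
            for el in n.children[0].children:
                if el.kind not in ("identifier", "call", "index", "field_access"):
                    raise CompileError(error(
                        E_SYNTAX, "invalid element in multi-output assignment", el.loc))
            return
        raise CompileError(error(E_SYNTAX, "invalid left-hand side of assignment", n.loc))

    def parse_if(self) -> Node:
        start = self.expect(TokenKind.KEYWORD, "if")
        cond = self.parse_expr()
        body, _ = self.parse_block(stop=("end", "elseif", "else"))
        children = [cond, Node("block", children=body, loc=self.loc(start))]
        while self.at_keyword("elseif"):
            t = self.next()
            c = self.parse_expr()
            b, _ = self.parse_block(stop=("end", "elseif", "else"))
            children.append(Node("elseif_branch",
                                 children=[c, Node("block", children=b)], loc=self.loc(t)))
        if self.at_keyword("else"):
            t = self.next()
            b, _ = self.parse_block(stop=("end",))
            children.append(Node("else_branch",
                                 children=[Node("block", children=b)], loc=self.loc(t)))
        self.expect(TokenKind.KEYWORD, "end")
        return Node("if", children=children, loc=self.loc(start))

    def parse_for(self) -> Node:
        start = self.expect(TokenKind.KEYWORD, "for")
        var = self.expect(TokenKind.IDENTIFIER)
        self.expect(TokenKind.OPERATOR, "=")
        it = self.parse_expr()
        body, _ = self.parse_block(stop=("end",))
        self.expect(TokenKind.KEYWORD, "end")
        return Node("for", children=[it, Node("block", children=body)],
                    loc=self.loc(start), name=var.lexeme)

    def parse_while(self) -> Node:
        start = self.expect(TokenKind.KEYWORD, "while")
        cond = self.parse_expr()
        body, _ = self.parse_block(stop=("end",))
        self.expect(TokenKind.KEYWORD, "end")
        return Node("while", children=[cond, Node("block", children=body)],
                    loc=self.loc(start))

    # -- expressions ---------------------------------------------------
    def parse_expr(self) -> Node:
        return self.parse_or()

    def _binary_level(self, sub, ops):
        left = sub()
        while self.at_left_of(ops):
            op = self.next()
            right = sub()
            left = Node("binary_op", children=[left, right],
                        loc=left.loc or self.loc(op), op=op.lexeme)
        return left

    def at_left_of(self, ops) -> bool:
        t = self.peek()
        if t.kind is not TokenKind.OPERATOR or t.lexeme not in ops:
            return False
        # matrix-literal element split: `[1 -2]` is two elements, `[1 - 2]`
        # and `[1-2]` stay a single expression
        if self.matrix_depth > 0 and self.subscript_depth == 0 and \
                t.lexeme in ("+", "-") and t.space_before and \
                not self.peek(1).space_before and self._starts_primary(self.peek(1)):
            return False
        return True

    @staticmethod
    def _starts_primary(t: Token) -> bool:
        return t.kind in (TokenKind.NUMBER, TokenKind.IDENTIFIER, TokenKind.STRING) or \
            (t.kind is TokenKind.PUNCTUATION and t.lexeme in "([") or \
            (t.kind is TokenKind.OPERATOR and t.lexeme == "@")

    def parse_or(self):
        return self._binary_level(self.parse_and, ("||",))

    def parse_and(self):
        return self._binary_level(self.parse_bitor, ("&&",))

    def parse_bitor(self):
        return self._binary_level(self.parse_bitand, ("|",))

    def parse_bitand(self):
        return self._binary_level(self.parse_comparison, ("&",))

    def parse_comparison(self):
        return self._binary_level(self.parse_range, _COMPARISON)

    def parse_range(self):
        first = self.parse_additive()
        if not self.at(TokenKind.OPERATOR, ":"):
            return first
        self.next()
        second = self.parse_additive()
        if self.at(TokenKind.OPERATOR, ":"):
            self.next()
            third = self.parse_additive()
            return Node("range", children=[first, second, third], loc=first.loc)
        return Node("range", children=[first, second], loc=first.loc)

    def parse_additive(self):
        return self._binary_level(self.parse_multiplicative, _ADDITIVE)

    def parse_multiplicative(self):
        return self._binary_level(self.parse_unary, _MULTIPLICATIVE)

    def parse_unary(self):
        t = self.peek()
        if t.kind is TokenKind.OPERATOR and t.lexeme in ("+", "-", "~"):
            self.next()
            operand = self.parse_unary()
            return Node("unary_op", children=[operand], loc=self.loc(t), op=t.lexeme)
        return self.parse_power()

    def parse_power(self):
        base = self.parse_postfix()
        if self.at(TokenKind.OPERATOR, "^") or self.at(TokenKind.OPERATOR, ".^"):
            op = self.next()
            # exponent may itself be unary ( 2^-3 )
            exp = self.parse_unary_for_power()
            return Node("binary_op", children=[base, exp], loc=base.loc, op=op.lexeme)
        return base

    def parse_unary_for_power(self):
        t = self.peek()
        if t.kind is TokenKind.OPERATOR and t.lexeme in ("+", "-"):
            self.next()
            return Node("unary_op", children=[self.parse_unary_for_power()],
                        loc=self.loc(t), op=t.lexeme)
        return self.parse_power()

    def parse_postfix(self):
        node = self.parse_primary()
        while True:
            if self.at(TokenKind.PUNCTUATION, "("):
                self.next()
                args = self.parse_args()
                self.expect(TokenKind.PUNCTUATION, ")")
                node = Node("call", children=[node] + args, loc=node.loc)
            elif self.at(TokenKind.PUNCTUATION, ".") and \
                    self.peek(1).kind is TokenKind.IDENTIFIER:
                self.next()
                fld = self.next()
                node = Node("field_access", children=[node], loc=node.loc, name=fld.lexeme)
            elif self.at(TokenKind.OPERATOR, "'") or self.at(TokenKind.OPERATOR, ".'"):
                self.next()
                node = Node("transpose", children=[node], loc=node.loc)
            else:
                return node

    def parse_args(self) -> List[Node]:
        args: List[Node] = []
        self.subscript_depth += 1
        saved_matrix = self.matrix_depth
        self.matrix_depth = 0
        try:
            while not self.at(TokenKind.PUNCTUATION, ")"):
                if self.at(TokenKind.OPERATOR, ":") and (
                        self.peek(1).kind is TokenKind.PUNCTUATION and
                        self.peek(1).lexeme in "),"):
                    t = self.next()
                    args.append(Node("colon_all", loc=self.loc(t)))
                else:
                    args.append(self.parse_expr())
                if self.at(TokenKind.PUNCTUATION, ","):
                    self.next()
                elif not self.at(TokenKind.PUNCTUATION, ")"):
                    self.fail("expected ',' or ')' in argument list")
        finally:
            self.subscript_depth -= 1
            self.matrix_depth = saved_matrix
        return args

    def parse_primary(self) -> Node:
        t = self.peek()
        if t.kind is TokenKind.NUMBER:
            self.next()
            return Node("number", loc=self.loc(t), value=float(t.lexeme))
        if t.kind is TokenKind.STRING:
            self.next()
            return Node("string", loc=self.loc(t), value=t.value)
        if t.kind is TokenKind.IDENTIFIER:
            self.next()
            return Node("identifier", loc=self.loc(t), name=t.lexeme)
        if t.kind is TokenKind.KEYWORD and t.lexeme == "end" and self.subscript_depth > 0:
            self.next()
            return Node("end_marker", loc=self.loc(t))
        if t.kind is TokenKind.PUNCTUATION and t.lexeme == "(":
            self.next()
            saved_sub, saved_mat = self.subscript_depth, self.matrix_depth
            self.subscript_depth, self.matrix_depth = 0, 0
            inner = self.parse_expr()
            self.subscript_depth, self.matrix_depth = saved_sub, saved_mat
            self.expect(TokenKind.PUNCTUATION, ")")
            return inner
        if t.kind is TokenKind.PUNCTUATION and t.lexeme == "[":
            return self.parse_matrix_literal()
        if t.kind is TokenKind.OPERATOR and t.lexeme == "@":
            self.next()
            if self.at(TokenKind.PUNCTUATION, "("):
                self.next()
                params: List[str] = []
                while not self.at(TokenKind.PUNCTUATION, ")"):
                    params.append(self.expect(TokenKind.IDENTIFIER).lexeme)
                    if self.at(TokenKind.PUNCTUATION, ","):
                        self.next()
                self.next()
                body = self.parse_expr()
                return Node("anonymous_function", children=[body],
                            loc=self.loc(t), params=params)
            name = self.expect(TokenKind.IDENTIFIER)
            return Node("func_handle", loc=self.loc(t), name=name.lexeme)
        self.fail("expected an expression")

    def parse_matrix_literal(self) -> Node:
        start = self.expect(TokenKind.PUNCTUATION, "[")
        self.matrix_depth += 1
        rows: List[Node] = []
        current: List[Node] = []

        def flush_row():
            nonlocal current
            if current:
                rows.append(Node("matrix_row", children=current, loc=current[0].loc))
                current = []

        try:
            while True:
                while self.peek().kind is TokenKind.NEWLINE:
                    self.next()
                    flush_row()
                if self.at(TokenKind.PUNCTUATION, "]"):
                    self.next()
                    break
                if self.at(TokenKind.PUNCTUATION, ";"):
                    self.next()
                    flush_row()
                    continue
                if self.at(TokenKind.PUNCTUATION, ","):
                    self.next()
                    continue
                if self.peek().kind is TokenKind.EOF:
                    self.fail("unterminated matrix literal", start)
                current.append(self.parse_expr())
        finally:
            self.matrix_depth -= 1
        flush_row()
        return Node("matrix_literal", children=rows, loc=self.loc(start))


def parse(tokens: List[Token], unit_name: str = "<input>") -> Node:
    """Parse a token list into a script or function_def root node."""
    return Parser(tokens, unit_name).parse_unit()


def parse_source(unit: SourceUnit) -> Node:
    return parse(tokenize(unit), unit.path)
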