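"""Lexer for the restricted MATLAB-compatible dialect.

Splits a source unit into located tokens.  Two dialect-specific wrinkles are
handled here rather than in the parser:

* the single quote is transpose after a value-ending token (identifier,
  number, ``)``, ``]``, ``end`` or another transpose) and a string delimiter
  everywhere else;
* each token records whether whitespace preceded it, which the parser needs
  to split space-separated elements inside matrix literals.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import List

from ..diagnostics import CompileError, E_LEX, SourceLocation, error


class TokenKind(Enum):
    IDENTIFIER = "identifier"
    KEYWORD = "keyword"
    NUMBER = "number"
    STRING = "string"
    OPERATOR = "operator"
    PUNCTUATION = "punctuation"
    NEWLINE = "newline"
    COMMENT = "comment"
    EOF = "eof"


KEYWORDS = frozenset({
    "if", "elseif", "else", "end", "for", "while",
    "break", "continue", "return", "function",
})

# longest-match first
_OPERATORS = [
    "...", "==", "~=", "<=", ">=", "&&", "||", ".*", "./", ".^", ".'",
    "+", "-", "*", "/", "^", "<", ">", "=", "&", "|", "~", ":", "@", "'",
]
_PUNCT = "()[]{},;."


@dataclass
class Token:
    kind: TokenKind
    lexeme: str
    line: int
    column: int
    space_before: bool = False
    value: object = None  # decoded payload (string literals)

    def __repr__(self):
        return f"Token({self.kind.value}, {self.lexeme!r}, {self.line}:{self.column})"


@dataclass
class SourceUnit:
    """A single ``.m`` file: its name, raw text and entry-point flag."""

    path: str
    text: str
    is_entry: bool = False

    def __post_init__(self):
        if not self.text:
            raise ValueError(f"source unit {self.path!r} is empty")


def _is_ident_start(c: str) -> bool:
    return c.isalpha() or c == "_"


def _is_ident(c: str) -> bool:
    return c.isalnum() or c == "_"


def tokenize(unit: SourceUnit, keep_comments: bool = False) -> List[Token]:
    """Tokenize a source unit; raises :class:`CompileError` on lexical errors."""
    text = unit.text.replace("\r\n", "\n")
    toks: List[Token] = []
    i, line, col = 0, 1, 1
    n = len(text)
    space = False

    def loc():
        return SourceLocation(unit.path, line, col)

    def prev_significant():
        for t in reversed(toks):
            if t.kind not in (TokenKind.COMMENT,):
                return t
        return None

    while i < n:
        c = text[i]
        if c in " \t":
            i += 1
            col += 1
            space = True
            continue
        if c == "\n":
            toks.append(Token(TokenKind.NEWLINE, "\n", line, col, space))
            i += 1
            line += 1
            col = 1
            space = False
            continue
        if c == "%":
            j = text.find("\n", i)
            j = n if j < 0 else j
            if keep_comments:
                toks.append(Token(TokenKind.COMMENT, text[i:j], line, col, space))
            col += j - i
            i = j
            space = False
            continue
        if text.startswith("...", i):
            # line continuation: swallow to and including end of line
            j = text.find("\n", i)
            if j < 0:
                i = n
            else:
                i = j + 1
                line += 1
                col = 1
            space = True
            continue
        if c.isdigit() or (c == "." and i + 1 < n and text[i + 1].isdigit()):
            j = i
            while j < n and text[j].isdigit():
                j += 1
            if j < n and text[j] == "." and not text.startswith("..", j):
                j += 1
                while j < n and text[j].isdigit():
                    j += 1
            if j < n and text[j] in "eE":
                k = j + 1
                if k < n and text[k] in "+-":
                    k += 1
                if k < n and text[k].isdigit():
                    j = k
                    while j < n and text[j].isdigit():
                        j += 1
            lex = text[i:j]
            toks.append(Token(TokenKind.NUMBER, lex, line, col, space))
            col += j - i
            i = j
            space = False
            continue
        if _is_ident_start(c):
            j = i
            while j < n and _is_ident(text[j]):
                j += 1
            lex = text[i:j]
            kind = TokenKind.KEYWORD if lex in KEYWORDS else TokenKind.IDENTIFIER
            toks.append(Token(kind, lex, line, col, space))
            col += j - i
            i = j
            space = False
            continue
        if c == "'":
            prev = prev_significant()
            is_transpose = (
                prev is not None
                and (
                    prev.kind in (TokenKind.IDENTIFIER, TokenKind.NUMBER)
                    or (prev.kind == TokenKind.PUNCTUATION and prev.lexeme in ")]")
                    or (prev.kind == TokenKind.KEYWORD and prev.lexeme == "end")
                    or (prev.kind == TokenKind.OPERATOR and prev.lexeme in ("'", ".'"))
                )
                and not space
            )
            if is_transpose:
                toks.append(Token(TokenKind.OPERATOR, "'", line, col, space))
                i += 1
                col += 1
                space = False
                continue
            # string literal, '' escapes a quote
            j = i + 1
            buf = []
            while True:
                if j >= n or text[j] == "\n":
                    raise CompileError(error(E_LEX, "unterminated string literal", loc()))
                if text[j] == "'":
                    if j + 1 < n and text[j + 1] == "'":
                        buf.append("'")
                        j += 2
                        continue
                    break
                buf.append(text[j])
                j += 1
            tok = Token(TokenKind.STRING, text[i:j + 1], line, col, space)
            tok.value = "".join(buf)  # type: ignore[attr-defined]
            toks.append(tok)
            col += j + 1 - i
            i = j + 1
            space = False
            continue
        matched = False
        for op in _OPERATORS:
            if text.startswith(op, i) and op != "'":
                toks.append(Token(TokenKind.OPERATOR, op, line, col, space))
                i += len(op)
                col += len(op)
                space = False
                matched = True
                break
        if matched:
            continue
        if c in _PUNCT:
            if c == "{" or c == "}":
                raise CompileError(error(
                    E_LEX, "cell arrays are outside the supported dialect subset", loc()))
            toks.append(Token(TokenKind.PUNCTUATION, c, line, col, space))
            i += 1
            col += 1
            space = False
            continue
        raise CompileError(error(E_LEX, f"illegal character {c!r}", loc()))

    toks.append(Token(TokenKind.EOF, "", line, col, space))
    return toks
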