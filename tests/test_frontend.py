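"""Lexer, parser, pretty-printer and program-graph tests."""

import pytest

from mat2c.diagnostics import CompileError
from mat2c.fixtures import generate_fixture, list_fixtures
from mat2c.frontend import (SourceUnit, TokenKind, build_program, parse,
                            parse_source, to_source, tokenize)


def toks(src, **kw):
    return tokenize(SourceUnit("t.m", src), **kw)


class TestTokenize:
    def test_minimal_statement(self):
        ts = toks("x = 1;")
        kinds = [(t.kind, t.lexeme) for t in ts[:-1] if t.kind is not TokenKind.NEWLINE]
        assert kinds == [
            (TokenKind.IDENTIFIER, "x"), (TokenKind.OPERATOR, "="),
            (TokenKind.NUMBER, "1"), (TokenKind.PUNCTUATION, ";")]

    def test_compound_operator_and_unary_minus(self):
        ts = toks("dy = -k .* y;")
        lex = [t.lexeme for t in ts if t.kind is TokenKind.OPERATOR]
        assert ".*" in lex and "-" in lex and "=" in lex

    def test_comments_skipped_or_kept(self):
        plain = toks("% comment\ny=2")
        assert all(t.kind is not TokenKind.COMMENT for t in plain)
        kept = toks("% comment\ny=2", keep_comments=True)
        assert any(t.kind is TokenKind.COMMENT for t in kept)
        names = [t.lexeme for t in plain if t.kind is TokenKind.IDENTIFIER]
        assert names == ["y"]

    def test_locations_reconstruct_input(self):
        src = "a = 1;\nbb = a + 2;\n"
        for t in toks(src):
            if t.kind in (TokenKind.NEWLINE, TokenKind.EOF):
                continue
            line = src.split("\n")[t.line - 1]
            assert line[t.column - 1:t.column - 1 + len(t.lexeme)] == t.lexeme

    def test_transpose_vs_string(self):
        ts = toks("b = a' + 'txt';")
        assert [t.kind for t in ts if t.lexeme == "'"] == [TokenKind.OPERATOR]
        assert any(t.kind is TokenKind.STRING for t in ts)

    def test_unterminated_string_is_lexical_error(self):
        with pytest.raises(CompileError) as ei:
            toks("s = 'oops")
        assert ei.value.first.code == "E_LEX"

    def test_illegal_character(self):
        with pytest.raises(CompileError) as ei:
            toks("x = $2;")
        assert ei.value.first.code == "E_LEX"
        assert ei.value.first.loc.column == 5


class TestParse:
    def test_standard_precedence(self):
        root = parse(toks("z = 1+2*3;"))
        rhs = root.children[0].children[1]
        assert rhs.op == "+"
        assert rhs.children[1].op == "*"

    def test_two_subscripts(self):
        root = parse(toks("x = A(2,3);"))
        idx = root.children[0].children[1]
        assert idx.kind == "call"  # call/index settled during scope resolution
        assert len(idx.children) == 3

    def test_unclosed_block_is_syntax_error(self):
        with pytest.raises(CompileError) as ei:
            parse(toks("if x>0\ny=1;"))
        assert ei.value.first.code == "E_SYNTAX"

    def test_power_binds_tighter_than_unary_minus(self):
        root = parse(toks("z = -2^2;"))
        rhs = root.children[0].children[1]
        assert rhs.kind == "unary_op" and rhs.children[0].op == "^"

    def test_matrix_literal_space_rule(self):
        two = parse(toks("v = [1 -2];")).children[0].children[1]
        assert len(two.children[0].children) == 2
        one = parse(toks("v = [1 - 2];")).children[0].children[1]
        assert len(one.children[0].children) == 1

    def test_unsupported_construct_rejected_not_misparsed(self):
        with pytest.raises(CompileError):
            parse_source(SourceUnit("t.m", "c = {1, 2};"))


@pytest.mark.parametrize("name", [n for n in list_fixtures()])
def test_print_reparse_roundtrip(name):
    """Pretty-printing any fixture source and re-parsing yields a
    structurally identical tree."""
    spec = generate_fixture(name, {"n": 3} if name == "linear_ode_system" else None)
    for fname, src in spec.sources.items():
        tree = parse_source(SourceUnit(fname, src))
        printed = to_source(tree)
        again = parse_source(SourceUnit(fname, printed))
        assert tree.structurally_equal(again), fname


class TestBuildProgram:
    def test_one_dependency(self, tmp_path):
        (tmp_path / "f.m").write_text("function y = f(x)\n  y = x + 1;\nend\n")
        entry = SourceUnit("main.m", "r = f(2);\n", is_entry=True)
        g = build_program(entry, [str(tmp_path)])
        assert set(g.units) == {"main", "f"}
        assert ("main", "f") in g.call_edges

    def test_builtin_only_entry(self):
        entry = SourceUnit("main.m", "z = zeros(2, 2);\nq = interp1([0 1], [0 2], 0.5);\n",
                           is_entry=True)
        g = build_program(entry)
        assert set(g.units) == {"main"} and not g.call_edges

    def test_cyclic_files_rejected(self, tmp_path):
        (tmp_path / "a.m").write_text("function y = a(x)\n  y = b(x);\nend\n")
        (tmp_path / "b.m").write_text("function y = b(x)\n  y = a(x);\nend\n")
        entry = SourceUnit("main.m", "r = a(1);\n", is_entry=True)
        with pytest.raises(CompileError) as ei:
            build_program(entry, [str(tmp_path)])
        assert ei.value.first.code == "E_CYCLIC_UNITS"

    def test_missing_function_file(self):
        entry = SourceUnit("main.m", "r = nosuchfn(1);\n", is_entry=True)
        with pytest.raises(CompileError) as ei:
            build_program(entry)
        assert ei.value.first.code == "E_MISSING_UNIT"
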