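"""Scope resolution, fixpoint type inference, checking and DOT rendering."""

import pytest

from mat2c.frontend import SourceUnit, build_program
from mat2c.sema import analyze, infer_types, render_dot, le
from mat2c.sema.types import Base, Shape, Type, join, BaseConflict

from conftest import analyze_source

NESTED_F = (
    "function y = f(x)\n"
    "  function z = g(u)\n"
    "    z = u * 2;\n"
    "  end\n"
    "  y = g(x) + 1;\n"
    "end\n"
)


def _lhs_types(program, tree):
    out = {}
    for st in program.entry_node.children:
        if st.kind == "assignment" and st.children[0].kind == "identifier":
            out[st.children[0].name] = tree.type_of(st.children[0])
    return out


class TestScopes:
    def test_nested_function_visible_inside_parent(self, tmp_path):
        (tmp_path / "f.m").write_text(NESTED_F)
        program = build_program(SourceUnit("m.m", "r = f(2);\n", is_entry=True),
                                [str(tmp_path)])
        tree = analyze(program)
        assert not tree.errors

    def test_nested_function_call_outside_parent_rejected(self, tmp_path):
        (tmp_path / "f.m").write_text(NESTED_F)
        program = build_program(
            SourceUnit("m.m", "r = f(2);\nq = g(3);\n", is_entry=True),
            [str(tmp_path)])
        tree = analyze(program)
        assert any(d.code == "E_SCOPE_CALL" for d in tree.errors)

    def test_use_before_definition(self):
        _, tree = analyze_source("y = z + 1;\n")
        assert any(d.code == "E_UNDEFINED" for d in tree.errors)

    def test_local_variable_shadows_function(self, tmp_path):
        (tmp_path / "f.m").write_text("function y = f(x)\n  y = x;\nend\n")
        program = build_program(
            SourceUnit("m.m", "f = [10 20 30];\nv = f(2);\n", is_entry=True),
            [str(tmp_path)])
        tree = analyze(program)
        assert not tree.errors
        # the use was rewritten to an index read, not a call
        second = program.entry_node.children[1]
        assert second.children[1].kind == "index"


class TestInference:
    def test_literal_propagation(self):
        program, tree = analyze_source("x = 1;\ny = x + 2;\n")
        t = _lhs_types(program, tree)
        assert str(t["x"]) == "real scalar"
        assert str(t["y"]) == "real scalar"

    def test_builtin_shape_rule(self):
        program, tree = analyze_source("v = zeros(3, 1);\nw = 2 * v;\n")
        t = _lhs_types(program, tree)
        assert str(t["v"]) == "real vector(3)"
        assert str(t["w"]) == "real vector(3)"

    def test_one_by_one_matrix_usable_as_scalar(self):
        program, tree = analyze_source("m = ones(1, 1);\ns = m + 1;\n")
        assert not tree.errors
        t = _lhs_types(program, tree)
        assert t["s"].shape.is_scalar

    def test_fixpoint_within_pass_cap(self):
        program, tree = analyze_source(
            "a = 1;\nb = a;\nc = [a b];\nd = c * 2;\n")
        assert tree.passes <= 50 and not tree.errors

    def test_idempotence(self):
        program, _ = analyze_source("x = 1;\nv = zeros(2, 2);\nw = v + x;\n")
        t1 = infer_types(program)
        m1 = {k: str(v) for k, v in t1.types.items()}
        t2 = infer_types(program)
        m2 = {k: str(v) for k, v in t2.types.items()}
        assert m1 == m2

    def test_definition_order_independence(self, tmp_path):
        (tmp_path / "fa.m").write_text("function y = fa(x)\n  y = x + 1;\nend\n")
        (tmp_path / "fb.m").write_text("function y = fb(x)\n  y = [x x];\nend\n")
        src_ab = "p = fa(1);\nq = fb(2);\n"
        src_ba = "q = fb(2);\np = fa(1);\n"
        r = {}
        for tag, src in (("ab", src_ab), ("ba", src_ba)):
            program = build_program(SourceUnit("m.m", src, is_entry=True),
                                    [str(tmp_path)])
            tree = analyze(program)
            assert not tree.errors
            r[tag] = {k: str(v) for k, v in _lhs_types(program, tree).items()}
        assert r["ab"] == r["ba"]

    def test_shape_merge_promotes_to_dynamic_with_warning(self):
        program, tree = analyze_source(
            "c = 1;\nif c > 0\n  x = zeros(2, 2);\nelse\n  x = zeros(3, 3);\nend\n"
            "y = x;\n")
        assert not tree.errors
        assert any(d.code == "W_SHAPE_MERGE" for d in tree.diagnostics)

    def test_monotone_annotation(self):
        """Annotations only ascend the lattice: every recorded type is above
        unknown and idempotent reruns do not move any node down."""
        program, _ = analyze_source("x = 1;\nv = [x 2];\n")
        t1 = infer_types(program)
        for node_id, ty in t1.types.items():
            assert le(Type(Base.UNKNOWN), ty)


class TestShapeOracleAgreement:
    @pytest.mark.parametrize("name,params", [
        ("feature_tour", None), ("interp1_script", None),
        ("setdiff_union", None), ("linear_ode_system", {"n": 3}),
    ])
    def test_static_shapes_match_runtime_shapes(self, tmp_path, name, params):
        """Statically inferred concrete shapes agree with the shapes the
        interpreter observes at each variable's final assignment."""
        import numpy as np
        from mat2c.fixtures import generate_fixture
        from mat2c.pipeline import analyze_path
        from mat2c.runtime import evaluate
        spec = generate_fixture(name, params, seed=7)
        entry = spec.write(str(tmp_path / name))
        program, tree = analyze_path(entry)
        assert not tree.errors
        env, _ = evaluate(program)
        inferred = tree.var_types[program.entry]
        for var, ty in inferred.items():
            if var not in env or not isinstance(env[var], np.ndarray):
                continue
            s = ty.shape
            if not ty.is_numeric or not s.known:
                continue  # dynamic dims carry no concrete claim
            assert env[var].shape == (s.rows, s.cols), (name, var, str(ty))


class TestTypeLattice:
    def test_join_unknown_is_identity(self):
        t = Type(Base.REAL, Shape.vector(3))
        assert join(Type(Base.UNKNOWN), t)[0] == t

    def test_join_incompatible_bases_is_error(self):
        with pytest.raises(BaseConflict):
            join(Type(Base.REAL), Type(Base.STRING))

    def test_scalar_below_dynamic(self):
        s = Type(Base.REAL, Shape.scalar())
        d = Type(Base.REAL, Shape.dyn())
        assert le(s, d) and not le(d, s)


class TestCheckTypes:
    def test_vector_quotient_rejected(self):
        _, tree = analyze_source("a = [1 2 3];\nb = [4 5 6];\nc = a / b;\n")
        assert any(d.code == "E_VECTOR_QUOTIENT" for d in tree.errors)

    def test_pointwise_quotient_accepted(self):
        _, tree = analyze_source("a = [1 2 3];\nb = [4 5 6];\nc = a ./ b;\n")
        assert not tree.errors

    def test_scalar_division_accepted(self):
        _, tree = analyze_source("a = 6;\nb = 2;\nc = a / b;\n")
        assert not tree.errors

    def test_matmul_inner_dim_mismatch(self):
        _, tree = analyze_source("A = zeros(2, 3);\nB = zeros(2, 3);\nC = A * B;\n")
        assert any(d.code == "E_SHAPE" for d in tree.errors)


class TestDot:
    def test_smallest_tree(self):
        program, tree = analyze_source("x = 1;\n")
        dot = render_dot(tree)
        assert dot.startswith("digraph")
        assert dot.count("label=") >= 3
        assert "real scalar" in dot

    def test_valid_digraph_structure(self):
        program, tree = analyze_source("v = zeros(2, 2);\nw = v + 1;\n")
        dot = render_dot(tree)
        assert dot.rstrip().endswith("}")
        n_nodes = dot.count("[label=")
        n_edges = dot.count("->")
        assert n_edges == n_nodes - 1  # a tree

    def test_deterministic(self):
        program, tree = analyze_source("x = 1;\ny = x * 2;\n")
        assert render_dot(tree) == render_dot(tree)
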