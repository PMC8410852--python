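"""Interpreter, builtin library, ODE solving and the out-of-bound guard."""

import math

import numpy as np
import pytest

from mat2c.diagnostics import MatRuntimeError
from mat2c.runtime import (OdeProblem, RunOptions, Timeseries,
                           builtin_interp1, builtin_load, builtin_setdiff,
                           builtin_union, detect_out_of_bounds, solve_ode)


def scalar(env, name):
    return float(np.asarray(env[name]).flat[0])


class TestEvaluate:
    def test_arithmetic_environment(self, run):
        env, _ = run("x = 1;\ny = x + 2;\n")
        assert scalar(env, "x") == 1.0 and scalar(env, "y") == 3.0

    def test_rastrigin_at_origin_is_zero(self, run, tmp_path):
        # known global minimum of the Rastrigin function
        from mat2c.frontend import SourceUnit, build_program
        from mat2c.sema import analyze
        from mat2c.runtime import evaluate
        from mat2c.fixtures import _OBJECTIVES
        (tmp_path / "rastrigin.m").write_text(_OBJECTIVES["rastrigin"][0])
        program = build_program(
            SourceUnit("m.m", "f0 = rastrigin(zeros(1, 5));\n", is_entry=True),
            [str(tmp_path)])
        tree = analyze(program)
        assert not tree.errors
        env, _ = evaluate(program)
        assert scalar(env, "f0") == 0.0

    def test_exp_decay_matches_closed_form(self, run):
        env, ts = run("rhs = @(t, y) -y;\n[t, y] = ode45(rhs, [0 1], 1);\n")
        grid = ts[0].times
        err = np.abs(ts[0].states[:, 0] - np.exp(-grid))
        assert err.max() < 1e-3 * 1.0 + 1e-6

    def test_value_semantics_copy(self, run):
        env, _ = run("a = [1 2 3];\nb = a;\nb(2) = 99;\nkept = a(2);\n")
        assert scalar(env, "kept") == 2.0

    def test_out_of_range_read_is_error(self, run):
        with pytest.raises(MatRuntimeError) as ei:
            run("a = [1 2];\nx = a(5);\n")
        assert ei.value.first.code == "E_RUNTIME"

    def test_out_of_range_write_grows_zero_filled(self, run):
        env, _ = run("a = [1 2];\na(5) = 9;\nz = a(4);\nn = length(a);\n")
        assert scalar(env, "z") == 0.0 and scalar(env, "n") == 5.0

    def test_while_break_continue(self, run):
        env, _ = run(
            "s = 0;\nk = 0;\nwhile 1\n  k = k + 1;\n  if k > 10\n    break\n"
            "  end\n  if mod(k, 2) == 0\n    continue\n  end\n  s = s + k;\nend\n")
        assert scalar(env, "s") == 25.0

    def test_logical_indexing(self, run):
        env, _ = run("u = [1 -4 9 -16];\npos = u(u > 0);\nn = length(pos);\n")
        assert scalar(env, "n") == 2.0
        assert list(np.asarray(env["pos"]).ravel()) == [1.0, 9.0]

    def test_struct_fields(self, run):
        env, _ = run("p.alpha = 2.5;\np.beta = -1;\nc = p.alpha * 2 + p.beta;\n")
        assert scalar(env, "c") == 4.0


class TestSolveOde:
    def test_exponential_decay_value_at_one(self):
        prob = OdeProblem(rhs=lambda t, y: -y, y0=[1.0], t_span=(0, 2),
                          family="nonstiff")
        grid = np.linspace(0, 2, 201)
        ts = solve_ode(prob, grid)
        y_at_1 = ts.states[100, 0]
        assert abs(y_at_1 - math.exp(-1)) < 1e-3 * math.exp(-1) + 1e-6

    def test_zero_dynamics_constant(self):
        prob = OdeProblem(rhs=lambda t, y: 0 * y, y0=[3.25], t_span=(0, 10),
                          family="nonstiff")
        ts = solve_ode(prob, np.linspace(0, 10, 50))
        assert np.allclose(ts.states, 3.25, rtol=0, atol=1e-12)

    def test_robertson_mass_conservation(self):
        def rob(t, y):
            return np.array([
                -0.04 * y[0] + 1e4 * y[1] * y[2],
                0.04 * y[0] - 1e4 * y[1] * y[2] - 3e7 * y[1] ** 2,
                3e7 * y[1] ** 2])
        prob = OdeProblem(rhs=rob, y0=[1, 0, 0], t_span=(0, 1e4), family="stiff")
        ts = solve_ode(prob, np.linspace(0, 1e4, 200))
        assert np.abs(ts.states.sum(axis=1) - 1.0).max() < 1e-5

    def test_halving_rtol_never_increases_error(self):
        errs = []
        for rtol in (1e-3, 5e-4, 2.5e-4, 1.25e-4):
            prob = OdeProblem(rhs=lambda t, y: -y, y0=[1.0], t_span=(0, 5),
                              rtol=rtol, family="nonstiff")
            grid = np.linspace(0, 5, 100)
            ts = solve_ode(prob, grid)
            errs.append(np.abs(ts.states[:, 0] - np.exp(-grid)).max())
        assert all(b <= a for a, b in zip(errs, errs[1:]))


class TestBuiltins:
    def test_interp1_midpoint(self):
        assert float(builtin_interp1([0, 1], [0, 2], 0.5).flat[0]) == 1.0

    def test_interp1_knot_identity(self):
        x = np.array([0.0, 1.0, 2.5])
        y = np.array([5.0, -1.0, 2.0])
        out = builtin_interp1(x, y, x)
        assert np.array_equal(out.ravel(), y)

    def test_interp1_out_of_range_nan(self):
        assert math.isnan(float(builtin_interp1([0, 1], [0, 2], -1.0).flat[0]))

    def test_interp1_non_monotone_rejected(self):
        with pytest.raises(MatRuntimeError):
            builtin_interp1([0, 2, 1], [1, 2, 3], 0.5)

    @pytest.mark.parametrize("a,b,expect", [
        ([1, 2, 3], [2], [1, 3]),
        ([3, 1, 1], [], [1, 3]),
        ([1], [1], []),
    ])
    def test_setdiff(self, a, b, expect):
        assert list(builtin_setdiff(a, b).ravel()) == expect

    @pytest.mark.parametrize("a,b,expect", [
        ([1, 3], [2], [1, 2, 3]),
        ([], [], []),
        ([1, 1], [1], [1]),
    ])
    def test_union(self, a, b, expect):
        assert list(builtin_union(a, b).ravel()) == expect

    def test_load_matrix(self, tmp_path):
        p = tmp_path / "d.txt"
        p.write_text("1 2\n3 4\n")
        m = builtin_load(str(p))
        assert m.shape == (2, 2) and m[1, 0] == 3.0

    def test_load_scalar(self, tmp_path):
        p = tmp_path / "d.txt"
        p.write_text("5\n")
        assert builtin_load(str(p)).shape == (1, 1)

    def test_load_ragged_rejected(self, tmp_path):
        p = tmp_path / "d.txt"
        p.write_text("1 2\n3\n")
        with pytest.raises(MatRuntimeError) as ei:
            builtin_load(str(p))
        assert ei.value.first.code == "E_IO"

    def test_load_missing_file(self):
        with pytest.raises(MatRuntimeError) as ei:
            builtin_load("definitely_not_here.txt")
        assert ei.value.first.code == "E_IO"


class TestOutOfBoundGuard:
    def test_nan_component_reported_with_time(self):
        d = detect_out_of_bounds([1.0, float("nan")], 3.5, ["y1", "y2"])
        assert d is not None and d.code == "E_OUT_OF_BOUNDS"
        assert "y2" in d.message and "3.5" in d.message

    def test_all_finite_is_none(self):
        assert detect_out_of_bounds([1.0, -2.0], 0.1, ["a", "b"]) is None

    def test_all_offenders_listed(self):
        d = detect_out_of_bounds([float("inf"), float("nan")], 1.0, ["y1", "y2"])
        assert "y1" in d.message and "y2" in d.message
        assert "Inf" in d.message and "NaN" in d.message

    def test_guard_halts_integration(self):
        # rhs turns NaN past t=1: the guard must halt and name the variable
        def rhs(t, y):
            return np.array([math.sqrt(1 - t) if t <= 1 else float("nan")])
        prob = OdeProblem(rhs=rhs, y0=[0.0], t_span=(0, 2), family="nonstiff")
        with pytest.raises(MatRuntimeError) as ei:
            solve_ode(prob, np.linspace(0, 2, 50))
        assert ei.value.first.code == "E_OUT_OF_BOUNDS"
        assert "y1" in ei.value.first.message


class TestTimeseries:
    def test_csv_roundtrip(self, tmp_path):
        ts = Timeseries(times=[0, 1, 2], states=[[1, 2], [3, 4], [5, 6]],
                        names=["a", "b"])
        p = tmp_path / "ts.csv"
        ts.to_csv(str(p))
        back = Timeseries.from_csv(str(p))
        assert back.names == ["a", "b"]
        assert np.array_equal(back.states, ts.states)

    def test_misaligned_rows_rejected(self):
        with pytest.raises(ValueError):
            Timeseries(times=[0, 1], states=[[1.0]], names=["a"])
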