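"""Fixture corpus: determinism, closed-form oracles, coverage, error fixtures."""

import math

import numpy as np
import pytest

from mat2c.codegen import supported_builtins
from mat2c.diagnostics import MatRuntimeError
from mat2c.fixtures import (BENCHMARK_OBJECTIVES, ERROR_FIXTURES,
                            EXECUTABLE_FIXTURES, closed_form_eval,
                            generate_fixture, list_fixtures, series_expm)
from mat2c.frontend import SourceUnit, parse_source
from mat2c.pipeline import analyze_path, interpret_fixture
from mat2c.runtime import RunOptions


class TestCorpus:
    def test_stiff_fixture_present(self):
        assert "robertson_stiff" in list_fixtures()

    def test_benchmark_objectives_present(self):
        assert set(BENCHMARK_OBJECTIVES) <= set(list_fixtures())

    def test_error_fixtures_present(self):
        assert "vector_quotient" in list_fixtures()
        assert "nested_scope_call" in list_fixtures()

    def test_unknown_fixture_rejected(self):
        with pytest.raises(KeyError):
            generate_fixture("no_such_model")

    def test_generation_deterministic(self):
        a = generate_fixture("exp_decay", {"k": 1, "y0": 1})
        b = generate_fixture("exp_decay", {"k": 1, "y0": 1})
        assert a.sources == b.sources

    def test_seeded_random_system_reproducible(self):
        a = generate_fixture("linear_ode_system", {"n": 3}, seed=7)
        b = generate_fixture("linear_ode_system", {"n": 3}, seed=7)
        assert a.sources == b.sources
        c = generate_fixture("linear_ode_system", {"n": 3}, seed=8)
        assert a.sources != c.sources

    @pytest.mark.parametrize("name", sorted(set(EXECUTABLE_FIXTURES) | set(ERROR_FIXTURES)))
    def test_all_sources_parse(self, name):
        spec = generate_fixture(name, {"n": 3} if name == "linear_ode_system" else None)
        for fname, src in spec.sources.items():
            parse_source(SourceUnit(fname, src))


class TestClosedForms:
    def test_exp_decay_initial_condition_exact(self):
        spec = generate_fixture("exp_decay", {"y0": 2.5})
        ts = closed_form_eval(spec, [0.0])
        assert ts.states[0, 0] == 2.5

    def test_harmonic_oscillator_periodicity(self):
        spec = generate_fixture("harmonic_oscillator")
        ts = closed_form_eval(spec, [0.0, 2 * math.pi])
        assert np.allclose(ts.states[0], ts.states[1], atol=1e-12)

    def test_series_expm_against_scipy(self):
        # the brute-force series oracle must agree with an independent route
        from scipy.linalg import expm
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = rng.uniform(-2, 2, size=(4, 4))
            assert np.allclose(series_expm(a), expm(a), rtol=1e-10, atol=1e-12)

    def test_linear_system_oracle_agreement(self):
        spec = generate_fixture("linear_ode_system", {"n": 2}, seed=11)
        A, y0 = spec.expected["matrix"], spec.expected["y0"]
        grid = np.linspace(0, 1, 7)
        ts = closed_form_eval(spec, grid)
        from scipy.linalg import expm
        direct = np.stack([expm(A * t) @ y0 for t in grid])
        assert np.allclose(ts.states, direct, rtol=1e-10, atol=1e-12)

    def test_no_closed_form_raises(self):
        spec = generate_fixture("robertson_stiff")
        with pytest.raises(ValueError):
            closed_form_eval(spec, [0.0])

    def test_positive_trajectories(self):
        """Corpus design: ODE fixture solutions stay strictly positive so the
        floored relative-error statistic is meaningful everywhere."""
        for name, params in [("exp_decay", None), ("logistic", None),
                             ("harmonic_oscillator", None),
                             ("linear_ode_system", {"n": 3})]:
            spec = generate_fixture(name, params, seed=5)
            t0, tf = spec.expected["t_span"]
            ts = closed_form_eval(spec, np.linspace(t0, tf, 400))
            assert ts.states.min() > 1e-3, name


class TestErrorFixtures:
    @pytest.mark.parametrize("name", ["vector_quotient", "nested_scope_call"])
    def test_sema_error_fixture_rejected_with_declared_code(self, name, tmp_path):
        spec = generate_fixture(name)
        entry = spec.write(str(tmp_path / name))
        _, tree = analyze_path(entry)
        codes = {d.code for d in tree.errors}
        assert spec.expected["code"] in codes
        assert codes == {spec.expected["code"]}

    def test_runtime_guard_fixture(self, tmp_path):
        spec = generate_fixture("guard_nan")
        with pytest.raises(MatRuntimeError) as ei:
            interpret_fixture(spec, str(tmp_path / "guard"))
        assert ei.value.first.code == "E_OUT_OF_BOUNDS"


class TestCoverage:
    """Every documented construct and every codegen builtin appears in the
    corpus (spec'd coverage invariant, enforced here)."""

    CONSTRUCTS = {
        "script", "function_def", "assignment", "if", "elseif_branch",
        "else_branch", "for", "while", "break", "continue", "call", "index",
        "range", "binary_op", "unary_op", "transpose", "matrix_literal",
        "number", "string", "identifier", "anonymous_function", "func_handle",
        "field_access", "end_marker",
    }

    CORE_BUILTINS = {
        "zeros", "ones", "size", "length", "abs", "min", "max", "sum", "exp",
        "log", "sqrt", "mod", "linspace", "interp1", "setdiff", "union",
        "load", "ode45", "ode15s",
    }

    def _all_nodes(self, tmp_path):
        # scan after analysis so call-vs-index is settled as in the pipeline
        kinds = set()
        names = set()
        for name in list_fixtures():
            params = {"n": 3} if name == "linear_ode_system" else None
            spec = generate_fixture(name, params)
            entry = spec.write(str(tmp_path / name))
            program, _ = analyze_path(entry)
            for root in program.units.values():
                for n in root.iter_nodes():
                    kinds.add(n.kind)
                    if n.kind == "identifier":
                        names.add(n.name)
                    if n.kind == "call" and n.children[0].kind == "identifier":
                        names.add(n.children[0].name)
        return kinds, names

    def test_every_construct_covered(self, tmp_path):
        kinds, _ = self._all_nodes(tmp_path)
        # elseif/else_branch appear wherever if has branches
        missing = self.CONSTRUCTS - kinds - {"elseif_branch", "else_branch"}
        assert not missing, f"constructs not exercised by any fixture: {missing}"

    def test_core_builtins_covered(self, tmp_path):
        _, names = self._all_nodes(tmp_path)
        missing = self.CORE_BUILTINS - names
        assert not missing, f"builtins not exercised by any fixture: {missing}"
        assert self.CORE_BUILTINS <= supported_builtins()

    def test_at_least_twelve_executable_fixtures(self):
        assert len(EXECUTABLE_FIXTURES) + 1 >= 12  # +1: linear system at n=2 and n=3


class TestBenchmarkDrivers:
    @pytest.mark.parametrize("name", BENCHMARK_OBJECTIVES)
    def test_driver_runs_and_minimum_is_exact_zero(self, name, tmp_path):
        spec = generate_fixture(name, seed=5)
        env, _ = interpret_fixture(spec, str(tmp_path / name), RunOptions())
        assert float(np.asarray(env["fmin"]).flat[0]) == 0.0
        assert float(np.asarray(env["best"]).flat[0]) > 0.0
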