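"""Floored relative-error statistic and comparison reports."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mat2c.numcompare import (ERROR_FLOOR, compare_environments,
                              compare_timeseries, relative_error,
                              resample_to_grid, stochastic_bands_overlap)
from mat2c.runtime import Timeseries

finite = st.floats(min_value=-1e12, max_value=1e12,
                   allow_nan=False, allow_infinity=False)


class TestRelativeError:
    def test_identical_values_are_zero(self):
        assert relative_error(5.0, 5.0) == 0.0

    def test_one_versus_zero_hits_the_floor(self):
        # |1-0| / (1e-6 + 0) = 1e6
        assert relative_error(1.0, 0.0) == pytest.approx(1e6)

    def test_floor_behavior_near_zero(self):
        # 1e-7 / (1e-6 + 1e-7) = 1/11
        assert relative_error(2e-7, 1e-7) == pytest.approx(1.0 / 11.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            relative_error(float("nan"), 1.0)

    @given(a=finite, b=finite)
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_nonnegative(self, a, b):
        e1 = relative_error(a, b)
        e2 = relative_error(b, a)
        assert e1 == e2 >= 0.0

    def test_scale_invariance_away_from_floor(self):
        # invariance under joint rescaling holds when values >> 1e-6 ...
        big = relative_error(2.0, 2.002)
        scaled = relative_error(2000.0, 2002.0)
        assert scaled == pytest.approx(big, rel=1e-3)
        # ... but the floor breaks it near zero
        tiny = relative_error(2e-7, 2.002e-7)
        assert tiny < big


def _ts(times, states, names=("y1",)):
    return Timeseries(times=np.asarray(times, float),
                      states=np.asarray(states, float), names=list(names))


class TestResample:
    def test_identity_on_same_grid(self):
        ts = _ts([0, 1, 2], [[1], [2], [3]])
        out = resample_to_grid(ts, [0, 1, 2])
        assert np.array_equal(out.states, ts.states)

    def test_linear_midpoint(self):
        ts = _ts([0, 1], [[0], [2]])
        out = resample_to_grid(ts, [0.5])
        assert out.states[0, 0] == 1.0

    def test_grid_outside_range_rejected(self):
        ts = _ts([0, 1], [[0], [2]])
        with pytest.raises(ValueError):
            resample_to_grid(ts, [2.0])


class TestCompareTimeseries:
    def test_identical_series_pass_any_tolerance(self):
        ts = _ts([0, 1, 2], [[1, 5], [2, 6], [3, 7]], names=["a", "b"])
        rep = compare_timeseries(ts, ts, tolerance=1e-12)
        assert rep.passed and np.all(rep.per_step_mean_error == 0)

    def test_scaled_variable_fails_and_is_listed(self):
        a = _ts([0, 1, 2], [[1, 5], [2, 6], [3, 7]], names=["a", "b"])
        bad = a.states.copy()
        bad[:, 1] *= 1.5
        b = _ts(a.times, bad, names=["a", "b"])
        rep = compare_timeseries(a, b, tolerance=1e-3)
        assert not rep.passed
        # the scaled variable is an offender at every step; err ~ 0.5 >> tol
        assert {(v, s) for v, s in rep.offenders} == {("b", 0), ("b", 1), ("b", 2)}
        assert rep.max_error == pytest.approx(0.5, rel=1e-3)

    def test_small_deviation_passes_at_paper_tolerance(self):
        a = _ts([0.0], [[1.0]])
        b = _ts([0.0], [[1.0005]])
        rep = compare_timeseries(a, b, tolerance=1e-3)
        # 0.0005 / (1e-6 + 1) ~= 5.0e-4
        assert rep.passed
        assert rep.per_step_mean_error[0] == pytest.approx(5.0e-4, rel=1e-2)

    def test_symmetry_of_error_vector(self):
        rng = np.random.default_rng(0)
        a = _ts(np.arange(5.0), rng.random((5, 3)), names=["a", "b", "c"])
        b = _ts(np.arange(5.0), rng.random((5, 3)), names=["a", "b", "c"])
        r1 = compare_timeseries(a, b, 1e-3)
        r2 = compare_timeseries(b, a, 1e-3)
        assert np.array_equal(r1.per_step_mean_error, r2.per_step_mean_error)

    def test_name_mismatch_rejected(self):
        a = _ts([0], [[1]], names=["x"])
        b = _ts([0], [[1]], names=["y"])
        with pytest.raises(ValueError):
            compare_timeseries(a, b)

    def test_report_json_is_machine_readable(self):
        import json
        ts = _ts([0, 1], [[1], [2]])
        rep = compare_timeseries(ts, ts)
        data = json.loads(rep.to_json())
        assert data["verdict"] == "pass" and data["n_vars"] == 1


class TestEnvironmentComparison:
    def test_identical_env_passes(self):
        env = {"a": np.array([1.0, 2.0]), "b": 3.0}
        rep = compare_environments(env, env)
        assert rep.passed

    def test_offender_named(self):
        a = {"x": 1.0, "y": 2.0}
        b = {"x": 1.0, "y": 3.0}
        rep = compare_environments(a, b, tolerance=1e-3)
        assert not rep.passed and ("y", 0) in rep.offenders


class TestStochasticBands:
    def test_same_distribution_overlaps(self):
        rng = np.random.default_rng(1)
        a = rng.normal(10, 1, size=(8, 5))
        b = rng.normal(10, 1, size=(8, 5))
        assert stochastic_bands_overlap(a, b)

    def test_separated_distributions_do_not(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, size=(8, 5))
        b = rng.normal(10, 0.1, size=(8, 5))
        assert not stochastic_bands_overlap(a, b)
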