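"""C emission: builtin mapping, provenance comments, determinism, and
compile-and-agree checks when a toolchain is present."""

import os
import re

import numpy as np
import pytest

from mat2c.codegen import (CodegenOptions, compile_units, emit_c, map_builtin,
                           run_compiled, write_units)
from mat2c.diagnostics import CompileError, MatRuntimeError
from mat2c.fixtures import generate_fixture
from mat2c.pipeline import analyze_path, translate_fixture

from conftest import analyze_source


def emit_source(src: str):
    program, tree = analyze_source(src)
    assert not tree.errors, [str(d) for d in tree.errors]
    return emit_c(tree)


class TestMapBuiltin:
    def test_interp1_maps_to_linear_interpolation_call(self):
        call = map_builtin("interp1", ["m", "m", "d"])
        code = call.render([("vx", "m"), ("vy", "m"), ("0.5", "d")])
        assert code == "m2c_interp1(vx, vy, m2c_scal(0.5))"

    def test_zeros_allocation_template(self):
        call = map_builtin("zeros", ["d", "d"])
        assert call.render([("3.0", "d"), ("1.0", "d")]) == "m2c_zeros(3.0, 1.0)"
        assert call.result_class == "m"

    def test_unknown_builtin_diagnostic(self):
        with pytest.raises(CompileError) as ei:
            map_builtin("foo", ["d"])
        assert ei.value.first.code == "E_UNKNOWN_BUILTIN"
        assert "foo" in ei.value.first.message

    def test_scalar_specialization(self):
        call = map_builtin("abs", ["d"])
        assert call.render([("x", "d")]) == "fabs(x)"
        assert call.result_class == "d"


class TestEmission:
    def test_source_line_comment_above_translation(self):
        units = emit_source("x = 1;\n")
        src = next(u for u in units if u.dialect == "c99_source")
        assert re.search(r"/\* m\.m:1: x = 1; \*/", src.text)

    def test_one_header_one_source(self):
        units = emit_source("x = 1;\ny = x + 2;\n")
        assert [u.dialect for u in units] == ["c99_header", "c99_source"]

    def test_emission_deterministic(self):
        a = emit_source("v = zeros(2, 2);\nfor i = 1:3\n  v(1, 1) = i;\nend\n")
        b = emit_source("v = zeros(2, 2);\nfor i = 1:3\n  v(1, 1) = i;\nend\n")
        assert a[1].text == b[1].text and a[0].text == b[0].text

    def test_line_map_totality(self):
        """Every source line holding an executable statement appears in the
        emitted line map, and mapped lines carry the matching comment."""
        src = "a = 1;\nb = a * 2;\nif b > 1\n  c = 3;\nend\n"
        units = emit_source(src)
        cu = units[1]
        mapped_src_lines = {v[1] for v in cu.line_map.values()}
        assert {1, 2, 3, 4} <= mapped_src_lines
        lines = cu.text.split("\n")
        for emitted_line, (unit, src_line) in cu.line_map.items():
            assert f"{unit}:{src_line}:" in lines[emitted_line - 1]

    def test_errors_block_emission(self):
        program, tree = analyze_source("a = [1 2];\nb = [3 4];\nc = a / b;\n")
        with pytest.raises(CompileError):
            emit_c(tree)


@pytest.fixture
def compiled_runner(tmp_path, has_cc):
    if not has_cc:
        pytest.skip("no C toolchain on this host")

    def build_and_run(src: str, files=None):
        program, tree = analyze_path_from_source(src, tmp_path, files or {})
        units = emit_c(tree)
        build = tmp_path / "build"
        write_units(units, str(build))
        exe = compile_units(str(build))
        out = tmp_path / "out"
        return run_compiled(exe, str(out), workdir=str(tmp_path))

    return build_and_run


def analyze_path_from_source(src, tmp_path, files):
    entry = tmp_path / "m.m"
    entry.write_text(src)
    for fname, text in files.items():
        (tmp_path / fname).write_text(text)
    return analyze_path(str(entry))


class TestCompiledBehavior:
    def test_arithmetic_environment(self, compiled_runner):
        env, _ = compiled_runner("x = 1;\ny = x + 2;\n")
        assert env["y"].flat[0] == 3.0

    def test_growing_array_and_end(self, compiled_runner):
        env, _ = compiled_runner(
            "w = [];\nfor i = 1:4\n  w(i) = i * i;\nend\nq = w(end);\n")
        assert env["q"].flat[0] == 16.0
        assert list(env["w"].ravel()) == [1.0, 4.0, 9.0, 16.0]

    def test_compiled_ode_writes_timeseries(self, compiled_runner):
        env, series = compiled_runner(
            "rhs = @(t, y) -y;\n[t, y] = ode45(rhs, [0 1], 1);\n")
        assert len(series) == 1
        ts = series[0]
        assert ts.n_steps == 200
        err = np.abs(ts.states[:, 0] - np.exp(-ts.times))
        assert err.max() < 1e-3 + 1e-6

    def test_compiled_guard_names_variable_and_time(self, tmp_path, has_cc):
        if not has_cc:
            pytest.skip("no C toolchain on this host")
        spec = generate_fixture("guard_nan")
        build = translate_fixture(spec, str(tmp_path / "g"))
        exe = compile_units(build)
        with pytest.raises(MatRuntimeError) as ei:
            run_compiled(exe, str(tmp_path / "g" / "out"),
                         workdir=str(tmp_path / "g"))
        msg = ei.value.first.message
        assert ei.value.first.code == "E_OUT_OF_BOUNDS"
        assert "y1" in msg and "t=" in msg

    def test_compile_is_clean_c99(self, tmp_path, has_cc):
        if not has_cc:
            pytest.skip("no C toolchain on this host")
        import subprocess
        spec = generate_fixture("feature_tour")
        build = translate_fixture(spec, str(tmp_path / "ft"))
        import glob
        from mat2c.codegen import find_compiler
        srcs = sorted(glob.glob(os.path.join(build, "*.c")))
        proc = subprocess.run(
            [find_compiler(), "-std=c99", "-Wall", "-pedantic", "-c"] + srcs,
            cwd=build, capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        assert "error:" not in proc.stderr
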