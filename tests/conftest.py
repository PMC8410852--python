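import pytest

from mat2c.frontend import SourceUnit, build_program
from mat2c.sema import analyze
from mat2c.runtime import RunOptions, evaluate
from mat2c.codegen import find_compiler


@pytest.fixture(scope="session")
def has_cc() -> bool:
    return find_compiler() is not None


def analyze_source(src: str, name: str = "m.m"):
    """Parse + scope-resolve + infer a single-unit program."""
    program = build_program(SourceUnit(name, src, is_entry=True))
    tree = analyze(program)
    return program, tree


def run_source(src: str, name: str = "m.m", **options):
    """Full interpreter run of a single script; asserts clean analysis."""
    program, tree = analyze_source(src, name)
    assert not tree.errors, [str(d) for d in tree.errors]
    return evaluate(program, RunOptions(**options))


@pytest.fixture
def run():
    return run_source


@pytest.fixture
def analyze_src():
    return analyze_source
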