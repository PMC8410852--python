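"""Builtin -> C translation table.

:func:`map_builtin` resolves a dialect builtin name plus argument value
classes to a call template for the emitted C.  Value classes are ``"d"``
(plain double), ``"m"`` (``m2c_mat``) and ``"s"`` (C string literal).  The
returned :class:`BuiltinCall` renders the call from ``(code, class)`` pairs,
coercing each argument to what the runtime function expects, and declares
the result class so the expression emitter can keep scalar subexpressions
in plain doubles.  Unknown names raise an unknown-builtin diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Tuple

from ..diagnostics import CompileError, E_UNKNOWN_BUILTIN, SourceLocation, error

_PI = "3.1415926535897931"

Pair = Tuple[str, str]  # (C code, value class)


def _d(p: Pair) -> str:
    code, cls = p
    return code if cls == "d" else f"m2c_item({code})"


def _m(p: Pair) -> str:
    code, cls = p
    return code if cls == "m" else f"m2c_scal({code})"


def _s(p: Pair) -> str:
    return p[0]


@dataclass
class BuiltinCall:
    """A resolved builtin: ``render(pairs)`` produces the C expression."""

    name: str
    result_class: str                      # "d" | "m" | "void"
    render: Callable[[List[Pair]], str]


def _elementwise(name: str, tag: str, dfn: str):
    def resolve(classes):
        if classes == ["d"]:
            return BuiltinCall(name, "d", lambda a: f"{dfn}({_d(a[0])})")
        return BuiltinCall(name, "m", lambda a: f"m2c_map({tag}, {_m(a[0])})")
    return resolve


def _dims(cfn: str):
    """zeros/ones/eye/rand/randn: one dimension argument means square."""
    def resolve(classes):
        def render(a):
            if len(a) == 0:
                return f"{cfn}(1.0, 1.0)"
            if len(a) == 1:
                return f"{cfn}({_d(a[0])}, {_d(a[0])})"
            return f"{cfn}({_d(a[0])}, {_d(a[1])})"
        return BuiltinCall(cfn, "m", render)
    return resolve


def _minmax(which: str):
    def resolve(classes):
        if len(classes) == 2:
            if classes == ["d", "d"]:
                fn = "fmin" if which == "min" else "fmax"
                return BuiltinCall(which, "d",
                                   lambda a: f"{fn}({_d(a[0])}, {_d(a[1])})")
            return BuiltinCall(which, "m",
                               lambda a: f"m2c_{which}2({_m(a[0])}, {_m(a[1])})")
        return BuiltinCall(which, "m", lambda a: f"m2c_{which}1({_m(a[0])})")
    return resolve


def _modrem(which: str):
    def resolve(classes):
        if classes == ["d", "d"]:
            return BuiltinCall(which, "d",
                               lambda a: f"m2c_d{which}({_d(a[0])}, {_d(a[1])})")
        return BuiltinCall(which, "m",
                           lambda a: f"m2c_{which}({_m(a[0])}, {_m(a[1])})")
    return resolve


def _size(classes):
    if len(classes) == 2:
        return BuiltinCall("size", "d",
                           lambda a: f"m2c_size_dim({_m(a[0])}, {_d(a[1])})")
    return BuiltinCall("size", "m", lambda a: f"m2c_size({_m(a[0])})")


def _m1(name: str, cfn: str, result: str = "m"):
    def resolve(classes):
        return BuiltinCall(name, result, lambda a: f"{cfn}({_m(a[0])})")
    return resolve


def _m2(name: str, cfn: str, result: str = "m"):
    def resolve(classes):
        return BuiltinCall(name, result,
                           lambda a: f"{cfn}({_m(a[0])}, {_m(a[1])})")
    return resolve


_TABLE = {
    "pi": lambda classes: BuiltinCall("pi", "d", lambda a: _PI),
    "zeros": _dims("m2c_zeros"),
    "ones": _dims("m2c_ones"),
    "eye": _dims("m2c_eye"),
    "rand": _dims("m2c_rand"),
    "randn": _dims("m2c_randn"),
    "size": _size,
    "length": _m1("length", "m2c_length", "d"),
    "numel": _m1("numel", "m2c_numel", "d"),
    "abs": _elementwise("abs", "M2C_ABS", "fabs"),
    "exp": _elementwise("exp", "M2C_EXP", "exp"),
    "log": _elementwise("log", "M2C_LOG", "log"),
    "log10": _elementwise("log10", "M2C_LOG10", "log10"),
    "sqrt": _elementwise("sqrt", "M2C_SQRT", "sqrt"),
    "sin": _elementwise("sin", "M2C_SIN", "sin"),
    "cos": _elementwise("cos", "M2C_COS", "cos"),
    "tan": _elementwise("tan", "M2C_TAN", "tan"),
    "floor": _elementwise("floor", "M2C_FLOOR", "floor"),
    "ceil": _elementwise("ceil", "M2C_CEIL", "ceil"),
    "round": lambda classes: (
        BuiltinCall("round", "d", lambda a: f"floor({_d(a[0])} + 0.5)")
        if classes == ["d"] else
        BuiltinCall("round", "m", lambda a: f"m2c_map(M2C_ROUND, {_m(a[0])})")),
    "mod": _modrem("mod"),
    "rem": _modrem("rem"),
    "min": _minmax("min"),
    "max": _minmax("max"),
    "sum": _m1("sum", "m2c_sum"),
    "prod": _m1("prod", "m2c_prod"),
    "any": _m1("any", "m2c_any", "d"),
    "all": _m1("all", "m2c_all", "d"),
    "isempty": _m1("isempty", "m2c_isempty", "d"),
    "norm": _m1("norm", "m2c_norm", "d"),
    "dot": _m2("dot", "m2c_dot", "d"),
    "linspace": lambda classes: BuiltinCall(
        "linspace", "m",
        lambda a: f"m2c_linspace({_d(a[0])}, {_d(a[1])}, {_d(a[2])})"),
    "interp1": lambda classes: BuiltinCall(
        "interp1", "m",
        lambda a: f"m2c_interp1({_m(a[0])}, {_m(a[1])}, {_m(a[2])})"),
    "setdiff": _m2("setdiff", "m2c_setdiff"),
    "union": _m2("union", "m2c_union"),
    "unique": _m1("unique", "m2c_unique"),
    "sort": _m1("sort", "m2c_sort"),
    "find": _m1("find", "m2c_find"),
    "repmat": lambda classes: BuiltinCall(
        "repmat", "m",
        lambda a: f"m2c_repmat({_m(a[0])}, {_d(a[1])}, {_d(a[2])})"),
    "load": lambda classes: BuiltinCall(
        "load", "m", lambda a: f"m2c_load({_s(a[0])})"),
    "disp": lambda classes: BuiltinCall("disp", "void", lambda a: "(void)0"),
    "fprintf": lambda classes: BuiltinCall("fprintf", "void", lambda a: "(void)0"),
}

#: names handled by dedicated statement forms, not the expression table
SPECIAL_FORMS = frozenset({"ode45", "ode23", "ode15s", "odeset"})


def map_builtin(name: str, arg_classes: List[str],
                loc: Optional[SourceLocation] = None) -> BuiltinCall:
    """Resolve a builtin name + argument classes to its C call template."""
    if name in SPECIAL_FORMS:
        raise CompileError(error(
            E_UNKNOWN_BUILTIN,
            f"builtin {name!r} is only supported in its statement form "
            "([t, y] = odeXX(rhs, tspan, y0))", loc))
    if name not in _TABLE:
        raise CompileError(error(
            E_UNKNOWN_BUILTIN, f"no C mapping for builtin {name!r}", loc))
    return _TABLE[name](list(arg_classes))


def supported_builtins() -> frozenset:
    return frozenset(_TABLE) | SPECIAL_FORMS
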