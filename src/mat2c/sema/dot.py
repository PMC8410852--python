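"""Render an annotated tree as DOT text for inspection with graphviz."""

from __future__ import annotations

from ..frontend.astnodes import Node
from .infer import AnnotatedTree


def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _label(tree: AnnotatedTree, n: Node) -> str:
    parts = [n.kind]
    if n.name is not None:
        parts.append(str(n.name))
    if n.op is not None:
        parts.append(n.op)
    if n.value is not None:
        parts.append(repr(n.value) if not isinstance(n.value, float) else
                     ("%g" % n.value))
    t = tree.type_of(n)
    parts.append(f": {t}")
    return _escape(" ".join(parts))


def render_dot(tree: AnnotatedTree, unit: str | None = None) -> str:
    """Deterministic DOT digraph of the (possibly partially) annotated tree;
    every node is labeled with its kind and inferred type."""
    unit = unit or tree.program.entry
    root = tree.program.units[unit]
    lines = ["digraph aast {", '  node [shape=box, fontname="monospace"];']
    counter = [0]

    def emit(n: Node) -> int:
        my = counter[0]
        counter[0] += 1
        lines.append(f'  n{my} [label="{_label(tree, n)}"];')
        kids = list(n.children) + list(n.subfunctions or [])
        for c in kids:
            cid = emit(c)
            lines.append(f"  n{my} -> n{cid};")
        return my

    emit(root)
    lines.append("}")
    return "\n".join(lines) + "\n"
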