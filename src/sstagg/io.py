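"""Reading and writing edge lists, node scores, weight and sign tables.

Default edge-list dialect (tab- or whitespace-separated)::

    #ref<TAB>A            # optional directive naming the reference node
    A   ->   B            # +1: increase in A causes increase in B
    B   -|   C   direct   # -1, with optional semantic edge class
    # comment lines start with '#'

Relation tokens: ``->`` / ``-|`` or ``increases`` / ``decreases``; the
``sif`` dialect additionally accepts ``activates`` / ``inhibits``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

from .errors import ConfigurationError, GraphParseError
from .graph import EDGE_CLASSES, SignedEdge, SignedGraph

_BASE_TOKENS = {
    "->": 1,
    "increases": 1,
    "-|": -1,
    "decreases": -1,
}
_SIF_TOKENS = {**_BASE_TOKENS, "activates": 1, "inhibits": -1}

DIALECTS = {"tsv": _BASE_TOKENS, "sif": _SIF_TOKENS}


def read_graph(
    path: str | Path,
    dialect: str = "tsv",
    reference: str | None = None,
) -> SignedGraph:
    """Parse an edge-list file into a :class:`SignedGraph`.

    The reference node comes from a ``#ref`` directive line unless overridden
    by the ``reference`` argument.  Duplicate identical edges (same endpoints,
    sign, class and direction) are collapsed with a warning; contradictory
    parallel edges (opposite signs) are retained as distinct edges.  A line
    declaring a bare node name (single column) adds an isolated node, which
    is only useful for the degenerate single-node graph.
    """
    if dialect not in DIALECTS:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}"
        )
    tokens = DIALECTS[dialect]
    path = Path(path)
    edges: list[SignedEdge] = []
    declared: list[str] = []
    seen: set[tuple[str, str, int, str]] = set()
    n_dupes = 0
    ref_directive: str | None = None

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.lower().startswith("ref"):
                parts = body.split(None, 1)
                if len(parts) == 2:
                    ref_directive = parts[1].strip()
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        fields = [f.strip() for f in fields if f.strip()]
        if len(fields) == 1:
            declared.append(fields[0])
            continue
        if len(fields) not in (3, 4):
            raise GraphParseError(
                f"{path.name}:{lineno}: expected 'source relation target [class]', "
                f"got {len(fields)} fields"
            )
        source, relation, target = fields[:3]
        if relation not in tokens:
            raise GraphParseError(
                f"{path.name}:{lineno}: unknown relation token {relation!r} "
                f"(dialect {dialect!r} accepts {sorted(tokens)})"
            )
        edge_class = fields[3] if len(fields) == 4 else "default"
        if edge_class not in EDGE_CLASSES:
            raise GraphParseError(
                f"{path.name}:{lineno}: unknown edge class {edge_class!r}"
            )
        key = (source, target, tokens[relation], edge_class)
        if key in seen:
            n_dupes += 1
            continue
        seen.add(key)
        edges.append(SignedEdge(source, target, tokens[relation], edge_class))

    if n_dupes:
        warnings.warn(
            f"{path.name}: collapsed {n_dupes} duplicate identical edge(s)",
            stacklevel=2,
        )
    ref = reference if reference is not None else ref_directive
    if ref is None:
        raise ConfigurationError(
            f"{path.name}: no reference node; add a '#ref\\t<node>' directive "
            "or pass reference="
        )
    return SignedGraph(edges, reference=ref, nodes=declared or None)


def write_graph(graph: SignedGraph, path: str | Path) -> None:
    """Write a graph in the default edge-list dialect (round-trips read_graph)."""
    path = Path(path)
    lines = [f"#ref\t{graph.reference}"]
    covered = set()
    for e in graph.edges:
        rel = "->" if e.sign > 0 else "-|"
        cls = "" if e.edge_class == "default" else f"\t{e.edge_class}"
        lines.append(f"{e.source}\t{rel}\t{e.target}{cls}")
        covered.add(e.source)
        covered.add(e.target)
    for n in graph.nodes:
        if n not in covered:
            lines.append(n)
    path.write_text("\n".join(lines) + "\n")


def read_scores(path: str | Path) -> dict[str, float]:
    """Read a node-score table: ``node<TAB>score``, header line optional."""
    path = Path(path)
    out: dict[str, float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 2:
            raise GraphParseError(
                f"{path.name}:{lineno}: expected 'node<TAB>score'"
            )
        node, value = fields
        try:
            x = float(value)
        except ValueError:
            if lineno == 1:  # tolerated header
                continue
            raise GraphParseError(
                f"{path.name}:{lineno}: non-numeric score {value!r}"
            ) from None
        out[node] = x
    return out


def write_scores(scores: Mapping[str, float], path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(f"{n}\t{x}" for n, x in scores.items()) + "\n"
    )


def read_signs(path: str | Path) -> dict[str, int]:
    """Read a node-sign table (values must be -1 or +1), e.g. pruned-network signs."""
    raw = read_scores(path)
    out: dict[str, int] = {}
    for n, v in raw.items():
        s = int(v)
        if s not in (-1, 1) or s != v:
            raise GraphParseError(f"sign for node {n!r} must be -1 or +1, got {v}")
        out[n] = s
    return out
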