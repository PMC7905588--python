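"""Weighted co-occurrence networks: construction, normalization, Pajek I/O.

An edge joins two features whenever both are positive in the same subject;
its weight is the number of subjects in which the pair co-occurs. The
network is stored as triples ``[Vi, Vj, Wij]`` (one row per unordered pair,
no self-loops) alongside the node catalog, the representation commonly used
to feed Pajek.

Pajek dialect
-------------
``write_pajek`` emits and ``read_pajek`` accepts this undirected dialect::

    *Vertices <n>
    1 "CODE" "Display label" block
    ...
    *Edges
    i j w

Vertex ids are 1-based; the code is always double-quoted, the display label
and block are optional on input (defaulting to the code and ``symptom``).
``*Arcs`` sections are rejected: co-occurrence networks are undirected.
"""

from __future__ import annotations

import logging
import shlex
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fatiguenet.containers import BLOCKS, BinaryCohortMatrix, Feature

logger = logging.getLogger(__name__)


class PajekParseError(ValueError):
    """Malformed Pajek file; the message names the offending line."""


@dataclass
class WeightedCooccurrenceNetwork:
    """Undirected weighted network of co-occurring symptoms/indexes."""

    nodes: list[Feature]
    triples: list[tuple[str, str, float]]
    _adj: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        codes = {f.code for f in self.nodes}
        if len(codes) != len(self.nodes):
            raise ValueError("duplicate node codes")
        seen = set()
        for a, b, w in self.triples:
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if a not in codes or b not in codes:
                raise ValueError(f"edge endpoint not in node list: ({a}, {b})")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate edge ({a}, {b})")
            seen.add(key)
            if w <= 0:
                raise ValueError(f"edge weight must be positive, got {w} on ({a}, {b})")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def codes(self) -> list[str]:
        return [f.code for f in self.nodes]

    def node(self, code: str) -> Feature:
        for f in self.nodes:
            if f.code == code:
                return f
        raise KeyError(code)

    def adjacency(self) -> dict[str, dict[str, float]]:
        """code -> {neighbor code -> weight}; cached."""
        if self._adj is None:
            adj: dict[str, dict[str, float]] = {f.code: {} for f in self.nodes}
            for a, b, w in self.triples:
                adj[a][b] = w
                adj[b][a] = w
            self._adj = adj
        return self._adj


def build_network(matrix: BinaryCohortMatrix,
                  blocks: tuple[str, ...] | None = None) -> WeightedCooccurrenceNetwork:
    """Count pairwise co-occurrences across subjects.

    ``W_ij`` is the number of subjects with both features positive; pairs
    never observed together get no edge, but features that are isolated (or
    never positive) are kept as nodes so counts match the catalog.
    """
    sub = matrix.subset(blocks)
    X = sub.data.to_numpy(dtype=np.int64)
    co = X.T @ X  # diagonal = marginal counts, off-diagonal = co-occurrence
    codes = sub.codes
    triples = [
        (codes[i], codes[j], float(co[i, j]))
        for i in range(len(codes))
        for j in range(i + 1, len(codes))
        if co[i, j] > 0
    ]
    nodes = [Feature(f.code, f.label, f.block, f.prevalence) for f in sub.features]
    return WeightedCooccurrenceNetwork(nodes, triples)


def normalize_weights(network: WeightedCooccurrenceNetwork) -> pd.DataFrame:
    """Association table: each pair's weight divided by the global maximum.

    Columns ``pair_a, pair_b, block_a, block_b, raw_weight,
    normalized_weight``, sorted by normalized weight descending (ties broken
    by raw weight descending, then lexicographic pair codes). The heaviest
    pair is exactly 1.0 by construction.
    """
    if not network.triples:
        raise ValueError("network has no edges to normalize")
    w_max = max(w for _, _, w in network.triples)
    blocks = {f.code: f.block for f in network.nodes}
    rows = []
    for a, b, w in network.triples:
        a, b = sorted((a, b))
        rows.append({"pair_a": a, "pair_b": b, "block_a": blocks[a], "block_b": blocks[b],
                     "raw_weight": w, "normalized_weight": w / w_max})
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["normalized_weight", "raw_weight", "pair_a", "pair_b"],
        ascending=[False, False, True, True], kind="mergesort",
    ).reset_index(drop=True)
    return table


def filter_associations(table: pd.DataFrame, mode: str = "threshold",
                        value: float | int = 0.5,
                        cross_block: bool = False) -> pd.DataFrame:
    """Keep the strongest associations.

    ``threshold`` keeps rows with normalized weight strictly above ``value``;
    ``top_k`` keeps the first ``value`` rows of the sorted table. With
    ``cross_block=True`` only symptom-index pairs are considered (the
    combined-network view).
    """
    out = table
    if cross_block:
        out = out[out["block_a"] != out["block_b"]].reset_index(drop=True)
    if mode == "threshold":
        if not 0.0 <= float(value) < 1.0:
            raise ValueError(f"threshold must be in [0, 1), got {value}")
        return out[out["normalized_weight"] > float(value)].reset_index(drop=True)
    if mode == "top_k":
        k = int(value)
        if k <= 0:
            raise ValueError(f"top_k requires k >= 1, got {value}")
        if k > len(out):
            logger.warning("filter_associations: k=%d exceeds table size %d, returning all",
                           k, len(out))
        return out.head(k).reset_index(drop=True)
    raise ValueError(f"unknown mode {mode!r}")


def _fmt_weight(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else repr(float(w))


def write_pajek(network: WeightedCooccurrenceNetwork, path: str | Path) -> None:
    """Write the network in the undirected Pajek ``.NET`` dialect above."""
    lines = [f"*Vertices {network.n}"]
    index = {}
    for i, f in enumerate(network.nodes, start=1):
        index[f.code] = i
        lines.append(f'{i} "{f.code}" "{f.label}" {f.block}')
    lines.append("*Edges")
    for a, b, w in network.triples:
        lines.append(f"{index[a]} {index[b]} {_fmt_weight(w)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pajek(path: str | Path) -> WeightedCooccurrenceNetwork:
    """Parse a Pajek ``.NET`` file in the dialect written by :func:`write_pajek`."""
    text = Path(path).read_text()
    nodes: list[Feature] = []
    order: dict[int, str] = {}
    triples: list[tuple[str, str, float]] = []
    seen_pairs: set[frozenset] = set()
    n_declared = None
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("*"):
            if low.startswith("*vertices"):
                parts = line.split()
                if len(parts) != 2 or not parts[1].isdigit():
                    raise PajekParseError(f"line {lineno}: malformed *Vertices header: {raw!r}")
                n_declared = int(parts[1])
                section = "vertices"
            elif low.startswith("*edges"):
                if n_declared is None:
                    raise PajekParseError(f"line {lineno}: *Edges before *Vertices")
                section = "edges"
            elif low.startswith("*arcs"):
                raise PajekParseError(
                    f"line {lineno}: *Arcs sections are not supported "
                    "(co-occurrence networks are undirected)")
            else:
                raise PajekParseError(f"line {lineno}: unknown section {raw!r}")
            continue
        if section == "vertices":
            try:
                parts = shlex.split(line)
            except ValueError as exc:
                raise PajekParseError(f"line {lineno}: unbalanced quotes: {raw!r}") from exc
            if len(parts) < 2 or not parts[0].isdigit():
                raise PajekParseError(f"line {lineno}: malformed vertex line: {raw!r}")
            if not ('"' in line):
                raise PajekParseError(f"line {lineno}: vertex label must be double-quoted: {raw!r}")
            vid = int(parts[0])
            if not 1 <= vid <= n_declared:
                raise PajekParseError(
                    f"line {lineno}: vertex id {vid} outside 1..{n_declared}")
            if vid in order:
                raise PajekParseError(f"line {lineno}: duplicate vertex id {vid}")
            code = parts[1]
            label = parts[2] if len(parts) >= 3 else code
            block = parts[3] if len(parts) >= 4 else "symptom"
            if block not in BLOCKS:
                raise PajekParseError(f"line {lineno}: unknown block {block!r}")
            order[vid] = code
            nodes.append(Feature(code, label, block))
        elif section == "edges":
            parts = line.split()
            if len(parts) != 3:
                raise PajekParseError(f"line {lineno}: edge line must be 'i j w': {raw!r}")
            try:
                i, j = int(parts[0]), int(parts[1])
                w = float(parts[2])
            except ValueError as exc:
                raise PajekParseError(f"line {lineno}: non-numeric edge entry: {raw!r}") from exc
            for vid in (i, j):
                if vid not in order:
                    raise PajekParseError(f"line {lineno}: vertex index {vid} out of range")
            key = frozenset((i, j))
            if i == j:
                raise PajekParseError(f"line {lineno}: self-loop on vertex {i}")
            if key in seen_pairs:
                raise PajekParseError(f"line {lineno}: duplicate edge ({i}, {j})")
            seen_pairs.add(key)
            triples.append((order[i], order[j], w))
        else:
            raise PajekParseError(f"line {lineno}: content outside any section: {raw!r}")
    if n_declared is None:
        raise PajekParseError("no *Vertices section found")
    if len(nodes) != n_declared:
        raise PajekParseError(
            f"*Vertices declares {n_declared} vertices but {len(nodes)} defined")
    return WeightedCooccurrenceNetwork(nodes, triples)
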