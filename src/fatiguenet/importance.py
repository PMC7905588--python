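"""Node importance by contraction in weighted co-occurrence networks.

The cohesion of a weighted network WG is

    d(WG) = 1 / (s * l)

where ``s`` aggregates node strength (by default the sum over non-isolated
nodes of strength divided by the number of neighbours) and ``l`` is the mean
shortest hop distance of the unweighted graph obtained by keeping edges
above a weight threshold. Contracting a node merges it with all its
neighbours into one super-node (parallel edges to outside nodes summed).
The importance of node Vi is

    IMC(Vi) = 1 - d(WG) / d(WG * Vi)

with d(WG * Vi) the cohesion after contracting Vi. Contracting a node whose
neighbourhood spans the whole connected part collapses the network and
yields IMC = 1 by the limit convention; a contraction that leaves cohesion
unchanged yields IMC = 0.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass

import pandas as pd

from fatiguenet.containers import Feature
from fatiguenet.conet import WeightedCooccurrenceNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohesionParams:
    """Choices in evaluating the cohesion statistic.

    ``strength_aggregation``: ``prose`` sums strength_i / degree_i over
    non-isolated nodes; ``typeset`` sums degree_i * strength_i (an
    alternative reading of the same statistic, kept for sensitivity checks).
    ``edge_threshold``: minimum weight (strict) for an edge of the unweighted
    distance graph; 0 keeps every positive co-occurrence.
    ``disconnected_policy``: ``finite_pairs_only`` averages distances over
    reachable pairs; ``component_restricted`` evaluates the statistic on the
    largest connected component only.
    """

    strength_aggregation: str = "prose"
    edge_threshold: float = 0.0
    disconnected_policy: str = "finite_pairs_only"

    def __post_init__(self) -> None:
        if self.strength_aggregation not in ("prose", "typeset"):
            raise ValueError(f"unknown strength_aggregation {self.strength_aggregation!r}")
        if self.edge_threshold < 0:
            raise ValueError("edge_threshold must be >= 0")
        if self.disconnected_policy not in ("finite_pairs_only", "component_restricted"):
            raise ValueError(f"unknown disconnected_policy {self.disconnected_policy!r}")


def node_strength(network: WeightedCooccurrenceNetwork, v: str) -> float:
    """Sum of weights of edges incident to ``v`` (0 for isolated nodes)."""
    if v not in network.adjacency():
        raise KeyError(f"unknown node {v!r}")
    return float(sum(network.adjacency()[v].values()))


def _components(adj: dict[str, dict[str, float]], threshold: float) -> list[set[str]]:
    seen: set[str] = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for w, wt in adj[u].items():
                if wt > threshold and w not in comp:
                    comp.add(w)
                    queue.append(w)
        seen |= comp
        comps.append(comp)
    return comps


def _hop_distance_stats(adj: dict[str, dict[str, float]], nodes: set[str] | None,
                        threshold: float) -> tuple[int, int]:
    """(sum of hop distances, count) over ordered reachable pairs (BFS per node)."""
    universe = set(adj) if nodes is None else nodes
    total = 0
    pairs = 0
    for src in universe:
        dist = {src: 0}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for w, wt in adj[u].items():
                if wt > threshold and w not in dist and w in universe:
                    dist[w] = dist[u] + 1
                    queue.append(w)
        total += sum(dist.values())
        pairs += len(dist) - 1
    if pairs == 0:
        raise ValueError("no connected pairs: cohesion undefined")
    return total, pairs


def cohesion(network: WeightedCooccurrenceNetwork,
             params: CohesionParams | None = None) -> float:
    """Cohesion d(WG) = 1 / (s * l); +inf for a single-node network."""
    params = params or CohesionParams()
    if network.n == 0:
        raise ValueError("empty network")
    if network.n == 1:
        return math.inf
    adj = network.adjacency()
    if not network.triples:
        raise ValueError("all nodes isolated: cohesion undefined")

    nodes: set[str] | None = None
    if params.disconnected_policy == "component_restricted":
        comps = _components(adj, params.edge_threshold)
        nodes = max(comps, key=len)

    universe = set(adj) if nodes is None else nodes
    s = 0.0
    for u in universe:
        nbrs = {w: wt for w, wt in adj[u].items()
                if wt > 0 and w in universe}
        if not nbrs:
            continue
        strength = sum(nbrs.values())
        if params.strength_aggregation == "prose":
            s += strength / len(nbrs)
        else:  # typeset
            s += len(nbrs) * strength
    # 1/(s*l) with l = total/pairs; dividing integers last keeps the
    # hand-derivable values (1/4, 1/3, ...) exact in floating point
    total, pairs = _hop_distance_stats(adj, nodes, params.edge_threshold)
    return pairs / (s * total)


def contract_node(network: WeightedCooccurrenceNetwork, v: str) -> WeightedCooccurrenceNetwork:
    """Merge ``v`` and all its neighbours into a single super-node.

    Edges from the merged set to an outside node are replaced by one edge
    carrying their summed weight; edges internal to the merged set vanish.
    """
    adj = network.adjacency()
    if v not in adj:
        raise KeyError(f"unknown node {v!r}")
    merged = {v} | set(adj[v])
    node_v = network.node(v)
    new_code = v + "*"
    while new_code in adj:  # ensure uniqueness against existing codes
        new_code += "*"
    new_nodes = [Feature(new_code, f"contracted({v})", node_v.block)]
    new_nodes += [f for f in network.nodes if f.code not in merged]

    outside_w: dict[str, float] = {}
    new_triples: list[tuple[str, str, float]] = []
    for a, b, w in network.triples:
        a_in, b_in = a in merged, b in merged
        if a_in and b_in:
            continue
        if a_in or b_in:
            out = b if a_in else a
            outside_w[out] = outside_w.get(out, 0.0) + w
        else:
            new_triples.append((a, b, w))
    new_triples += [(new_code, out, w) for out, w in sorted(outside_w.items())]
    return WeightedCooccurrenceNetwork(new_nodes, new_triples)


def _cohesion_or_inf(network: WeightedCooccurrenceNetwork, params: CohesionParams) -> float:
    """Cohesion, with edgeless (fully collapsed) networks mapped to +inf."""
    if network.n <= 1 or not network.triples:
        return math.inf
    return cohesion(network, params)


def imc(network: WeightedCooccurrenceNetwork, v: str,
        params: CohesionParams | None = None) -> float:
    """Importance of ``v``: 1 - d(WG) / d(WG * Vi)."""
    params = params or CohesionParams()
    d0 = cohesion(network, params)
    dv = _cohesion_or_inf(contract_node(network, v), params)
    if math.isinf(dv):
        return 1.0
    return 1.0 - d0 / dv


def rank_core(network: WeightedCooccurrenceNetwork,
              params: CohesionParams | None = None,
              k: int = 10) -> tuple[pd.DataFrame, list[str]]:
    """Rank all nodes by IMC and return the importance table plus the core set.

    Ties are broken by strength descending, then code lexicographically, so
    the ranking is deterministic. Columns: node, label, imc, rank, strength,
    degree.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    params = params or CohesionParams()
    adj = network.adjacency()
    rows = []
    for f in network.nodes:
        rows.append({
            "node": f.code,
            "label": f.label,
            "imc": imc(network, f.code, params),
            "strength": node_strength(network, f.code),
            "degree": len(adj[f.code]),
        })
    table = pd.DataFrame(rows)
    table = table.sort_values(by=["imc", "strength", "node"],
                              ascending=[False, False, True],
                              kind="mergesort").reset_index(drop=True)
    table["rank"] = range(1, len(table) + 1)
    table = table[["node", "label", "imc", "rank", "strength", "degree"]]
    if k > network.n:
        logger.warning("rank_core: k=%d exceeds node count %d, returning all", k, network.n)
    core = table["node"].head(min(k, network.n)).tolist()
    return table, core


def extract_core_subnetwork(network: WeightedCooccurrenceNetwork,
                            core: list[str] | set[str],
                            core_b: list[str] | set[str] | None = None):
    """Induced subgraph on the core node set(s), raw weights retained.

    With one set, returns the induced network. With two sets (the combined
    symptom-index view), returns ``(network, roles)`` where ``roles`` maps
    each edge's sorted pair to ``within_a``/``within_b``/``cross``.
    """
    adj = network.adjacency()
    sets = [set(core)] + ([set(core_b)] if core_b is not None else [])
    for cs in sets:
        unknown = cs - set(adj)
        if unknown:
            raise KeyError(f"unknown core nodes: {sorted(unknown)}")
    keep = set().union(*sets)
    nodes = [f for f in network.nodes if f.code in keep]
    triples = [(a, b, w) for a, b, w in network.triples if a in keep and b in keep]
    sub = WeightedCooccurrenceNetwork(nodes, triples)
    if core_b is None:
        return sub
    set_a, set_b = sets
    roles = {}
    for a, b, _ in triples:
        key = tuple(sorted((a, b)))
        if a in set_a and b in set_a:
            roles[key] = "within_a"
        elif a in set_b and b in set_b:
            roles[key] = "within_b"
        else:
            roles[key] = "cross"
    return sub, roles
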