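"""Topological node importance via iterative minimum-degree reduction.

Peeling a network from its lowest-degree nodes upward concentrates weight on
hubs and bottlenecks: every removed node hands its accumulated mass to the
part of the graph that survives it.  Node weights start at 0 and edge weights
at 1; removing a node v of current degree k transfers

* k = 0: nothing;
* k = 1 (neighbor u): node_weight(u) += node_weight(v) + edge_weight(v, u);
* k >= 2: for every unordered neighbor pair (u, z),
  edge_weight(u, z) += [node_weight(v) + edge_weight(v, u) + edge_weight(v, z)] / C(k, 2),
  creating the "skeleton" edge (u, z) with weight 0 first if it is absent.

Reduction stops when every remaining node has degree > d (or the graph is
empty).  A node's importance S(v) is its final node weight plus the weight of
its surviving incident edges; nodes that were removed freeze their node
weight at removal time.  The cross-network topological similarity of two
nodes is the min/max ratio of their importances, a scale-aware score in
[0, 1] that is 1 exactly when the importances agree and are positive.

The reduction is deterministic: among minimum-degree candidates the
lexicographically smallest node ID is removed first.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import networkx as nx

from .biosim import SimMatrix


@dataclass
class TopoWeights:
    """Result of the minimum-degree reduction of one network."""

    node_weight: dict[str, float]
    edge_weight: dict[tuple[str, str], float]  # surviving edges, sorted-tuple keys
    importance: dict[str, float]
    threshold_d: int
    #: per-removal trace: (node, degree at removal, live node+edge mass after)
    trace: list[tuple[str, int, float]] = field(default_factory=list)


def min_degree_reduce(net: nx.Graph, d: int = 10, record_trace: bool = False) -> TopoWeights:
    """Run the minimum-degree heuristic and return per-node importances.

    ``d`` is the degree threshold: reduction stops once every surviving node
    has degree > d.  The input graph is not modified.
    """
    if d < 1:
        raise ValueError(f"degree threshold d must be >= 1, got {d}")

    nw: dict[str, float] = {v: 0.0 for v in net.nodes}
    adj: dict[str, dict[str, float]] = {v: {} for v in net.nodes}
    for a, b in net.edges:
        if a == b:
            continue
        adj[a][b] = 1.0
        adj[b][a] = 1.0

    importance: dict[str, float] = {}
    trace: list[tuple[str, int, float]] = []
    # lazy min-heap keyed (degree, node); stale entries skipped on pop
    heap: list[tuple[int, str]] = [(len(adj[v]), v) for v in adj]
    heapq.heapify(heap)
    alive = set(adj)

    while heap:
        deg, v = heapq.heappop(heap)
        if v not in alive or len(adj[v]) != deg:
            continue
        if deg > d:
            # smallest current degree exceeds the threshold: reduction is done
            break
        neighbors = sorted(adj[v])
        k = len(neighbors)
        if k == 1:
            u = neighbors[0]
            nw[u] += nw[v] + adj[v][u]
        elif k >= 2:
            denom = k * (k - 1) / 2
            for u, z in itertools.combinations(neighbors, 2):
                share = (nw[v] + adj[v][u] + adj[v][z]) / denom
                if z not in adj[u]:
                    adj[u][z] = 0.0
                    adj[z][u] = 0.0
                adj[u][z] += share
                adj[z][u] += share
        for u in neighbors:
            del adj[u][v]
            heapq.heappush(heap, (len(adj[u]), u))
        adj[v].clear()
        alive.discard(v)
        importance[v] = nw[v]  # frozen at removal time
        if record_trace:
            live = sum(nw[u] for u in alive) + sum(
                w for u in alive for z, w in adj[u].items() if u < z
            )
            trace.append((v, deg, live))

    edge_weight: dict[tuple[str, str], float] = {}
    for u in alive:
        for z, w in adj[u].items():
            if u < z:
                edge_weight[(u, z)] = w
    for u in alive:
        importance[u] = nw[u] + sum(adj[u].values())

    return TopoWeights(
        node_weight=nw,
        edge_weight=edge_weight,
        importance=importance,
        threshold_d=d,
        trace=trace,
    )


def topo_similarity(tw1: TopoWeights, tw2: TopoWeights) -> SimMatrix:
    """Cross-network topological similarity T(i, j) = min(S_i, S_j) / max(S_i, S_j).

    Entries lie in [0, 1]; a pair where the larger importance is 0 scores 0.
    Both inputs must come from reductions with the same threshold d.
    """
    if tw1.threshold_d != tw2.threshold_d:
        raise ValueError(
            f"threshold mismatch: d={tw1.threshold_d} vs d={tw2.threshold_d}"
        )
    entries: dict[tuple[str, str], float] = {}
    for i, si in tw1.importance.items():
        for j, sj in tw2.importance.items():
            hi = max(si, sj)
            entries[(i, j)] = (min(si, sj) / hi) if hi > 0 else 0.0
    return SimMatrix(role="topological", entries=entries, normalized=True)


def write_topo_weights(tw: TopoWeights, path) -> None:
    """Debug dump: node, final node weight, importance (TSV)."""
    with open(path, "w") as fh:
        fh.write("node\tnode_weight\timportance\n")
        for v in sorted(tw.importance):
            fh.write(f"{v}\t{tw.node_weight[v]:.10g}\t{tw.importance[v]:.10g}\n")
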