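"""Source-anchored path analytics on an estimated network.

These are the analytics that make a risk score interpretable inside a
symptom network: the *predictive path diagram* layers the network into
levels of connectivity outward from a designated source node (level 1 =
direct neighbors of the source, level k = nodes first reachable in k
hops); *shortest predictive pathways* are minimum-cost routes from the
source under the inverse-association distance 1/|w|; and *node-specific
predictive betweenness* counts how often a node lies on those shortest
pathways, one endpoint always being the source.

Levels use unweighted hop counts (the verbal recursive definition of the
diagram), while pathways use weighted distances; both views are reported.
Negative edges are traversable through their absolute weight but flagged,
and can be excluded entirely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError
from .ggm import NetworkModel

__all__ = ["PathDiagram", "TargetPaths", "BetweennessProfile", "edge_distance",
           "predictive_path_diagram", "shortest_predictive_paths",
           "node_predictive_betweenness"]

DISTANCE_TRANSFORM = "inverse_absolute_weight"


@dataclass(frozen=True)
class EdgeDistances:
    """Pairwise one-hop distances 1/|w| (inf where there is no edge) and the
    mask of edges carrying a negative weight."""

    distance: np.ndarray
    negative_edge: np.ndarray
    labels: tuple[str, ...]


@dataclass(frozen=True)
class PathDiagram:
    source: str
    levels: tuple[tuple[str, ...], ...]
    cross_level_edges: tuple[tuple[str, str], ...]
    within_level_edges: tuple[tuple[str, str], ...]
    unreachable: tuple[str, ...]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_of(self, node: str) -> int | None:
        """1-based level of a node; 0 for the source; None if unreachable."""
        if node == self.source:
            return 0
        for k, level in enumerate(self.levels, start=1):
            if node in level:
                return k
        return None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "source": self.source,
            "levels": [list(l) for l in self.levels],
            "cross_level_edges": [list(e) for e in self.cross_level_edges],
            "within_level_edges": [list(e) for e in self.within_level_edges],
            "unreachable": list(self.unreachable),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class TargetPaths:
    target: str
    distance: float
    paths: tuple[tuple[str, ...], ...]  # all tied shortest node sequences
    has_negative: bool  # any tied path traverses a negative edge


@dataclass(frozen=True)
class BetweennessProfile:
    """Per-node traversal counts over all shortest source->target pathways,
    fractionally weighted over tied paths (Brandes-style), or binary
    (1 per target whose shortest-path set touches the node)."""

    source: str
    counts: dict[str, float]
    targets_reached: int
    distance_transform: str = DISTANCE_TRANSFORM
    tie_rule: str = "fractional"

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, name="predictive_betweenness")


def edge_distance(weights: np.ndarray, labels=None) -> EdgeDistances:
    """Map association weights to traversal costs: distance = 1/|w|.

    Zero weights mean "no edge" (infinite distance).  Negative weights
    contribute via their absolute value and are flagged."""
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InputError("weights must be square")
    if not np.allclose(W, W.T, atol=1e-12) or np.any(np.diag(W) != 0):
        raise InputError("weights must be symmetric with a zero diagonal")
    with np.errstate(divide="ignore"):
        dist = np.where(W != 0, 1.0 / np.abs(W), np.inf)
    np.fill_diagonal(dist, np.inf)
    if labels is None:
        labels = tuple(f"V{i}" for i in range(W.shape[0]))
    return EdgeDistances(distance=dist, negative_edge=W < 0, labels=tuple(labels))


def _graph(model: NetworkModel, exclude_negative: bool) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(model.labels)
    ii, jj = np.where(np.triu(model.adjacency, 1))
    for i, j in zip(ii, jj):
        w = model.weights[i, j]
        if exclude_negative and w < 0:
            continue
        G.add_edge(model.labels[i], model.labels[j],
                   weight=w, distance=1.0 / abs(w), negative=bool(w < 0))
    return G


def predictive_path_diagram(model: NetworkModel, source: str,
                            max_levels: int | None = None,
                            exclude_negative: bool = False) -> PathDiagram:
    """Breadth-first layering of the network outward from the source.

    Level k holds the nodes whose unweighted hop distance from the source
    is exactly k; edges are split into cross-level (k -> k+1, including
    source -> level 1) and within-level sets.  BFS layering guarantees no
    edge skips a level.  Nodes beyond ``max_levels`` or disconnected from
    the source are listed as unreachable.
    """
    model.index(source)
    order = {lab: i for i, lab in enumerate(model.labels)}
    G = _graph(model, exclude_negative)
    hops = nx.single_source_shortest_path_length(G, source)

    max_hop = max(hops.values(), default=0)
    n_levels = max_hop if max_levels is None else min(max_hop, max_levels)
    levels = []
    for k in range(1, n_levels + 1):
        members = sorted((v for v, h in hops.items() if h == k), key=order.get)
        levels.append(tuple(members))
    placed = {source} | {v for level in levels for v in level}
    unreachable = tuple(sorted((v for v in model.labels if v not in placed),
                               key=order.get))

    cross, within = [], []
    for u, v in G.edges():
        if u not in placed or v not in placed:
            continue
        hu, hv = hops[u], hops[v]
        if hu == hv:
            a, b = sorted((u, v), key=order.get)
            within.append((a, b))
        else:
            a, b = (u, v) if hu < hv else (v, u)
            cross.append((a, b))
    key = lambda e: (order[e[0]], order[e[1]])
    return PathDiagram(source=source, levels=tuple(levels),
                       cross_level_edges=tuple(sorted(cross, key=key)),
                       within_level_edges=tuple(sorted(within, key=key)),
                       unreachable=unreachable)


def _dijkstra_dag(G: nx.Graph, source: str):
    """Predecessor DAG and distances of all shortest paths from source."""
    pred, dist = nx.dijkstra_predecessor_and_distance(G, source, weight="distance")
    return pred, dist


def _enumerate_paths(pred, node, order) -> list[tuple[str, ...]]:
    if not pred[node]:  # source
        return [(node,)]
    out = []
    for u in sorted(pred[node], key=order.get):
        out.extend(path + (node,) for path in _enumerate_paths(pred, u, order))
    return out


def shortest_predictive_paths(model: NetworkModel, source: str,
                              exclude_negative: bool = False
                              ) -> dict[str, TargetPaths]:
    """All tied shortest pathways from the source to every other node.

    Distances use the inverse-absolute-weight transform; for each
    reachable target the minimal total distance and *all* tied node
    sequences are returned.  Unreachable targets get infinite distance
    and an empty path set.
    """
    model.index(source)
    order = {lab: i for i, lab in enumerate(model.labels)}
    G = _graph(model, exclude_negative)
    pred, dist = _dijkstra_dag(G, source)

    out: dict[str, TargetPaths] = {}
    for target in model.labels:
        if target == source:
            continue
        if target not in dist:
            out[target] = TargetPaths(target, np.inf, (), False)
            continue
        paths = tuple(_enumerate_paths(pred, target, order))
        has_neg = any(
            G.edges[a, b]["negative"]
            for path in paths for a, b in zip(path, path[1:]))
        out[target] = TargetPaths(target, float(dist[target]), paths, has_neg)
    return out


def node_predictive_betweenness(model: NetworkModel, source: str,
                                tie_rule: str = "fractional",
                                exclude_negative: bool = False
                                ) -> BetweennessProfile:
    """How often each node lies on shortest pathways out of the source.

    ``fractional``: each of the m tied shortest paths to a target
    contributes 1/m to every intermediate node on it (endpoints excluded);
    this is the Brandes dependency of the source restricted to pairs
    (source, t), and degenerates to integer counts when paths are unique.
    ``binary``: a node receives 1 per target for which it lies on at least
    one tied shortest path.
    """
    if tie_rule not in ("fractional", "binary"):
        raise InputError(f"unknown tie_rule {tie_rule!r}")
    model.index(source)
    G = _graph(model, exclude_negative)
    pred, dist = _dijkstra_dag(G, source)
    counts = {lab: 0.0 for lab in model.labels}
    reached = [v for v in dist if v != source]

    if tie_rule == "fractional":
        # Brandes accumulation over the shortest-path DAG
        sigma = {source: 1.0}
        for v in sorted(dist, key=dist.get):
            if v == source:
                continue
            sigma[v] = sum(sigma[u] for u in pred[v])
        delta = {v: 0.0 for v in dist}
        for v in sorted(dist, key=dist.get, reverse=True):
            for u in pred[v]:
                delta[u] += sigma[u] / sigma[v] * (1.0 + delta[v])
        for v in reached:
            counts[v] = delta[v]
    else:
        # membership of v in some shortest path to t == v is an ancestor of
        # t in the predecessor DAG
        for t in reached:
            stack, seen = [t], set()
            while stack:
                v = stack.pop()
                for u in pred[v]:
                    if u not in seen:
                        seen.add(u)
                        stack.append(u)
            seen.discard(source)
            seen.discard(t)
            for v in seen:
                counts[v] += 1.0

    counts[source] = 0.0
    return BetweennessProfile(source=source, counts=counts,
                              targets_reached=len(reached), tie_rule=tie_rule)
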