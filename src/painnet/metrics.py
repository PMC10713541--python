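"""Topology measures for the directed weighted pain network.

Everything here is implemented from first principles on the
:class:`~painnet.graph.PainGraph` container — breadth-first shortest paths,
Brandes betweenness accumulation, local clustering on the undirected
skeleton, degree assortativity as a Pearson correlation over edge
endpoints, the Lorenz concentration curve of the degree sequence.  The
intent is that a generic graph library can serve as an *independent* oracle
in the test suite rather than as the computation itself.

Conventions (all declared, since a directed graph makes several of these
ambiguous):

* shortest paths are unweighted hop counts unless a weighted variant is
  requested explicitly;
* unreachable ordered pairs are excluded from diameter and mean distance
  and their count is reported;
* closeness uses out-distances: ``1 / sum(d(v, u))`` over targets ``u``
  reachable from ``v``;
* clustering and assortativity are computed on the undirected skeleton of
  the digraph;
* top-k rankings break ties lexicographically by acronym.
"""

from __future__ import annotations

import heapq
import json
import math
from collections import deque
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .graph import PainGraph
from .io import ProjectionTable

__all__ = [
    "build_graph",
    "density",
    "diameter",
    "reciprocity",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "clustering_coefficients",
    "transitivity",
    "assortativity_degree",
    "degree_distribution",
    "lorenz_curve",
    "mean_distance",
    "top_k",
    "MeanDistance",
    "MetricsReport",
    "compute_metrics",
]


# ---------------------------------------------------------------------------
# graph construction

def build_graph(
    table: ProjectionTable,
    edge_threshold: float = 0.01,
    hemisphere_rule: Literal["sum", "ipsi"] = "sum",
) -> PainGraph:
    """Threshold an aggregated projection table into a simple digraph.

    Every catalog area becomes a node (isolated areas included, so the node
    count matches the catalog).  An edge u→v exists iff the combined
    projection strength of the ordered pair reaches ``edge_threshold``
    (default 0.01, the level below which projections are considered
    spurious); its weight is that combined strength.  ``hemisphere_rule``
    chooses the combination: ``"sum"`` adds ipsilateral and contralateral
    volumes (the inclusive default), ``"ipsi"`` uses ipsilateral only.
    Self-projections are dropped.
    """
    if not table.is_aggregated:
        raise ValueError("aggregate the table before building a graph")
    if hemisphere_rule not in ("sum", "ipsi"):
        raise ValueError(f"unknown hemisphere_rule {hemisphere_rule!r}")
    rec = table.records
    if hemisphere_rule == "ipsi":
        rec = rec[rec["hemisphere"] == "ipsi"]
    combined = rec.groupby(["source", "target"], sort=True)["volume"].sum()

    g = PainGraph()
    coords = table.catalog.coords()
    for row in table.catalog.frame.itertuples():
        x, y, z = coords[row.acronym]
        g.add_node(row.acronym, group=row.group, x=x, y=y, z=z)
    for (u, v), w in combined.items():
        if u != v and w >= edge_threshold:
            g.add_edge(u, v, w)
    return g


# ---------------------------------------------------------------------------
# shortest-path kernels (index-based for speed)

def _bfs_lengths(succ: list[list[int]], source: int) -> dict[int, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in succ[u]:
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


def _dijkstra_lengths(
    succ_w: list[list[tuple[int, float]]], source: int
) -> dict[int, float]:
    dist: dict[int, float] = {}
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in dist:
            continue
        dist[u] = d
        for v, w in succ_w[u]:
            if v not in dist:
                heapq.heappush(heap, (d + w, v))
    return dist


def _all_pairs_stats(g: PainGraph, weighted: bool = False):
    """Yield per-source distance dicts over the whole graph."""
    index, succ, _ = g.int_adjacency()
    if weighted:
        nodes = g.nodes
        succ_w = [
            [(index[v], w) for v, w in g.successors(n).items()] for n in nodes
        ]
        for s in range(len(nodes)):
            yield s, _dijkstra_lengths(succ_w, s)
    else:
        for s in range(len(succ)):
            yield s, _bfs_lengths(succ, s)


# ---------------------------------------------------------------------------
# scalar measures

def density(g: PainGraph) -> float:
    """Edge count over the number of possible directed edges |V|(|V|-1)."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("density undefined for graphs with fewer than 2 nodes")
    return g.n_edges / (n * (n - 1))


def diameter(g: PainGraph, weighted: bool = False) -> float:
    """Longest shortest path over reachable ordered pairs (hops by default)."""
    if g.n_nodes == 0:
        raise ValueError("diameter undefined for an empty graph")
    best = 0.0
    for s, dist in _all_pairs_stats(g, weighted=weighted):
        for t, d in dist.items():
            if t != s and d > best:
                best = d
    return best if weighted else int(best)


def reciprocity(g: PainGraph) -> float:
    """Fraction of directed edges whose reverse edge also exists."""
    m = g.n_edges
    if m == 0:
        raise ValueError("reciprocity undefined for an edgeless graph")
    mutual = sum(1 for u, v, _ in g.edges() if g.has_edge(v, u))
    return mutual / m


def degree_centrality(g: PainGraph) -> pd.DataFrame:
    """Per-node in-, out- and total degree (total = in + out)."""
    rows = {
        n: (g.in_degree(n), g.out_degree(n), g.total_degree(n)) for n in g.nodes
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["in_degree", "out_degree", "total_degree"]
    )


def closeness_centrality(
    g: PainGraph, mode: Literal["out", "in"] = "out"
) -> dict[str, float]:
    """1 / (sum of shortest-path distances to reachable nodes).

    Nodes that reach no other node get NaN (flagged undefined).  ``mode``
    "in" scores distances *to* the node instead.
    """
    nodes = g.nodes
    index, succ, pred = g.int_adjacency()
    adj = succ if mode == "out" else pred
    scores: dict[str, float] = {}
    for i, n in enumerate(nodes):
        dist = _bfs_lengths(adj, i)
        total = sum(d for t, d in dist.items() if t != i)
        scores[n] = 1.0 / total if total > 0 else math.nan
    return scores


def betweenness_centrality(g: PainGraph) -> dict[str, float]:
    """Brandes accumulation of shortest-path dependencies (directed, hops).

    Returns raw (unnormalized) counts: g(v) = sum over ordered pairs
    (s, t), s != v != t, of the fraction of s→t geodesics through v.
    """
    nodes = g.nodes
    index, succ, _ = g.int_adjacency()
    n = len(nodes)
    bc = np.zeros(n)
    for s in range(n):
        # single-source shortest-path DAG
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        parents: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        queue = deque([s])
        while queue:
            u = queue.popleft()
            order.append(u)
            for v in succ[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    parents[v].append(u)
        delta = np.zeros(n)
        for v in reversed(order):
            for u in parents[v]:
                delta[u] += sigma[u] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    return {n_: float(bc[i]) for i, n_ in enumerate(nodes)}


def clustering_coefficients(g: PainGraph) -> tuple[dict[str, float], float]:
    """Local clustering on the undirected skeleton, plus the mean.

    Local value = realized links among a node's neighbors over the maximum
    possible k(k-1)/2; nodes with skeleton degree < 2 score 0 and are
    excluded from the mean.
    """
    nbrs = g.undirected_neighbors()
    local: dict[str, float] = {}
    eligible: list[float] = []
    for n, nb in nbrs.items():
        k = len(nb)
        if k < 2:
            local[n] = 0.0
            continue
        links = 0
        nb_list = list(nb)
        for i, u in enumerate(nb_list):
            nu = nbrs[u]
            for v in nb_list[i + 1 :]:
                if v in nu:
                    links += 1
        c = 2.0 * links / (k * (k - 1))
        local[n] = c
        eligible.append(c)
    mean = float(np.mean(eligible)) if eligible else math.nan
    return local, mean


def transitivity(g: PainGraph) -> float:
    """Global transitivity of the skeleton: 3 x triangles / open triads."""
    nbrs = g.undirected_neighbors()
    closed = 0
    triads = 0
    for n, nb in nbrs.items():
        k = len(nb)
        if k < 2:
            continue
        triads += k * (k - 1) // 2
        nb_list = list(nb)
        for i, u in enumerate(nb_list):
            nu = nbrs[u]
            closed += sum(1 for v in nb_list[i + 1 :] if v in nu)
    return closed / triads if triads else math.nan


def assortativity_degree(g: PainGraph) -> float:
    """Pearson correlation of skeleton degrees across edge endpoints.

    Each undirected edge contributes both endpoint orderings.  Raises for
    regular graphs (zero degree variance across endpoints).
    """
    nbrs = g.undirected_neighbors()
    deg = {n: len(nb) for n, nb in nbrs.items()}
    xs: list[int] = []
    ys: list[int] = []
    for u, v in g.undirected_weights():
        xs.extend((deg[u], deg[v]))
        ys.extend((deg[v], deg[u]))
    if not xs:
        raise ValueError("assortativity undefined for an edgeless graph")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("assortativity undefined: graph is degree-regular")
    return float(np.corrcoef(x, y)[0, 1])


def degree_distribution(g: PainGraph) -> dict[int, int]:
    """Histogram of total degree; values sum to |V|."""
    hist: dict[int, int] = {}
    for n in g.nodes:
        d = g.total_degree(n)
        hist[d] = hist.get(d, 0) + 1
    return dict(sorted(hist.items()))


def lorenz_curve(degrees: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Lorenz concentration curve of a degree sequence.

    Returns (cumulative node share, cumulative degree share) from (0,0) to
    (1,1), computed on the ascending-sorted sequence.  A regular sequence
    gives the diagonal; concentration of edges on few hubs bows the curve
    below it.
    """
    d = np.sort(np.asarray(degrees, dtype=float))
    if d.size == 0 or d.sum() == 0:
        raise ValueError("Lorenz curve undefined for empty or all-zero degrees")
    x = np.concatenate(([0.0], np.arange(1, d.size + 1) / d.size))
    y = np.concatenate(([0.0], np.cumsum(d) / d.sum()))
    return x, y


class MeanDistance(NamedTuple):
    value: float
    unreachable_pairs: int


def mean_distance(g: PainGraph) -> MeanDistance:
    """Average unweighted shortest-path length over reachable ordered pairs.

    Unreachable ordered pairs are excluded and counted in the second field.
    """
    n = g.n_nodes
    total = 0
    reachable = 0
    for s, dist in _all_pairs_stats(g):
        reached = len(dist) - 1
        reachable += reached
        total += sum(dist.values())
    if reachable == 0:
        raise ValueError("mean distance undefined: no reachable ordered pairs")
    return MeanDistance(total / reachable, n * (n - 1) - reachable)


def top_k(scores: dict[str, float], k: int = 3) -> list[str]:
    """Highest-scoring nodes, NaN excluded, ties broken by acronym."""
    items = [(n, s) for n, s in scores.items() if not math.isnan(s)]
    items.sort(key=lambda t: (-t[1], t[0]))
    return [n for n, _ in items[:k]]


# ---------------------------------------------------------------------------
# report

@dataclass
class MetricsReport:
    """Bundle of all whole-graph and per-node topology measures."""

    n_nodes: int
    n_edges: int
    density: float
    diameter: int
    reciprocity: float
    mean_clustering: float
    assortativity: float
    mean_distance: float
    unreachable_pairs: int
    per_node: pd.DataFrame  # in/out/total degree, closeness, betweenness, clustering
    degree_histogram: dict[int, int]
    lorenz: tuple[np.ndarray, np.ndarray]

    def top3(self) -> dict[str, list[str]]:
        pn = self.per_node
        return {
            "degree": top_k(pn["total_degree"].to_dict()),
            "closeness": top_k(pn["closeness"].to_dict()),
            "betweenness": top_k(pn["betweenness"].to_dict()),
        }

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "diameter": self.diameter,
            "reciprocity": self.reciprocity,
            "mean_clustering": self.mean_clustering,
            "assortativity": self.assortativity,
            "mean_distance": self.mean_distance,
            "unreachable_pairs": self.unreachable_pairs,
            "degree_histogram": {str(k): v for k, v in self.degree_histogram.items()},
            "lorenz_node_share": self.lorenz[0].tolist(),
            "lorenz_degree_share": self.lorenz[1].tolist(),
            "top3": self.top3(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def per_node_tsv(self, path) -> None:
        self.per_node.to_csv(path, sep="\t", index_label="acronym", float_format="%.10g")


def compute_metrics(g: PainGraph) -> MetricsReport:
    """Compute the full topology report for one graph."""
    deg = degree_centrality(g)
    close = closeness_centrality(g)
    btw = betweenness_centrality(g)
    local, mean_c = clustering_coefficients(g)
    try:
        assort = assortativity_degree(g)
    except ValueError:
        assort = math.nan
    md = mean_distance(g)
    per_node = deg.assign(
        closeness=pd.Series(close),
        betweenness=pd.Series(btw),
        clustering=pd.Series(local),
    )
    return MetricsReport(
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        density=density(g),
        diameter=diameter(g),
        reciprocity=reciprocity(g),
        mean_clustering=mean_c,
        assortativity=assort,
        mean_distance=md.value,
        unreachable_pairs=md.unreachable_pairs,
        per_node=per_node,
        degree_histogram=degree_distribution(g),
        lorenz=lorenz_curve(deg["total_degree"].to_numpy()),
    )
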