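"""Random-walk (Walktrap) community detection with modularity cut selection.

The Pons–Latapy idea: a short random walk started in a dense community
tends to stay inside it, so two vertices in the same community see similar
walk distributions.  Vertices are compared by the distance

    r_ij = sqrt( sum_k (P^t_ik - P^t_jk)^2 / d_k )

where ``P`` is the row-normalized weighted transition matrix of the
undirected skeleton, ``t`` the walk length and ``d_k`` the weighted degree
of vertex ``k``.  Communities are merged agglomeratively, always the
adjacent pair whose merge minimizes the Ward-style increase in
within-community squared distance; the cut returned is the dendrogram
level with maximal weighted modularity Q.

The whole procedure is deterministic: there is no randomness beyond the
(analytically propagated) random walk, and merge ties are broken by the
smallest community-id pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .graph import PainGraph

__all__ = ["CommunityPartition", "walktrap", "modularity"]


@dataclass
class CommunityPartition:
    """Node→community assignment plus the merge history that produced it."""

    assignment: dict[str, int]
    merge_sequence: list[tuple[int, int, int]]  # (community a, community b, new id)
    modularity_trace: list[float]  # Q after 0, 1, ... merges
    chosen_level: int  # index into the trace with maximal Q
    modularity: float  # Q of the returned assignment

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> list[list[str]]:
        """Members per community, largest first, ties by first acronym."""
        groups: dict[int, list[str]] = {}
        for node, cid in self.assignment.items():
            groups.setdefault(cid, []).append(node)
        return sorted(groups.values(), key=lambda ms: (-len(ms), ms[0]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "assignment": self.assignment,
                    "n_communities": self.n_communities,
                    "modularity": self.modularity,
                    "chosen_level": self.chosen_level,
                    "modularity_trace": self.modularity_trace,
                    "merge_sequence": self.merge_sequence,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def _skeleton(
    g: PainGraph, weighted: bool, log_weights: bool
) -> tuple[list[str], np.ndarray]:
    """Symmetric weighted adjacency of the undirected skeleton."""
    nodes = g.nodes
    index = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for (u, v), w in g.undirected_weights().items():
        val = w if weighted else 1.0
        if weighted and log_weights:
            # affine log rescale keeping weights positive over >1e5-fold ranges
            val = np.log10(w) + 8.0
            if val <= 0:
                val = 1e-6
        A[index[u], index[v]] = val
        A[index[v], index[u]] = val
    return nodes, A


def modularity(g: PainGraph, assignment: dict[str, int]) -> float:
    """Weighted Newman modularity on the undirected skeleton.

    Q = sum_c [ w_c / W - (s_c / 2W)^2 ] with W the total skeleton weight,
    w_c the within-community weight and s_c the summed strength of the
    community's members.  Q = 0 for the single-community partition.
    """
    missing = [n for n in g.nodes if n not in assignment]
    if missing:
        raise ValueError(f"assignment does not cover nodes: {missing[:5]}")
    W = 0.0
    within: dict[int, float] = {}
    strength: dict[int, float] = {}
    for (u, v), w in g.undirected_weights().items():
        W += w
        cu, cv = assignment[u], assignment[v]
        strength[cu] = strength.get(cu, 0.0) + w
        strength[cv] = strength.get(cv, 0.0) + w
        if cu == cv:
            within[cu] = within.get(cu, 0.0) + w
    if W == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    q = 0.0
    for c, s in strength.items():
        q += within.get(c, 0.0) / W - (s / (2.0 * W)) ** 2
    return q


def walktrap(
    g: PainGraph,
    steps: int = 4,
    weighted: bool = True,
    log_weights: bool = False,
) -> CommunityPartition:
    """Detect densely connected subgraphs by short random walks.

    Disconnected components are handled independently (merging is
    restricted to adjacent communities, so components can never merge);
    isolated nodes remain singleton communities.
    """
    if steps < 1:
        raise ValueError("walk length must be >= 1")
    if g.n_edges == 0:
        raise ValueError("walktrap needs at least one edge")
    nodes, A = _skeleton(g, weighted, log_weights)
    n = len(nodes)
    d = A.sum(axis=1)  # weighted degree
    active = d > 0  # isolated nodes sit out of the walk

    P = np.zeros_like(A)
    P[active] = A[active] / d[active, None]
    Pt = np.linalg.matrix_power(P, steps)
    inv_d = np.zeros(n)
    inv_d[active] = 1.0 / d[active]

    # community state; ids 0..n-1 are the singletons, merged ids continue up
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    vec: dict[int, np.ndarray] = {i: Pt[i] for i in range(n)}
    neighbors: dict[int, set[int]] = {i: set() for i in range(n)}
    for i in range(n):
        for j in np.flatnonzero(A[i]):
            if j != i:
                neighbors[i].add(int(j))

    assign = {nodes[i]: i for i in range(n)}
    trace = [modularity(g, assign)]
    merges: list[tuple[int, int, int]] = []
    partitions = [dict(assign)]
    next_id = n

    def delta_sigma(a: int, b: int) -> float:
        na, nb = len(members[a]), len(members[b])
        diff = vec[a] - vec[b]
        return (na * nb / (na + nb)) * float(np.sum(diff * diff * inv_d)) / n

    while True:
        # candidate merges: adjacent community pairs
        best = None
        best_key = None
        for a in sorted(members):
            for b in sorted(neighbors[a]):
                if b <= a:
                    continue
                key = (delta_sigma(a, b), a, b)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (a, b)
        if best is None:
            break
        a, b = best
        new = next_id
        next_id += 1
        na, nb = len(members[a]), len(members[b])
        vec[new] = (na * vec[a] + nb * vec[b]) / (na + nb)
        members[new] = members.pop(a) + members.pop(b)
        del vec[a], vec[b]
        nbrs = (neighbors.pop(a) | neighbors.pop(b)) - {a, b}
        neighbors[new] = nbrs
        for c in nbrs:
            neighbors[c].discard(a)
            neighbors[c].discard(b)
            neighbors[c].add(new)
        merges.append((a, b, new))
        assign = {}
        for cid, mem in members.items():
            for i in mem:
                assign[nodes[i]] = cid
        partitions.append(dict(assign))
        trace.append(modularity(g, assign))

    chosen = int(np.argmax(trace))
    chosen_assign = partitions[chosen]
    # relabel communities 0..k-1 in order of first appearance
    relabel: dict[int, int] = {}
    final: dict[str, int] = {}
    for node in nodes:
        cid = chosen_assign[node]
        if cid not in relabel:
            relabel[cid] = len(relabel)
        final[node] = relabel[cid]
    return CommunityPartition(
        assignment=final,
        merge_sequence=merges,
        modularity_trace=trace,
        chosen_level=chosen,
        modularity=trace[chosen],
    )
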