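"""Error- and attack-tolerance simulation.

Following the Albert–Jeong–Barabási protocol: remove a fraction ``f`` of
nodes either uniformly at random (error / random failure) or by repeatedly
deleting the node with the currently highest total degree (attack), then
track three observables of the remaining graph:

* mean distance — average unweighted shortest-path length over reachable
  ordered pairs (a ``--metric diameter`` variant is available);
* ``S`` — size of the largest weakly connected cluster as a fraction of
  the *original* node count;
* ``<s>`` — mean size of all clusters except the largest (0 when the
  remainder is a single cluster).

Each (fraction, mode) cell is averaged over ``n_reps`` independent
replicates (default 100); attack replicates differ only through random
tie-breaking among equal-degree nodes.  Everything is deterministic given
the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .graph import PainGraph
from .metrics import mean_distance
from .nullmodels import barabasi_albert

__all__ = [
    "remove_fraction",
    "robustness_curve",
    "compare_to_scalefree",
    "RobustnessCurve",
]

Mode = Literal["random", "attack"]


def _select_removal(
    succ: list[list[int]], pred: list[list[int]], k: int, mode: Mode,
    rng: np.random.Generator, recompute: bool = True,
) -> list[int]:
    """Indices of the k nodes to delete, by the requested policy."""
    n = len(succ)
    if mode == "random":
        return list(rng.choice(n, size=k, replace=False)) if k else []
    # attack: peel off the current top-degree node, ties broken at random
    alive = np.ones(n, dtype=bool)
    deg = np.array([len(succ[i]) + len(pred[i]) for i in range(n)], dtype=float)
    removed: list[int] = []
    for _ in range(k):
        cand = np.flatnonzero(alive & (deg == deg[alive].max()))
        pick = int(cand[rng.integers(len(cand))])
        alive[pick] = False
        deg[pick] = -1.0
        removed.append(pick)
        if recompute:
            for j in succ[pick]:
                if alive[j]:
                    deg[j] -= 1
            for j in pred[pick]:
                if alive[j]:
                    deg[j] -= 1
    return removed


def remove_fraction(
    g: PainGraph, f: float, mode: Mode, rng=None, recompute_degrees: bool = True
) -> PainGraph:
    """Remove round(f*n) nodes and return the induced remainder."""
    if not 0.0 <= f < 1.0:
        raise ValueError(f"removal fraction must lie in [0, 1), got {f}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    nodes = g.nodes
    _, succ, pred = g.int_adjacency()
    k = round(f * len(nodes))
    removed = set(_select_removal(succ, pred, k, mode, rng, recompute_degrees))
    return g.subgraph(n for i, n in enumerate(nodes) if i not in removed)


def _component_stats(succ, pred, alive: np.ndarray) -> tuple[int, list[int]]:
    """Largest weak-component size and sizes of the other components."""
    n = len(succ)
    seen = ~alive.copy()
    sizes: list[int] = []
    for s in range(n):
        if seen[s]:
            continue
        stack = [s]
        seen[s] = True
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for v in succ[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
            for v in pred[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        sizes.append(size)
    sizes.sort(reverse=True)
    return (sizes[0], sizes[1:]) if sizes else (0, [])


def _mean_distance_masked(succ, alive: np.ndarray) -> float:
    """Mean hop distance over reachable ordered alive pairs (NaN if none)."""
    total = 0
    count = 0
    alive_idx = np.flatnonzero(alive)
    for s in alive_idx:
        dist = {int(s): 0}
        queue = [int(s)]
        while queue:
            nxt: list[int] = []
            for u in queue:
                du = dist[u]
                for v in succ[u]:
                    if alive[v] and v not in dist:
                        dist[v] = du + 1
                        nxt.append(v)
            queue = nxt
        total += sum(dist.values())
        count += len(dist) - 1
    return total / count if count else float("nan")


def _diameter_masked(succ, alive: np.ndarray) -> float:
    best = 0
    for s in np.flatnonzero(alive):
        dist = {int(s): 0}
        queue = [int(s)]
        while queue:
            nxt: list[int] = []
            for u in queue:
                du = dist[u]
                for v in succ[u]:
                    if alive[v] and v not in dist:
                        dist[v] = du + 1
                        nxt.append(v)
            queue = nxt
        if dist:
            best = max(best, max(dist.values()))
    return float(best)


@dataclass
class RobustnessCurve:
    """Replicate-averaged response to node removal, one row per fraction."""

    mode: Mode
    fractions: list[float]
    mean_distance: list[float]  # replicate mean of the distance metric
    S: list[float]  # largest cluster / original n
    s_mean: list[float]  # mean size of non-largest clusters
    n_reps: int
    seed: int
    metric: str = "mean_distance"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "f": self.fractions,
                "mean_distance": self.mean_distance,
                "S": self.S,
                "s_mean": self.s_mean,
                "mode": self.mode,
            }
        )


def robustness_curve(
    g: PainGraph,
    fractions: Sequence[float],
    mode: Mode,
    n_reps: int = 100,
    seed: int = 0,
    metric: Literal["mean_distance", "diameter"] = "mean_distance",
    recompute_degrees: bool = True,
) -> RobustnessCurve:
    """Simulate removal at each fraction, averaging over ``n_reps`` replicates."""
    if mode not in ("random", "attack"):
        raise ValueError(f"unknown mode {mode!r}")
    mean_distance(g)  # raises if no reachable pair at f = 0
    nodes = g.nodes
    n = len(nodes)
    _, succ, pred = g.int_adjacency()
    dist_fn = _mean_distance_masked if metric == "mean_distance" else _diameter_masked

    rng = np.random.default_rng(seed)
    out_d: list[float] = []
    out_S: list[float] = []
    out_s: list[float] = []
    for f in fractions:
        if not 0.0 <= f < 1.0:
            raise ValueError(f"removal fraction must lie in [0, 1), got {f}")
        k = round(f * n)
        d_acc: list[float] = []
        S_acc: list[float] = []
        s_acc: list[float] = []
        for _ in range(n_reps):
            removed = _select_removal(succ, pred, k, mode, rng, recompute_degrees)
            alive = np.ones(n, dtype=bool)
            alive[removed] = False
            largest, rest = _component_stats(succ, pred, alive)
            S_acc.append(largest / n)
            s_acc.append(float(np.mean(rest)) if rest else 0.0)
            d_acc.append(dist_fn(succ, alive))
        finite = [x for x in d_acc if not math.isnan(x)]
        out_d.append(float(np.mean(finite)) if finite else float("nan"))
        out_S.append(float(np.mean(S_acc)))
        out_s.append(float(np.mean(s_acc)))
    return RobustnessCurve(
        mode=mode,
        fractions=list(map(float, fractions)),
        mean_distance=out_d,
        S=out_S,
        s_mean=out_s,
        n_reps=n_reps,
        seed=seed,
        metric=metric,
    )


def compare_to_scalefree(
    g: PainGraph,
    fractions: Sequence[float],
    seed: int = 0,
    n_reps: int = 100,
    ba_power: float = 0.5,
) -> dict[str, dict[Mode, RobustnessCurve]]:
    """Robustness of ``g`` and of a density-matched scale-free graph.

    Returns ``{"graph": {mode: curve}, "scale_free": {mode: curve}}`` for
    both removal modes, all driven by sub-seeds of ``seed``.
    """
    n, m = g.n_nodes, g.n_edges
    ba = barabasi_albert(n, power=ba_power, m_per_step=max(1, round(m / n)), seed=seed)
    out: dict[str, dict[Mode, RobustnessCurve]] = {"graph": {}, "scale_free": {}}
    for off, (label, target) in enumerate((("graph", g), ("scale_free", ba))):
        for j, mode in enumerate(("random", "attack")):
            out[label][mode] = robustness_curve(
                target, fractions, mode, n_reps=n_reps, seed=seed + 1000 * off + 100 * j
            )
    return out
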