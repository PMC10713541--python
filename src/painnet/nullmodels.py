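"""Matched random-network comparison models.

Three classical generators, parameterized to match an observed network's
node count and edge density:

* Erdős–Rényi ``G(n, m)``: exactly ``m`` distinct directed edges chosen
  uniformly — matches density exactly and makes comparisons less noisy
  than the binomial ``G(n, p)`` variant.
* Watts–Strogatz small world: an undirected ring lattice with ``nei``
  neighbors per side, each lattice edge rewired with probability ``p``
  (default 0.05); the result is converted to mutual directed pairs, so its
  reciprocity is exactly 1 by construction.
* Barabási–Albert scale free: growth with preferential attachment
  probability ∝ degree^power + 1 (the +1 keeps zero-degree nodes
  reachable); every edge points from the newborn node to an older one, so
  reciprocity is exactly 0 and the graph is acyclic.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

from .graph import PainGraph

__all__ = [
    "erdos_renyi",
    "watts_strogatz",
    "barabasi_albert",
    "matched_null_models",
    "node_name",
]


def node_name(i: int) -> str:
    return f"N{i:03d}"


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def erdos_renyi(n: int, m: int, seed=None) -> PainGraph:
    """Uniform random digraph with exactly ``m`` edges, no self-loops."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not 0 <= m <= n * (n - 1):
        raise ValueError(f"m={m} infeasible for n={n} (max {n * (n - 1)})")
    rng = _as_rng(seed)
    picks = rng.choice(n * (n - 1), size=m, replace=False)
    g = PainGraph()
    for i in range(n):
        g.add_node(node_name(i))
    for p in picks:
        u, r = divmod(int(p), n - 1)
        v = r if r < u else r + 1  # skip the diagonal
        g.add_edge(node_name(u), node_name(v))
    return g


def watts_strogatz(n: int, nei: int, p: float = 0.05, seed=None) -> PainGraph:
    """Rewired ring lattice, returned as a mutual-directed graph."""
    if not 1 <= nei < n / 2:
        raise ValueError(f"nei={nei} must satisfy 1 <= nei < n/2 for n={n}")
    if not 0 <= p <= 1:
        raise ValueError("rewiring probability must lie in [0, 1]")
    rng = _as_rng(seed)
    edges: set[frozenset[int]] = {
        frozenset((i, (i + k) % n)) for i in range(n) for k in range(1, nei + 1)
    }
    # rewire lattice edges in a fixed scan order for determinism
    for i in range(n):
        for k in range(1, nei + 1):
            j = (i + k) % n
            e = frozenset((i, j))
            if e not in edges:
                continue  # already rewired away
            if rng.random() < p:
                # keep endpoint i, draw a fresh partner
                candidates = [
                    t for t in range(n) if t != i and frozenset((i, t)) not in edges
                ]
                if not candidates:
                    continue
                new = candidates[int(rng.integers(len(candidates)))]
                edges.remove(e)
                edges.add(frozenset((i, new)))
    g = PainGraph()
    for i in range(n):
        g.add_node(node_name(i))
    for e in sorted(tuple(sorted(x)) for x in edges):
        u, v = e
        g.add_edge(node_name(u), node_name(v))
        g.add_edge(node_name(v), node_name(u))
    return g


def barabasi_albert(n: int, power: float = 0.5, m_per_step: int = 1, seed=None) -> PainGraph:
    """Preferential-attachment growth; edges point newborn → older node."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not 1 <= m_per_step < n:
        raise ValueError(f"m_per_step={m_per_step} must satisfy 1 <= m < n")
    rng = _as_rng(seed)
    g = PainGraph()
    g.add_node(node_name(0))
    degree = np.zeros(n)
    for t in range(1, n):
        g.add_node(node_name(t))
        weights = degree[:t] ** power + 1.0
        probs = weights / weights.sum()
        draws = rng.choice(t, size=m_per_step, replace=True, p=probs)
        for target in sorted(set(int(x) for x in draws)):
            g.add_edge(node_name(t), node_name(target))
            degree[t] += 1
            degree[target] += 1
    return g


def matched_null_models(
    n: int, m: int, seed=None, ws_p: float = 0.05, ba_power: float = 0.5
) -> dict[str, PainGraph]:
    """One instance of each model matched to (n, m) as closely as each allows.

    WS uses nei = round(m / (2n)) so the undirected lattice density matches
    the skeleton of an m-edge digraph; BA uses m_per_step = round(m / n).
    """
    rng = _as_rng(seed)
    nei = max(1, round(m / (2 * n)))
    m_step = max(1, round(m / n))
    return {
        "erdos_renyi": erdos_renyi(n, m, rng),
        "watts_strogatz": watts_strogatz(n, nei, ws_p, rng),
        "barabasi_albert": barabasi_albert(n, ba_power, m_step, rng),
    }
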