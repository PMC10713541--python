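"""Minimal directed weighted graph container for brain connectivity networks.

The analysis layer (:mod:`painnet.metrics`, :mod:`painnet.community`,
:mod:`painnet.robustness`) implements every graph algorithm from scratch on
top of this container; third-party graph libraries are used only as test
oracles.  The container is deliberately small: a simple digraph (no self
loops, no parallel edges) with strictly positive edge weights and optional
per-node attributes (anatomical group, injection coordinate).
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from typing import Iterable, Iterator

__all__ = ["PainGraph"]

_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


class PainGraph:
    """Simple directed graph with positive edge weights.

    Nodes are identified by string acronyms and kept in insertion order so
    that every computation over the graph is deterministic.
    """

    def __init__(self) -> None:
        self._succ: dict[str, dict[str, float]] = {}
        self._pred: dict[str, dict[str, float]] = {}
        self.node_attrs: dict[str, dict] = {}

    # -- construction -----------------------------------------------------

    def add_node(self, node: str, **attrs) -> None:
        if node not in self._succ:
            self._succ[node] = {}
            self._pred[node] = {}
            self.node_attrs[node] = {}
        if attrs:
            self.node_attrs[node].update(attrs)

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        if u == v:
            raise ValueError(f"self-loop rejected: {u!r}")
        if not weight > 0:
            raise ValueError(f"edge weight must be positive, got {weight!r}")
        self.add_node(u)
        self.add_node(v)
        self._succ[u][v] = float(weight)
        self._pred[v][u] = float(weight)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], nodes: Iterable[str] = ()
    ) -> "PainGraph":
        g = cls()
        for n in nodes:
            g.add_node(n)
        for u, v, w in edges:
            g.add_edge(u, v, w)
        return g

    def copy(self) -> "PainGraph":
        g = PainGraph()
        for n in self.nodes:
            g.add_node(n, **self.node_attrs[n])
        for u, v, w in self.edges():
            g.add_edge(u, v, w)
        return g

    def subgraph(self, keep: Iterable[str]) -> "PainGraph":
        """Induced subgraph on ``keep`` (order follows the parent graph)."""
        keep = set(keep)
        g = PainGraph()
        for n in self.nodes:
            if n in keep:
                g.add_node(n, **self.node_attrs[n])
        for u, v, w in self.edges():
            if u in keep and v in keep:
                g.add_edge(u, v, w)
        return g

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self._succ)

    @property
    def n_nodes(self) -> int:
        return len(self._succ)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self._succ.values())

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, nbrs in self._succ.items():
            for v, w in nbrs.items():
                yield u, v, w

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._succ and v in self._succ[u]

    def weight(self, u: str, v: str) -> float:
        return self._succ[u][v]

    def successors(self, u: str) -> dict[str, float]:
        return self._succ[u]

    def predecessors(self, v: str) -> dict[str, float]:
        return self._pred[v]

    def out_degree(self, u: str) -> int:
        return len(self._succ[u])

    def in_degree(self, u: str) -> int:
        return len(self._pred[u])

    def total_degree(self, u: str) -> int:
        return len(self._succ[u]) + len(self._pred[u])

    # -- undirected views -------------------------------------------------

    def undirected_neighbors(self) -> dict[str, set[str]]:
        """Neighbor sets of the undirected skeleton (direction ignored)."""
        nbrs: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v, _ in self.edges():
            nbrs[u].add(v)
            nbrs[v].add(u)
        return nbrs

    def undirected_weights(self) -> dict[tuple[str, str], float]:
        """Undirected skeleton weights; antiparallel weights are summed."""
        out: dict[tuple[str, str], float] = {}
        for u, v, w in self.edges():
            key = (u, v) if u < v else (v, u)
            out[key] = out.get(key, 0.0) + w
        return out

    # -- integer adjacency for the algorithm kernels ----------------------

    def int_adjacency(self) -> tuple[dict[str, int], list[list[int]], list[list[int]]]:
        """Node index map plus successor / predecessor lists of indices."""
        index = {n: i for i, n in enumerate(self._succ)}
        succ = [[index[v] for v in self._succ[n]] for n in self._succ]
        pred = [[index[u] for u in self._pred[n]] for n in self._pred]
        return index, succ, pred

    # -- I/O ---------------------------------------------------------------

    def to_edgelist_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["source", "target", "weight"])
            for u, v, w in self.edges():
                writer.writerow([u, v, repr(w)])

    @classmethod
    def from_edgelist_tsv(cls, path) -> "PainGraph":
        g = cls()
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or not {"source", "target", "weight"} <= set(
                reader.fieldnames
            ):
                raise ValueError(f"{path}: expected columns source, target, weight")
            for row in reader:
                g.add_edge(row["source"], row["target"], float(row["weight"]))
        return g

    def to_graphml(self, path) -> None:
        root = ET.Element("graphml", xmlns=_GRAPHML_NS)
        key = ET.SubElement(
            root, "key", id="w", **{"for": "edge", "attr.name": "weight", "attr.type": "double"}
        )
        del key
        for i, name in enumerate(("group", "x", "y", "z")):
            typ = "string" if name == "group" else "double"
            ET.SubElement(
                root, "key", id=f"n{i}", **{"for": "node", "attr.name": name, "attr.type": typ}
            )
        graph = ET.SubElement(root, "graph", id="G", edgedefault="directed")
        for n in self.nodes:
            el = ET.SubElement(graph, "node", id=n)
            attrs = self.node_attrs[n]
            names = ("group", "x", "y", "z")
            for i, name in enumerate(names):
                if name in attrs:
                    d = ET.SubElement(el, "data", key=f"n{i}")
                    d.text = str(attrs[name])
        for u, v, w in self.edges():
            el = ET.SubElement(graph, "edge", source=u, target=v)
            d = ET.SubElement(el, "data", key="w")
            d.text = repr(w)
        ET.ElementTree(root).write(path, xml_declaration=True, encoding="UTF-8")

    @classmethod
    def from_graphml(cls, path) -> "PainGraph":
        tree = ET.parse(path)
        root = tree.getroot()
        ns = {"g": _GRAPHML_NS}
        # map key id -> attribute name
        keymap = {k.get("id"): k.get("attr.name") for k in root.findall("g:key", ns)}
        graph = root.find("g:graph", ns)
        if graph is None:
            raise ValueError(f"{path}: no <graph> element")
        g = cls()
        for node in graph.findall("g:node", ns):
            attrs = {}
            for d in node.findall("g:data", ns):
                name = keymap.get(d.get("key"), d.get("key"))
                attrs[name] = float(d.text) if name in ("x", "y", "z") else d.text
            g.add_node(node.get("id"), **attrs)
        for edge in graph.findall("g:edge", ns):
            w = 1.0
            for d in edge.findall("g:data", ns):
                if keymap.get(d.get("key")) == "weight":
                    w = float(d.text)
            g.add_edge(edge.get("source"), edge.get("target"), w)
        return g

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PainGraph |V|={self.n_nodes} |E|={self.n_edges}>"
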