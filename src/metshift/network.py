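"""Undirected networks over metabolite names.

The common currency of the GGM and network-comparison layers: an edge is an
unordered pair of node names, optionally weighted. Node names are matched
exactly (case-sensitive) after stripping surrounding whitespace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

Edge = tuple[str, str]


def canonical_edge(a: str, b: str) -> Edge:
    """Return the unordered pair (a, b) in sorted order, names stripped.

    Raises ValueError on a self-loop.
    """
    a, b = str(a).strip(), str(b).strip()
    if a == b:
        raise ValueError(f"self-loop edge on node {a!r}")
    return (a, b) if a <= b else (b, a)


@dataclass
class UndirectedNetwork:
    """A set of unordered node pairs with optional per-edge weights."""

    edges: frozenset[Edge] = field(default_factory=frozenset)
    weights: dict[Edge, float] = field(default_factory=dict)
    nodes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.edges = frozenset(canonical_edge(*e) for e in self.edges)
        self.weights = {canonical_edge(*e): float(w) for e, w in self.weights.items()}
        endpoints = {u for e in self.edges for u in e}
        self.nodes = frozenset(self.nodes) | endpoints

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Edge],
        weights: Mapping[Edge, float] | None = None,
        nodes: Iterable[str] = (),
    ) -> "UndirectedNetwork":
        return cls(frozenset(edges), dict(weights or {}), frozenset(nodes))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        return sum(node in e for e in self.edges)

    def max_degree(self) -> int:
        deg: dict[str, int] = {}
        for u, v in self.edges:
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        return max(deg.values(), default=0)

    def __contains__(self, edge: Edge) -> bool:
        return canonical_edge(*edge) in self.edges

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UndirectedNetwork):
            return NotImplemented
        return self.edges == other.edges

    def __hash__(self) -> int:
        return hash(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for e in sorted(self.edges):
            g.add_edge(*e, weight=self.weights.get(e, 1.0))
        return g

    def warn_on_vocabulary_mismatch(self, other: "UndirectedNetwork") -> None:
        """Warn when the two networks' node vocabularies do not overlap fully."""
        only_self = sorted(self.nodes - other.nodes)
        only_other = sorted(other.nodes - self.nodes)
        if only_self or only_other:
            warnings.warn(
                "node vocabularies differ between networks; "
                f"only in first: {only_self[:10]}, only in second: {only_other[:10]}",
                stacklevel=2,
            )


def read_edge_list(path: str | Path) -> UndirectedNetwork:
    """Read a TSV edge list with columns node_a, node_b and optional weight.

    Edges are canonicalized as unordered pairs; "A B" and "B A" rows collapse
    to one edge. A self-loop row or a repeated edge with conflicting weights
    raises ValueError.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs at least two columns")
    has_weight = df.shape[1] >= 3
    edges: set[Edge] = set()
    weights: dict[Edge, float] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            e = canonical_edge(row[0], row[1])
        except ValueError as err:
            raise ValueError(f"{path} row {i}: {err}") from None
        if has_weight and not pd.isna(row[2]):
            w = float(row[2])
            if e in weights and weights[e] != w:
                raise ValueError(
                    f"{path} row {i}: edge {e} repeated with conflicting "
                    f"weights {weights[e]} and {w}"
                )
            weights[e] = w
        edges.add(e)
    return UndirectedNetwork.from_edges(edges, weights)


def write_edge_list(network: UndirectedNetwork, path: str | Path) -> None:
    """Write a network as TSV (node_a, node_b[, weight]); inverse of read_edge_list."""
    with open(path, "w") as fh:
        if network.weights:
            fh.write("node_a\tnode_b\tweight\n")
            for e in sorted(network.edges):
                w = network.weights.get(e, "")
                fh.write(f"{e[0]}\t{e[1]}\t{w}\n")
        else:
            fh.write("node_a\tnode_b\n")
            for e in sorted(network.edges):
                fh.write(f"{e[0]}\t{e[1]}\n")


def write_graphml(network: UndirectedNetwork, path: str | Path) -> None:
    nx.write_graphml(network.to_networkx(), path)
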