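"""Global directed network construction and local-network extraction.

The method walks a directed gene-interaction network: each gene ``g^k``
anchors a local network consisting of itself plus its first-order
neighbors, and the entropy of the probability flow from the center to its
neighbors is what gets scored.  Neighbors are taken along outgoing edges
by default (the flow is transmitted *from* the center along directed
edges); ``neighbor_mode`` switches to in-neighbors or the union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger("smfe")

__all__ = ["DirectedNetwork", "LocalNetwork", "build_network", "local_network", "scoreable_genes"]

NEIGHBOR_MODES = ("out", "in", "both")


@dataclass(frozen=True)
class LocalNetwork:
    """A center gene plus its M first-order neighbors (sorted by gene ID)."""

    center: str
    neighbors: tuple[str, ...]

    def __post_init__(self):
        if self.center in self.neighbors:
            raise ValueError(f"center {self.center!r} cannot be its own neighbor")

    @property
    def m(self) -> int:
        return len(self.neighbors)


class DirectedNetwork:
    """A directed gene-interaction network without self-loops or isolated nodes."""

    def __init__(self, edges: Iterable[tuple[str, str]]):
        edge_set = {(str(s), str(t)) for s, t in edges if str(s) != str(t)}
        self.edges: frozenset[tuple[str, str]] = frozenset(edge_set)
        self.nodes: frozenset[str] = frozenset(n for e in edge_set for n in e)
        self._out: dict[str, tuple[str, ...]] = {}
        self._in: dict[str, tuple[str, ...]] = {}
        out: dict[str, list[str]] = {n: [] for n in self.nodes}
        inn: dict[str, list[str]] = {n: [] for n in self.nodes}
        for s, t in edge_set:
            out[s].append(t)
            inn[t].append(s)
        self._out = {n: tuple(sorted(v)) for n, v in out.items()}
        self._in = {n: tuple(sorted(v)) for n, v in inn.items()}

    def out_neighbors(self, gene: str) -> tuple[str, ...]:
        return self._out[gene]

    def in_neighbors(self, gene: str) -> tuple[str, ...]:
        return self._in[gene]

    def neighbors(self, gene: str, mode: str = "out") -> tuple[str, ...]:
        if mode == "out":
            return self._out[gene]
        if mode == "in":
            return self._in[gene]
        if mode == "both":
            return tuple(sorted(set(self._out[gene]) | set(self._in[gene])))
        raise ValueError(f"neighbor_mode must be one of {NEIGHBOR_MODES}, got {mode!r}")

    def subgraph(self, keep: Iterable[str]) -> "DirectedNetwork":
        keep = set(keep)
        return DirectedNetwork((s, t) for s, t in self.edges if s in keep and t in keep)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __eq__(self, other) -> bool:
        return isinstance(other, DirectedNetwork) and self.edges == other.edges

    def __contains__(self, gene: str) -> bool:
        return gene in self.nodes

    def __repr__(self) -> str:
        return f"DirectedNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


def build_network(
    edges: Sequence[tuple],
    threshold: float = 0.8,
    directed: bool = False,
) -> DirectedNetwork:
    """Assemble the global directed network from an edge list.

    Parameters
    ----------
    edges
        Either scored triples ``(a, b, score)`` with scores on [0, 1], or
        bare pairs ``(source, target)`` (treated as score 1).
    threshold
        Minimum confidence score to keep an edge; the conventional STRING
        high-confidence cut is 0.8.
    directed
        When True, each pair is one directed edge source->target.  When
        False (no orientation supplied) each kept undirected edge becomes
        two directed edges — a documented fallback for users without an
        oriented network.

    Self-loops and nodes left isolated after thresholding are discarded.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    kept: list[tuple[str, str]] = []
    for edge in edges:
        if len(edge) == 3:
            a, b, score = edge
            if score < threshold:
                continue
        else:
            a, b = edge
        kept.append((str(a), str(b)))
        if not directed:
            kept.append((str(b), str(a)))
    if not directed:
        logger.info("undirected input: each kept edge used in both directions")
    net = DirectedNetwork(kept)
    if net.n_edges == 0:
        logger.warning("no edges passed the %.3g confidence threshold: empty network", threshold)
    return net


def local_network(net: DirectedNetwork, gene: str, neighbor_mode: str = "out") -> LocalNetwork:
    """Extract the local network of ``gene``: itself plus first-order neighbors."""
    if gene not in net:
        raise KeyError(f"unknown gene {gene!r}")
    return LocalNetwork(gene, net.neighbors(gene, neighbor_mode))


def scoreable_genes(
    net: DirectedNetwork, min_neighbors: int = 2, neighbor_mode: str = "out"
) -> set[str]:
    """Genes with at least ``min_neighbors`` neighbors.

    The differential score normalizes by log M, which vanishes at M = 1
    and is undefined at M = 0, so centers need M >= 2.  Excluded genes can
    still appear as neighbors of scoreable centers.
    """
    return {g for g in net.nodes if len(net.neighbors(g, neighbor_mode)) >= min_neighbors}
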