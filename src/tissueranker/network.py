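"""Protein-protein interaction networks and hub-centered complex extraction.

A "protein complex" here is the ego network of a hub: the hub protein plus
all of its direct interaction partners.  Hubs are the nodes whose degree
meets a cutoff (default 5 interactors), and the same protein may appear as
an interactor of several hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "ProteinComplex",
    "read_interactions",
    "extract_complexes",
]


@dataclass(frozen=True)
class ProteinComplex:
    """A hub protein together with its direct interactors.

    Interactors are stored sorted lexicographically so that every
    downstream average and report is reproducible regardless of input
    edge order.
    """

    hub: str
    interactors: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.hub in self.interactors:
            raise ValueError(f"hub {self.hub!r} listed among its own interactors")
        if len(set(self.interactors)) != len(self.interactors):
            raise ValueError(f"duplicate interactors for hub {self.hub!r}")

    @property
    def size(self) -> int:
        return len(self.interactors)


@dataclass
class InteractionNetwork:
    """Undirected interaction network: unique nodes, deduplicated edges,
    no self-loops."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))


def read_interactions(path: str | Path, fmt: str = "edge-list-tsv") -> InteractionNetwork:
    """Read an undirected network from a two-column edge list.

    Parameters
    ----------
    path
        TSV/whitespace-delimited file; lines starting with ``#`` are
        comments.  Each data line must carry at least two identifier
        tokens; extra columns are ignored.
    fmt
        ``"edge-list-tsv"`` (default) or ``"mitab"``.  The MITAB dialect
        reads only columns 1-2 and strips a leading ``prefix:`` from each
        identifier (PSI-MITAB 2.5 identifier syntax).

    Returns
    -------
    InteractionNetwork
        Deduplicated undirected network; self-loops are dropped and their
        count logged.

    Raises
    ------
    OSError
        If the file cannot be read.
    ValueError
        If no parsable edge is found.
    """
    if fmt not in {"edge-list-tsv", "mitab"}:
        raise ValueError(f"unknown format {fmt!r}")
    path = Path(path)
    graph: nx.Graph = nx.Graph()
    n_self = 0
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}: line with fewer than two columns: {line!r}")
            a, b = tokens[0].strip(), tokens[1].strip()
            if fmt == "mitab":
                a = a.split(":", 1)[-1]
                b = b.split(":", 1)[-1]
            n_lines += 1
            if a == b:
                n_self += 1
                continue
            graph.add_edge(a, b)
    if n_lines == 0:
        raise ValueError(f"{path}: no parsable edges")
    if n_self:
        logger.info("dropped %d self-loop(s) while reading %s", n_self, path)
    if graph.number_of_edges() == 0:
        raise ValueError(f"{path}: no edges left after self-loop removal")
    return InteractionNetwork(graph)


def extract_complexes(net: InteractionNetwork, min_degree: int = 5) -> list[ProteinComplex]:
    """Extract one hub-centered complex per node with degree >= ``min_degree``.

    Each complex's interactors are exactly the hub's network neighbors,
    sorted lexicographically.  Complexes are returned sorted by hub id, so
    the result is independent of input edge order.
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    complexes = [
        ProteinComplex(hub=node, interactors=tuple(sorted(net.neighbors(node))))
        for node in sorted(net.nodes)
        if net.degree(node) >= min_degree
    ]
    logger.info("extracted %d complex(es) at min_degree=%d", len(complexes), min_degree)
    return complexes
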