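"""Network and complex-set I/O, plus neighborhood-overlap edge weighting.

A protein-protein interaction (PPI) network is an undirected simple graph
over string protein identifiers.  Interactions observed between proteins
that share few interaction partners are more likely to be spurious, so each
edge (i, j) is weighted by the overlap of the closed neighborhoods
N(i), N(j) (a node's neighbors plus the node itself):

* ``product`` variant:   S_ij = |N(i) ∩ N(j)| / (|N(i)| · |N(j)|)
* ``geometric`` variant: S_ij = |N(i) ∩ N(j)| / sqrt(|N(i)| · |N(j)|)

Non-adjacent pairs (including the diagonal) get weight zero.  The geometric
variant is the cosine-like normalization bounded in (0, 1] on edges; the
product variant is the literal per-pair normalization.  Both are exposed
because published descriptions of this weighting are typeset ambiguously.

Complex sets (predicted or gold standard) use the de facto plain-text
format of MCL/ClusterONE outputs and CYC2008 exports: one complex per line,
whitespace-separated protein IDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "WeightMatrix",
    "ComplexSet",
    "read_edgelist",
    "compute_weights",
    "read_complexes",
    "write_complexes",
    "filter_min_size",
]


class PPINetwork:
    """Undirected simple graph of proteins with a fixed lexicographic node order.

    Self-loops are dropped at construction (with a warning) and parallel /
    reversed duplicate edges collapse, so the adjacency matrix is binary,
    symmetric and zero on the diagonal.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        n_loops = 0
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                n_loops += 1
                g.add_node(u)
                continue
            g.add_edge(u, v)
        if n_loops:
            logger.warning("dropped %d self-loop(s)", n_loops)
        self._graph = g
        self._nodes: tuple[str, ...] = tuple(sorted(g.nodes))

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "PPINetwork":
        return cls(graph.edges(), graph.nodes())

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> tuple[str, ...]:
        """Protein IDs in lexicographic order (fixes matrix row order)."""
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self._graph.edges()}

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix in node order."""
        return nx.to_numpy_array(self._graph, nodelist=self._nodes, dtype=float)

    def subnetwork(self, nodes: Iterable[str]) -> "PPINetwork":
        """Vertex-induced subnetwork (edges to outside nodes are discarded)."""
        sub = self._graph.subgraph(set(nodes))
        return PPINetwork(sub.edges(), sub.nodes())

    def __len__(self) -> int:
        return self.n_nodes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return self._nodes == other._nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"PPINetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric nonnegative pairwise interaction weights, aligned to a node order."""

    values: np.ndarray
    nodes: tuple[str, ...]
    variant: str = "product"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("weight matrix must be square")
        if v.shape[0] != len(self.nodes):
            raise ValueError("weight matrix does not match node list")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.nodes)


@dataclass
class ComplexSet:
    """Ordered collection of protein-ID sets (predicted or reference complexes)."""

    complexes: list[frozenset[str]] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        self.complexes = [frozenset(map(str, c)) for c in self.complexes]
        if any(len(c) == 0 for c in self.complexes):
            raise ValueError("complexes must be nonempty protein sets")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.complexes)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.complexes[i]

    def dedup(self) -> "ComplexSet":
        """Collapse exact-duplicate sets, keeping first occurrence order."""
        seen: set[frozenset[str]] = set()
        out = []
        for c in self.complexes:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return ComplexSet(out, source=self.source)

    def proteins(self) -> set[str]:
        return set().union(*self.complexes) if self.complexes else set()


def read_edgelist(path: str | Path, format: str = "tsv") -> PPINetwork:
    """Read an undirected PPI network from a whitespace-delimited edge list.

    ``tsv``: two or more columns per line; the first two are protein IDs and
    any further columns (e.g. confidence weights) are ignored.  ``sif``:
    Cytoscape simple-interaction format ``source  type  target [target ...]``.
    Duplicate and reversed-duplicate lines collapse; self-loops are dropped
    with a warning.
    """
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format: {format!r}")
    path = Path(path)
    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if format == "tsv":
                if len(tokens) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected at least 2 columns, got {len(tokens)}"
                    )
                edges.append((tokens[0], tokens[1]))
            else:  # sif
                if len(tokens) == 1:
                    nodes.append(tokens[0])  # isolated node, legal SIF
                elif len(tokens) == 2:
                    raise ValueError(
                        f"{path}:{lineno}: SIF line needs 'source type target'"
                    )
                else:
                    src = tokens[0]
                    edges.extend((src, tgt) for tgt in tokens[2:])
    if not edges and not nodes:
        raise ValueError(f"{path}: no edges found")
    return PPINetwork(edges, nodes)


def compute_weights(net: PPINetwork, variant: str = "product") -> WeightMatrix:
    """Neighborhood-overlap weight matrix of a network.

    With M = A + I (closed-neighborhood indicator), |N(i) ∩ N(j)| = (M·M)_ij
    and |N(i)| = row sums of M; weights are supported exactly on the edge
    set.  Every edge has |N(i) ∩ N(j)| ≥ 2 (both endpoints belong to both
    closed neighborhoods), so weights are strictly positive on edges.
    """
    if variant not in ("product", "geometric"):
        raise ValueError(f"unknown weight variant: {variant!r}")
    if net.n_nodes == 0:
        raise ValueError("cannot weight an empty network")
    A = net.adjacency()
    M = A + np.eye(net.n_nodes)
    common = M @ M
    sizes = M.sum(axis=1)
    denom = np.outer(sizes, sizes)
    if variant == "geometric":
        denom = np.sqrt(denom)
    S = np.where(A > 0, common / denom, 0.0)
    return WeightMatrix(values=S, nodes=net.nodes, variant=variant)


def read_complexes(path: str | Path, source: str | None = None) -> ComplexSet:
    """Read complexes from text: one complex per line, whitespace-separated IDs.

    Duplicate IDs within a line collapse; empty lines are skipped with a
    warning.
    """
    path = Path(path)
    complexes: list[frozenset[str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if not tokens:
                logger.warning("%s:%d: empty line skipped", path, lineno)
                continue
            complexes.append(frozenset(tokens))
    return ComplexSet(complexes, source=source if source is not None else str(path))


def write_complexes(cs: ComplexSet, path: str | Path) -> None:
    """Write one complex per line, member IDs sorted for reproducible files."""
    path = Path(path)
    with path.open("w") as fh:
        for c in cs:
            fh.write(" ".join(sorted(c)) + "\n")


def filter_min_size(cs: ComplexSet, min_size: int) -> ComplexSet:
    """Keep complexes with at least ``min_size`` proteins, preserving order."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return ComplexSet([c for c in cs if len(c) >= min_size], source=cs.source)
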