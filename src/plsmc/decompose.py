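"""Recursive decomposition of a PPI network into bounded-size subnetworks.

Fitting the propensity model directly on a genome-scale network is
prohibitively slow, so the network is first cut into subnetworks of at most
``max_size`` proteins by greedy agglomerative modularity maximization
(Clauset-Newman-Moore, the "fastCommunity" algorithm), applied recursively
to any part that is still too large.  Clustering runs on the unweighted
graph; interaction weights are computed per subnetwork afterwards, from the
subnetwork's own topology.

Parts are vertex-induced subgraphs, so edges between subnetworks are
discarded: a complex spanning two subnetworks is undetectable downstream.
That loss is inherent to the divide-and-conquer strategy.  A part that
greedy modularity refuses to split (a single community) is returned whole
with a warning rather than force-bisected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
from networkx.algorithms.community import greedy_modularity_communities

from .network_io import PPINetwork

logger = logging.getLogger(__name__)

__all__ = ["DecomposeConfig", "modularity_split", "decompose"]

#: No yeast complex catalogued in CYC2008 exceeds 200 proteins, and larger
#: caps trade little accuracy for much slower optimization.
DEFAULT_MAX_SIZE = 200


@dataclass(frozen=True)
class DecomposeConfig:
    """Size cap for the recursive split.

    ``max_size`` must be at least 4: a complex needs three proteins, so a
    smaller cap could not contain any detectable complex plus context.
    """

    max_size: int = DEFAULT_MAX_SIZE

    def __post_init__(self) -> None:
        if self.max_size < 4:
            raise ValueError("max_size must be >= 4")


def _sort_key(part: PPINetwork) -> tuple[str, ...]:
    return part.nodes


def modularity_split(net: PPINetwork) -> list[PPINetwork]:
    """One level of greedy modularity clustering; returns induced subnetworks.

    Connected components are separated first (merging across components can
    never raise modularity).  Within a component the Clauset-Newman-Moore
    greedy merge is run to its modularity maximum; a component that is best
    left whole (e.g. a clique) comes back as a single part.  The returned
    parts partition the node set and are ordered by node label.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot split an empty network")
    parts: list[PPINetwork] = []
    for comp in nx.connected_components(net.graph):
        sub = net.graph.subgraph(comp)
        if sub.number_of_nodes() < 3 or sub.number_of_edges() == 0:
            parts.append(PPINetwork(sub.edges(), sub.nodes()))
            continue
        communities = greedy_modularity_communities(sub)
        for comm in communities:
            csub = sub.subgraph(comm)
            parts.append(PPINetwork(csub.edges(), csub.nodes()))
    parts.sort(key=_sort_key)
    return parts


def decompose(net: PPINetwork, cfg: DecomposeConfig | None = None) -> list[PPINetwork]:
    """Recursively split ``net`` until every part has at most ``cfg.max_size`` nodes.

    A part the splitter returns unchanged is kept as-is with a warning (it
    is "unsplittable": a single modularity community larger than the cap).
    The returned parts are node-disjoint and cover the input node set.
    """
    cfg = cfg or DecomposeConfig()
    done: list[PPINetwork] = []
    stack: list[PPINetwork] = [net]
    while stack:
        part = stack.pop()
        if part.n_nodes <= cfg.max_size:
            done.append(part)
            continue
        pieces = modularity_split(part)
        if len(pieces) == 1:
            logger.warning(
                "subnetwork of %d nodes exceeds max_size=%d but is a single "
                "modularity community; processing it whole",
                part.n_nodes,
                cfg.max_size,
            )
            done.append(part)
            continue
        stack.extend(pieces)
    done.sort(key=_sort_key)
    return done
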