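"""Synthetic PPI networks with planted, optionally overlapping complexes.

The generator follows a planted-partition (stochastic block) construction:
proteins are allocated to complexes (a member is recycled from an earlier
complex with probability ``overlap_prob``), a pool of background proteins
belongs to no complex, and then every co-complex protein pair is connected
independently with probability ``p_in`` while every other pair gets a
background edge with probability ``p_out``.  This mirrors the modelling
premise that co-complex proteins are likely to interact — complexes appear
as dense regions against a sparse background — without attempting an
AP-MS-specific noise model.

The planted complexes are returned as the matching gold standard, so the
whole detection pipeline and its evaluation metrics can be exercised with
no external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .network_io import ComplexSet, PPINetwork

__all__ = ["SyntheticSpec", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-complex generator.

    Defaults describe a small benchmark instance: 10 complexes of 5–10
    proteins, dense inside (p_in = 0.9), very sparse background
    (p_out = 0.005), mild overlap, and 10 background proteins.
    """

    n_complexes: int = 10
    size_range: tuple[int, int] = (5, 10)
    overlap_prob: float = 0.1
    p_in: float = 0.9
    p_out: float = 0.005
    n_background: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if lo < 3 or hi < lo:
            raise ValueError("size_range must satisfy 3 <= min <= max")
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("probabilities must satisfy 0 <= p_out < p_in <= 1")
        if not (0 <= self.overlap_prob <= 1):
            raise ValueError("overlap_prob must be in [0, 1]")
        if self.n_complexes < 0 or self.n_background < 0:
            raise ValueError("counts must be nonnegative")


def generate(spec: SyntheticSpec) -> tuple[PPINetwork, ComplexSet]:
    """Draw one synthetic network and its planted gold standard.

    Fully determined by ``spec.seed``.  Every planted protein appears in the
    network's node set even if it ends up with no edges.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.size_range

    counter = 0

    def new_protein() -> str:
        nonlocal counter
        counter += 1
        return f"P{counter:04d}"

    complexes: list[frozenset[str]] = []
    used: list[str] = []  # proteins already planted, in creation order
    for _ in range(spec.n_complexes):
        size = int(rng.integers(lo, hi + 1))
        members: set[str] = set()
        while len(members) < size:
            candidates = [p for p in used if p not in members]
            if candidates and rng.random() < spec.overlap_prob:
                members.add(candidates[int(rng.integers(len(candidates)))])
            else:
                p = new_protein()
                used.append(p)
                members.add(p)
        complexes.append(frozenset(members))

    background = [new_protein() for _ in range(spec.n_background)]
    nodes = sorted(used + background)

    cocomplex: set[frozenset[str]] = set()
    for c in complexes:
        cocomplex.update(frozenset(pair) for pair in combinations(sorted(c), 2))

    edges: list[tuple[str, str]] = []
    for u, v in combinations(nodes, 2):
        p = spec.p_in if frozenset((u, v)) in cocomplex else spec.p_out
        if rng.random() < p:
            edges.append((u, v))

    net = PPINetwork(edges, nodes)
    gold = ComplexSet(complexes, source=f"planted(seed={spec.seed})")
    return net, gold
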