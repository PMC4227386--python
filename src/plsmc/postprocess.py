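"""Turn estimated propensities into complexes.

A protein joins candidate complex k whenever its propensity clears the
threshold τ.  Columns that capture no protein disappear, exact-duplicate
complexes collapse to one, and complexes with fewer than ``min_size``
(default 3) proteins are removed — a pair of proteins is an interaction,
not a complex.  Because a protein's row may clear τ in several columns,
overlapping complexes arise naturally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import OptimizationResult
from .network_io import ComplexSet, filter_min_size

__all__ = ["PostprocessConfig", "threshold_complexes", "merge_results"]


@dataclass(frozen=True)
class PostprocessConfig:
    """Propensity threshold τ and minimum complex size.

    τ defaults to 0.2, the middle of the 0.05–0.5 range a model-selection
    sweep would scan; it is a single global threshold, not per-complex.
    """

    tau: float = 0.2
    min_size: int = 3

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


def threshold_complexes(
    result: OptimizationResult | np.ndarray,
    node_ids: Sequence[str],
    cfg: PostprocessConfig | None = None,
) -> ComplexSet:
    """Extract complexes {i : θ_ik ≥ τ} from each column of the propensity matrix."""
    cfg = cfg or PostprocessConfig()
    theta = result.theta if isinstance(result, OptimizationResult) else np.asarray(result)
    if theta.ndim != 2 or theta.shape[0] != len(node_ids):
        raise ValueError(
            f"propensity matrix with {theta.shape[0]} rows does not match "
            f"{len(node_ids)} node IDs"
        )
    ids = list(node_ids)
    complexes = []
    for k in range(theta.shape[1]):
        members = frozenset(ids[i] for i in np.flatnonzero(theta[:, k] >= cfg.tau))
        if members:
            complexes.append(members)
    cs = ComplexSet(complexes).dedup()
    return filter_min_size(cs, cfg.min_size)


def merge_results(parts: Sequence[ComplexSet]) -> ComplexSet:
    """Concatenate per-subnetwork complex sets, preserving subnetwork order.

    The subnetworks are node-disjoint by construction, so no cross-part
    deduplication is possible; overlapping protein sets across parts violate
    that contract and raise.
    """
    seen: set[str] = set()
    merged = []
    for part in parts:
        part_proteins = part.proteins()
        overlap = seen & part_proteins
        if overlap:
            raise ValueError(
                f"complex sets to merge share proteins across parts: "
                f"{sorted(overlap)[:5]}"
            )
        seen |= part_proteins
        merged.extend(part.complexes)
    return ComplexSet(merged)
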