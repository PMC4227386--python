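"""Evaluation of predicted complexes against a reference catalogue.

Three complementary views of agreement between a predicted set P and a
reference (gold standard) set B:

* **f-measure** — complex-level: a prediction p matches a reference b when
  the overlap score os(p, b) = |p∩b|² / (|p|·|b|) reaches the matching
  threshold ov (0.25 by convention).  Precision counts matched predictions,
  recall counts matched references, and f is their harmonic mean.
* **Acc** — protein-level: from the confusion matrix T_ij = |b_i ∩ p_j|,
  sensitivity Sn = Σ_i max_j T_ij / Σ_i |b_i| and positive predictive value
  PPV = Σ_j max_i T_ij / Σ_ij T_ij; Acc is their geometric mean
  sqrt(Sn·PPV).
* **MMR** — maximum matching ratio: the mean over reference complexes of
  the best overlap score any prediction achieves against them.

The composite score f + Acc + MMR (range [0, 3]) is the single number used
for model selection and method comparison.  A "perfect match" is os = 1,
i.e. exact set equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from math import sqrt
from typing import AbstractSet

from .network_io import ComplexSet

logger = logging.getLogger(__name__)

__all__ = [
    "EvalConfig",
    "EvalReport",
    "overlap_score",
    "precision_recall_f",
    "sn_ppv_acc",
    "mmr",
    "evaluate",
]


@dataclass(frozen=True)
class EvalConfig:
    """Matching threshold and reference filtering for evaluation.

    ``ov``
        overlap-score threshold for complex matching, in (0, 1]; 0.25 is the
        community convention.
    ``min_ref_size``
        reference complexes smaller than this are dropped before scoring
        (catalogues list pairs, which are not complexes for this purpose).
    ``strict_greater``
        require os > ov instead of os ≥ ov.  Off by default so the
        conventional 0.25 threshold behaves as in the benchmark literature.
    ``acc_geometric``
        Acc = sqrt(Sn·PPV) (the metric's standard form) when true; the
        literal product Sn·PPV when false.
    """

    ov: float = 0.25
    min_ref_size: int = 3
    strict_greater: bool = False
    acc_geometric: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.ov <= 1):
            raise ValueError("ov must be in (0, 1]")
        if self.min_ref_size < 1:
            raise ValueError("min_ref_size must be >= 1")

    def matches(self, os_value: float) -> bool:
        return os_value > self.ov if self.strict_greater else os_value >= self.ov


@dataclass
class EvalReport:
    """All matching statistics of a prediction against a reference set."""

    precision: float
    recall: float
    f_measure: float
    sn: float
    ppv: float
    acc: float
    mmr: float
    composite: float
    n_cp: int
    n_cb: int
    n_predicted: int
    n_reference: int
    perfect_matches: int

    def to_dict(self) -> dict:
        return asdict(self)


def overlap_score(p: AbstractSet[str], b: AbstractSet[str]) -> float:
    """Overlap score os(p, b) = |p∩b|² / (|p|·|b|) ∈ [0, 1]; 1 iff p == b."""
    if not p or not b:
        raise ValueError("overlap score of an empty set is undefined")
    inter = len(set(p) & set(b))
    return inter * inter / (len(p) * len(b))


def precision_recall_f(
    P: ComplexSet, B: ComplexSet, cfg: EvalConfig | None = None
) -> tuple[float, float, float]:
    """Complex-level precision, recall and f-measure at threshold ``cfg.ov``."""
    cfg = cfg or EvalConfig()
    if len(P) == 0 or len(B) == 0:
        logger.warning("empty prediction or reference set: f-measure metrics are 0")
        return 0.0, 0.0, 0.0
    n_cp = sum(1 for p in P if any(cfg.matches(overlap_score(p, b)) for b in B))
    n_cb = sum(1 for b in B if any(cfg.matches(overlap_score(p, b)) for p in P))
    precision = n_cp / len(P)
    recall = n_cb / len(B)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f


def sn_ppv_acc(
    P: ComplexSet, B: ComplexSet, geometric: bool = True
) -> tuple[float, float, float]:
    """Protein-level sensitivity, PPV and their (geometric-mean) accuracy."""
    if len(P) == 0 or len(B) == 0:
        logger.warning("empty prediction or reference set: Sn/PPV/Acc are 0")
        return 0.0, 0.0, 0.0
    T = [[len(b & p) for p in P] for b in B]
    sn_num = sum(max(row) for row in T)
    sn_den = sum(len(b) for b in B)
    sn = sn_num / sn_den
    col_max = [max(T[i][j] for i in range(len(B))) for j in range(len(P))]
    ppv_den = sum(sum(row) for row in T)
    ppv = sum(col_max) / ppv_den if ppv_den > 0 else 0.0
    acc = sqrt(sn * ppv) if geometric else sn * ppv
    return sn, ppv, acc


def mmr(P: ComplexSet, B: ComplexSet) -> float:
    """Maximum matching ratio: mean best overlap score per reference complex."""
    if len(B) == 0:
        raise ValueError("MMR needs a nonempty reference set")
    if len(P) == 0:
        return 0.0
    return sum(max(overlap_score(p, b) for p in P) for b in B) / len(B)


def evaluate(
    P: ComplexSet, B: ComplexSet, cfg: EvalConfig | None = None
) -> EvalReport:
    """Full evaluation report, including the composite score f + Acc + MMR.

    The reference set is expected to be size-filtered already (see
    ``cfg.min_ref_size`` and :func:`plsmc.network_io.filter_min_size`);
    this function does not filter.
    """
    cfg = cfg or EvalConfig()
    precision, recall, f = precision_recall_f(P, B, cfg)
    sn, ppv, acc = sn_ppv_acc(P, B, geometric=cfg.acc_geometric)
    if len(B) == 0:
        mmr_value = 0.0
        perfect = 0
    else:
        mmr_value = mmr(P, B)
        pred_sets = set(P.complexes)
        perfect = sum(1 for b in B if b in pred_sets)
    if len(P) == 0 or len(B) == 0:
        n_cp = n_cb = 0
    else:
        n_cp = sum(1 for p in P if any(cfg.matches(overlap_score(p, b)) for b in B))
        n_cb = sum(1 for b in B if any(cfg.matches(overlap_score(p, b)) for p in P))
    return EvalReport(
        precision=precision,
        recall=recall,
        f_measure=f,
        sn=sn,
        ppv=ppv,
        acc=acc,
        mmr=mmr_value,
        composite=f + acc + mmr_value,
        n_cp=n_cp,
        n_cb=n_cb,
        n_predicted=len(P),
        n_reference=len(B),
        perfect_matches=perfect,
    )
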