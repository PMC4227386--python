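"""End-to-end complex detection: decompose → weight → fit → threshold → merge.

The pipeline mirrors the method's algorithm skeleton: the input network is
recursively split into subnetworks of bounded size, each subnetwork gets its
own neighborhood-overlap weight matrix, the propensity model is fitted per
subnetwork with random restarts, propensities are thresholded into
complexes, and the per-subnetwork complex sets are concatenated.

``grid_search`` reproduces the standard model-selection protocol against a
gold standard: sweep the penalty λ over 2⁻⁵…2⁵ and the threshold τ over
0.05–0.5 (step 0.05) and keep the pair with the best composite score.  The
fit is reused across τ values, so the sweep costs one optimization per λ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import OptimizationResult, OptimizerConfig, default_k, fit_restarts
from .decompose import DecomposeConfig, decompose
from .metrics import EvalConfig, evaluate
from .network_io import ComplexSet, PPINetwork, compute_weights, filter_min_size
from .postprocess import PostprocessConfig, merge_results, threshold_complexes

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "detect_complexes", "grid_search", "PAPER_LAMBDA_GRID", "TAU_GRID"]

#: Conventional model-selection grids: λ = 2^-5 … 2^5, τ = 0.05 … 0.5 step 0.05.
PAPER_LAMBDA_GRID: tuple[float, ...] = tuple(2.0 ** p for p in range(-5, 6))
TAU_GRID: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(1, 11))


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the detection pipeline in one place."""

    lam: float = 1.0
    tau: float = 0.2
    k: int | None = None  # None -> ceil(n/3) per subnetwork
    max_size: int = 200
    restarts: int = 100
    seed: int = 0
    weight_variant: str = "product"
    min_size: int = 3
    max_iter: int = 1000
    rel_tol: float = 1e-6


def _subnetwork_seed(base_seed: int, index: int) -> int:
    """Deterministic per-subnetwork seed stream, independent across indices."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(index,))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def _fit_subnetworks(
    net: PPINetwork, cfg: PipelineConfig
) -> list[tuple[PPINetwork, OptimizationResult]]:
    """Decompose and fit every subnetwork; thresholding is left to the caller."""
    parts = decompose(net, DecomposeConfig(max_size=cfg.max_size))
    fitted: list[tuple[PPINetwork, OptimizationResult]] = []
    for idx, part in enumerate(parts):
        S = compute_weights(part, variant=cfg.weight_variant)
        opt_cfg = OptimizerConfig(
            k=cfg.k if cfg.k is not None else default_k(part.n_nodes),
            lam=cfg.lam,
            max_iter=cfg.max_iter,
            rel_tol=cfg.rel_tol,
            restarts=cfg.restarts,
            seed=_subnetwork_seed(cfg.seed, idx),
        )
        fitted.append((part, fit_restarts(S, opt_cfg)))
    return fitted


def _threshold_all(
    fitted: Sequence[tuple[PPINetwork, OptimizationResult]],
    tau: float,
    min_size: int,
) -> ComplexSet:
    post_cfg = PostprocessConfig(tau=tau, min_size=min_size)
    parts = [threshold_complexes(res, part.nodes, post_cfg) for part, res in fitted]
    return merge_results(parts)


def detect_complexes(
    net: PPINetwork, cfg: PipelineConfig | None = None
) -> tuple[ComplexSet, dict]:
    """Run the full pipeline on a network.

    Returns the predicted complexes and a JSON-serializable run summary
    recording effective parameters and, per subnetwork, its size, final
    objective, iteration count and winning restart.
    """
    cfg = cfg or PipelineConfig()
    fitted = _fit_subnetworks(net, cfg)
    predicted = _threshold_all(fitted, cfg.tau, cfg.min_size)
    summary = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "parameters": {
            "lambda": cfg.lam,
            "tau": cfg.tau,
            "k": cfg.k if cfg.k is not None else "ceil(n/3)",
            "max_size": cfg.max_size,
            "restarts": cfg.restarts,
            "seed": cfg.seed,
            "weight_variant": cfg.weight_variant,
            "min_size": cfg.min_size,
            "max_iter": cfg.max_iter,
            "rel_tol": cfg.rel_tol,
        },
        "n_subnetworks": len(fitted),
        "subnetworks": [
            {
                "n_nodes": part.n_nodes,
                "n_edges": part.n_edges,
                "k": int(res.theta.shape[1]),
                "objective": res.objective,
                "iterations": res.iterations,
                "converged": res.converged,
                "winning_restart": res.seed_used,
            }
            for part, res in fitted
        ],
        "n_complexes": len(predicted),
    }
    return predicted, summary


def grid_search(
    net: PPINetwork,
    gold: ComplexSet,
    cfg: PipelineConfig | None = None,
    lambdas: Sequence[float] | None = None,
    taus: Sequence[float] | None = None,
    eval_cfg: EvalConfig | None = None,
) -> dict:
    """Select (λ, τ) maximizing the composite score against ``gold``.

    The gold standard is size-filtered with ``eval_cfg.min_ref_size`` before
    scoring.  Ties break toward the first (λ, τ) pair in grid order.
    Returns the best pair, its score, the winning prediction, and the full
    score table.
    """
    cfg = cfg or PipelineConfig()
    eval_cfg = eval_cfg or EvalConfig()
    lambdas = tuple(lambdas) if lambdas is not None else PAPER_LAMBDA_GRID
    taus = tuple(taus) if taus is not None else TAU_GRID
    reference = filter_min_size(gold, eval_cfg.min_ref_size)

    best = None
    table = []
    for lam in lambdas:
        lam_cfg = PipelineConfig(**{**cfg.__dict__, "lam": lam})
        fitted = _fit_subnetworks(net, lam_cfg)
        for tau in taus:
            predicted = _threshold_all(fitted, tau, cfg.min_size)
            report = evaluate(predicted, reference, eval_cfg)
            table.append(
                {"lambda": lam, "tau": tau, "composite": report.composite,
                 "f_measure": report.f_measure, "acc": report.acc, "mmr": report.mmr}
            )
            if best is None or report.composite > best["composite"]:
                best = {
                    "lambda": lam,
                    "tau": tau,
                    "composite": report.composite,
                    "report": report,
                    "predicted": predicted,
                }
    assert best is not None
    return {
        "best_lambda": best["lambda"],
        "best_tau": best["tau"],
        "best_composite": best["composite"],
        "best_report": best["report"],
        "best_predicted": best["predicted"],
        "table": table,
    }
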