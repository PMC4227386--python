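"""Penalized least-squares estimation of protein-to-complex propensities.

The model posits a nonnegative N×K matrix Θ = [θ_ik] of propensities, where
θ_ik scores how strongly protein i belongs to candidate complex k.  The
cocomplex coefficient of a protein pair, C_ij = Σ_z θ_iz θ_jz, is fitted to
the interaction weight S_ij by minimizing

    L(Θ) = Σ_{i,j} ½ (Σ_z θ_iz θ_jz − S_ij)² + λ Σ_i Σ_z θ_iz²,   Θ ≥ 0,

where the sum runs over all ordered pairs (i, j) including i = j (the
diagonal of S is zero, so the i = j terms act as additional shrinkage on
row norms).  The ridge penalty λ > 0 controls the overlap rate: without it
a protein can accumulate many large propensities and be assigned to far too
many complexes.

The minimizer is sought with a damped multiplicative update derived from the
KKT conditions of the nonnegativity-constrained problem:

    θ_ik ← θ_ik/2 + (θ_ik/2) · [Σ_j θ_jk S_ij] / [Σ_j θ_jk C_ij + λ θ_ik]

which preserves nonnegativity (zero entries are fixed points), is a gradient
step with an adaptive, entrywise step length, and does not increase L.
Because L is non-convex in Θ, the fit is repeated from many random starts
and the run with the smallest final L is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network_io import WeightMatrix

__all__ = [
    "OptimizerConfig",
    "OptimizationResult",
    "objective",
    "gradient",
    "update_step",
    "random_init",
    "estimate",
    "fit_restarts",
    "default_k",
]


def default_k(n_nodes: int) -> int:
    """Default number of candidate complexes for a subnetwork of n proteins.

    A reported complex has at least 3 members, so at most ceil(n/3) disjoint
    complexes fit in the subnetwork; overlapping complexes beyond that are
    rare at subnetwork scale.
    """
    return max(1, math.ceil(n_nodes / 3))


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings for the propensity fit.

    ``k``
        number of candidate complexes (columns of Θ); ``None`` applies the
        ceil(n/3) rule per subnetwork.
    ``lam``
        ridge penalty λ > 0 shrinking propensities (λ = 0 is accepted for
        the unpenalized least-squares variant).  Default 1.0, the center of
        the 2⁻⁵…2⁵ grid a model-selection sweep would scan.
    ``restarts``
        independent random initializations; the minimum-objective run wins.
    ``eps``
        tiny guard added to the update denominator so all-zero columns do
        not divide by zero; a true zero entry stays zero regardless.
    """

    k: int | None = None
    lam: float = 1.0
    max_iter: int = 1000
    rel_tol: float = 1e-6
    restarts: int = 100
    seed: int = 0
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


@dataclass
class OptimizationResult:
    """Outcome of one (or the best of many) propensity fits.

    ``trajectory`` holds the objective value before any update followed by
    the value after each iteration; it is non-increasing up to roundoff and
    its last entry equals ``objective``.
    """

    theta: np.ndarray
    objective: float
    trajectory: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    seed_used: int | None = None


def _as_matrix(S: WeightMatrix | np.ndarray) -> np.ndarray:
    if isinstance(S, WeightMatrix):
        return S.values
    return np.asarray(S, dtype=float)


def objective(theta: np.ndarray, S: WeightMatrix | np.ndarray, lam: float) -> float:
    """Penalized squared reconstruction error L(Θ) over all ordered pairs."""
    S = _as_matrix(S)
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[0] != S.shape[0]:
        raise ValueError(
            f"theta shape {theta.shape} incompatible with weights {S.shape}"
        )
    resid = theta @ theta.T - S
    return float(0.5 * np.sum(resid * resid) + lam * np.sum(theta * theta))


def gradient(theta: np.ndarray, S: WeightMatrix | np.ndarray, lam: float) -> np.ndarray:
    """Analytic gradient ∂L/∂θ_ik = 2 Σ_j θ_jk C_ij − 2 Σ_j θ_jk S_ij + 2λ θ_ik."""
    S = _as_matrix(S)
    theta = np.asarray(theta, dtype=float)
    return 2.0 * (theta @ (theta.T @ theta)) - 2.0 * (S @ theta) + 2.0 * lam * theta


def update_step(
    theta: np.ndarray,
    S: WeightMatrix | np.ndarray,
    lam: float,
    eps: float = 1e-12,
) -> np.ndarray:
    """One damped multiplicative update of every propensity simultaneously.

    Nonnegativity is preserved and zero entries remain zero.  Raises if any
    input entry is negative (the rule is only valid on the feasible set).
    """
    S = _as_matrix(S)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("propensity matrix must be nonnegative")
    numer = S @ theta                      # Σ_j θ_jk S_ij   (S symmetric)
    denom = theta @ (theta.T @ theta) + lam * theta + eps
    return 0.5 * theta + 0.5 * theta * numer / denom


def random_init(
    S: WeightMatrix | np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Random starting point with entries uniform on (0, s].

    The scale s = sqrt(mean(S)/k) places the initial reconstruction ΘΘᵀ on
    the same order of magnitude as S, so early iterations neither explode
    nor collapse.
    """
    S = _as_matrix(S)
    n = S.shape[0]
    mean = float(S.mean())
    s = math.sqrt(max(mean, 1e-12) / k)
    # 1 - random() is uniform on (0, 1], keeping strictly positive entries.
    return s * (1.0 - rng.random((n, k)))


def estimate(
    S: WeightMatrix | np.ndarray,
    cfg: OptimizerConfig,
    init: np.ndarray,
) -> OptimizationResult:
    """Iterate the multiplicative update from ``init`` until convergence.

    Stops when the relative objective change |L_t − L_{t−1}| / (1 + L_{t−1})
    drops below ``cfg.rel_tol``, or after ``cfg.max_iter`` iterations.
    Deterministic given ``init``.
    """
    S = _as_matrix(S)
    theta = np.array(init, dtype=float, copy=True)
    if np.any(theta < 0):
        raise ValueError("initial propensity matrix must be nonnegative")
    lam = cfg.lam
    trajectory = [objective(theta, S, lam)]
    converged = False
    iterations = 0
    for _ in range(cfg.max_iter):
        theta = update_step(theta, S, lam, cfg.eps)
        L = objective(theta, S, lam)
        prev = trajectory[-1]
        trajectory.append(L)
        iterations += 1
        if abs(L - prev) / (1.0 + prev) < cfg.rel_tol:
            converged = True
            break
    return OptimizationResult(
        theta=theta,
        objective=trajectory[-1],
        trajectory=trajectory,
        iterations=iterations,
        converged=converged,
    )


def fit_restarts(
    S: WeightMatrix | np.ndarray,
    cfg: OptimizerConfig,
) -> OptimizationResult:
    """Fit from ``cfg.restarts`` random starts and keep the minimum-L run.

    Restart r draws its initialization from an RNG seeded by the pair
    (cfg.seed, r), so every restart is independent yet reproducible, and the
    winner does not depend on execution order.  Ties break toward the lowest
    restart index.
    """
    S = _as_matrix(S)
    k = cfg.k if cfg.k is not None else default_k(S.shape[0])
    best: OptimizationResult | None = None
    for r in range(cfg.restarts):
        rng = np.random.default_rng([cfg.seed, r])
        init = random_init(S, k, rng)
        result = estimate(S, cfg, init)
        result.seed_used = r
        if best is None or result.objective < best.objective:
            best = result
    assert best is not None
    return best
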