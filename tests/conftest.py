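"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive transcriptions (explicit Python
loops over indices and pairs) so they stay independent of the vectorized
implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from plsmc import ComplexSet, PPINetwork

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=40)
settings.load_profile("suite")


# ---------------------------------------------------------------- oracles


def naive_update_step(theta: np.ndarray, S: np.ndarray, lam: float,
                      eps: float = 1e-12) -> np.ndarray:
    """Entrywise triple-loop transcription of the damped multiplicative rule."""
    n, k = theta.shape
    out = np.zeros_like(theta)
    for i in range(n):
        for c in range(k):
            numer = sum(theta[j, c] * S[i, j] for j in range(n))
            denom = (
                sum(
                    theta[j, c] * sum(theta[i, z] * theta[j, z] for z in range(k))
                    for j in range(n)
                )
                + lam * theta[i, c]
                + eps
            )
            out[i, c] = theta[i, c] / 2 + (theta[i, c] / 2) * numer / denom
    return out


def naive_objective(theta: np.ndarray, S: np.ndarray, lam: float) -> float:
    """Loop transcription of the penalized least-squares objective."""
    n, k = theta.shape
    total = 0.0
    for i in range(n):
        for j in range(n):
            c_ij = sum(theta[i, z] * theta[j, z] for z in range(k))
            total += 0.5 * (c_ij - S[i, j]) ** 2
    total += lam * sum(theta[i, z] ** 2 for i in range(n) for z in range(k))
    return total


def brute_force_report(P: list[set], B: list[set], ov: float = 0.25) -> dict:
    """Double-loop recomputation of every evaluation metric."""
    def os_(p, b):
        return len(p & b) ** 2 / (len(p) * len(b))

    if not P or not B:
        return dict(precision=0.0, recall=0.0, f_measure=0.0, sn=0.0, ppv=0.0,
                    acc=0.0, mmr=0.0 if B else None, composite=0.0,
                    n_cp=0, n_cb=0, perfect_matches=0)
    n_cp = 0
    for p in P:
        if any(os_(p, b) >= ov for b in B):
            n_cp += 1
    n_cb = 0
    for b in B:
        if any(os_(p, b) >= ov for p in P):
            n_cb += 1
    precision = n_cp / len(P)
    recall = n_cb / len(B)
    f = 0.0
    if precision + recall > 0:
        f = 2 * precision * recall / (precision + recall)
    sn_num = sn_den = 0
    for b in B:
        sn_num += max(len(b & p) for p in P)
        sn_den += len(b)
    ppv_num = 0
    ppv_den = 0
    for p in P:
        ppv_num += max(len(b & p) for b in B)
        ppv_den += sum(len(b & p) for b in B)
    sn = sn_num / sn_den
    ppv = ppv_num / ppv_den if ppv_den else 0.0
    acc = math.sqrt(sn * ppv)
    mmr_val = sum(max(os_(p, b) for p in P) for b in B) / len(B)
    perfect = sum(1 for b in B if any(p == b for p in P))
    return dict(precision=precision, recall=recall, f_measure=f, sn=sn, ppv=ppv,
                acc=acc, mmr=mmr_val, composite=f + acc + mmr_val,
                n_cp=n_cp, n_cb=n_cb, perfect_matches=perfect)


def random_weight_matrix(rng: np.random.Generator, n: int,
                         density: float = 0.2) -> np.ndarray:
    """Symmetric nonnegative matrix with zero diagonal (edge-supported weights)."""
    mask = np.triu(rng.random((n, n)) < density, 1)
    vals = rng.random((n, n))
    S = np.where(mask, vals, 0.0)
    return S + S.T


def random_complex_sets(rng: np.random.Generator, universe: int = 30,
                        max_sets: int = 8) -> tuple[list[set], list[set]]:
    """A random (predicted, reference) pair over a small protein universe."""
    proteins = [f"Y{i:03d}" for i in range(universe)]

    def draw():
        sets = []
        for _ in range(int(rng.integers(1, max_sets + 1))):
            size = int(rng.integers(1, 8))
            sets.append(set(rng.choice(proteins, size=size, replace=False)))
        return sets

    return draw(), draw()


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def path_graph() -> PPINetwork:
    """A-B-C path: the smallest network with distinct neighborhood sizes."""
    return PPINetwork([("A", "B"), ("B", "C")])


@pytest.fixture
def triangle() -> PPINetwork:
    return PPINetwork([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def bridged_double_k4() -> tuple[PPINetwork, list[set]]:
    """Two K4 cliques joined by a single bridge edge, plus the two cliques."""
    left = ["a1", "a2", "a3", "a4"]
    right = ["b1", "b2", "b3", "b4"]
    edges = []
    for group in (left, right):
        edges += [(u, v) for i, u in enumerate(group) for v in group[i + 1:]]
    edges.append(("a1", "b1"))
    return PPINetwork(edges), [set(left), set(right)]


@pytest.fixture
def k6() -> PPINetwork:
    nodes = [f"n{i}" for i in range(6)]
    return PPINetwork([(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]])
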