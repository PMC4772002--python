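"""Shared fixtures and independent oracles for the test suite.

Oracles here deliberately use naive, transparent algorithms (explicit
loops, exact combinatorics) so they stay independent of the package's
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hetvig import CountMatrix, TrioDesign, TruthSpec
from hetvig.simulate import CLASS_LABELS

ALL_CLASSES_EQUAL = {label: 1.0 / len(CLASS_LABELS) for label in CLASS_LABELS}


@pytest.fixture(scope="session")
def small_trio():
    """A small simulated cross covering all classes, shared across tests."""
    from hetvig import simulate_trio_counts

    spec = TruthSpec(
        n_genes=130, classes=ALL_CLASSES_EQUAL, fold_change=4, dispersion=0.01,
        n_reps=3, seed=11,
    )
    return simulate_trio_counts(spec)


@pytest.fixture
def tiny_counts():
    counts = pd.DataFrame(
        [[10, 12, 30, 31, 20, 21], [5, 6, 5, 4, 5, 6], [100, 90, 10, 12, 50, 55]],
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
        columns=["m1", "m2", "p1", "p2", "f1", "f2"],
    )
    return CountMatrix(counts)


@pytest.fixture
def tiny_design():
    return TrioDesign(
        cross_id="c1",
        maternal_samples=("m1", "m2"),
        paternal_samples=("p1", "p2"),
        hybrid_samples=("f1", "f2"),
    )


# ---------------------------------------------------------------- oracles


def bh_reference(p: np.ndarray) -> np.ndarray:
    """Quadratic-time BH step-up: adj_i = min over j with p_j >= p_i of p_j*m/rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def exact_test_oracle(k_a, k_b, sf_a, sf_b, alpha) -> float:
    """Exhaustive-split conditional exact test, computed in linear space."""
    k_a = np.asarray(k_a, dtype=np.int64)
    k_b = np.asarray(k_b, dtype=np.int64)
    sf_a = np.asarray(sf_a, dtype=float)
    sf_b = np.asarray(sf_b, dtype=float)
    ka, kb = int(k_a.sum()), int(k_b.sum())
    total = ka + kb
    if total == 0:
        return 1.0
    q = float(np.mean(np.concatenate([k_a / sf_a, k_b / sf_b])))

    def marginal_pmf(mu_j):
        mu = float(np.sum(mu_j))
        var = float(np.sum(mu_j + alpha * mu_j**2))
        x = np.arange(total + 1)
        if var <= mu * (1 + 1e-12):
            return stats.poisson.pmf(x, mu)
        r = mu * mu / (var - mu)
        return stats.nbinom.pmf(x, r, r / (r + mu))

    pa = marginal_pmf(q * sf_a)
    pb = marginal_pmf(q * sf_b)
    probs = [pa[a] * pb[total - a] for a in range(total + 1)]
    obs = probs[ka]
    num = sum(pr for pr in probs if pr <= obs * (1 + 1e-8))
    return min(num / sum(probs), 1.0)


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """Exact upper-tail hypergeometric by integer combinatorics."""
    denom = math.comb(N, n)
    num = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
        if n - j <= N - K
    )
    return num / denom


def average_linkage_oracle(dist: np.ndarray) -> list[float]:
    """O(n^3) average-linkage agglomeration; returns sorted merge heights."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                a, b = ids[x], ids[y]
                da = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or da < best[0]:
                    best = (da, a, b)
        h, a, b = best
        heights.append(h)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return sorted(heights)
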