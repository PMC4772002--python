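"""Differential expression between two conditions from raw counts.

The statistical family is the classic count-based exact-test workflow:
median-of-ratios size factors, per-gene method-of-moments negative-binomial
dispersion shared conservatively with a mean-dispersion trend, a two-sided
conditional exact test on the group sums, and Benjamini-Hochberg control
of the false discovery rate at an adjusted-p threshold (default 0.05).

The exact test conditions on the pooled total of the two group sums. Each
group sum is modelled as a single negative binomial matched to the summed
per-replicate means (proportional to summed size factors) and the summed
per-replicate variances mu + alpha*mu^2; with alpha = 0 this is the exact
Poisson law and the conditional distribution is binomial. The two-sided
p-value sums the probabilities of all splits of the total that are no more
probable than the observed one (ties included).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .io import CountMatrix, TrioDesign

__all__ = [
    "size_factors_median_ratio",
    "estimate_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "de_test_two_groups",
    "pairwise_trio_de",
]

logger = logging.getLogger(__name__)

#: relative tolerance for probability ties in the two-sided exact test
_TIE_RTOL = 1e-8


def size_factors_median_ratio(m: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization.

    For every gene with nonzero counts in all samples, the ratio of each
    sample's count to the gene's geometric mean is formed; the size factor
    of a sample is the median of these ratios.
    """
    k = m.counts.to_numpy(dtype=float)
    expressed = (k > 0).all(axis=1)
    if not expressed.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "pre-filter the matrix before normalization"
        )
    ke = k[expressed]
    gm = np.exp(np.log(ke).mean(axis=1, keepdims=True))
    sf = np.median(ke / gm, axis=0)
    return pd.Series(sf, index=m.sample_ids, name="size_factor")


@dataclass(frozen=True)
class DispersionEstimate:
    gene_id: str
    alpha: float
    method: str  # "per-gene" or "trend-floored"


def _pooled_moments(
    z: np.ndarray, groups: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Base mean and pooled within-group variance of normalized counts."""
    mu = z.mean(axis=1)
    ss = np.zeros(z.shape[0])
    df = 0
    for idx in groups:
        if len(idx) < 2:
            continue
        zg = z[:, idx]
        ss += ((zg - zg.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += len(idx) - 1
    if df == 0:
        raise ValueError("no group with >= 2 replicates")
    return mu, ss / df


def estimate_dispersion(
    m: CountMatrix,
    groups: Mapping[str, Sequence[str]],
    size_factors: pd.Series,
) -> pd.DataFrame:
    """Per-gene NB dispersion with conservative trend sharing.

    Method-of-moments on normalized counts: with z = k/s, Var(z) is
    approximately mu * mean(1/s) + alpha * mu^2, so the raw estimate is
    (pooled within-group variance - mu * mean(1/s)) / mu^2, floored at
    zero. A parametric trend alpha(mu) = a0 + a1/mu is fitted across
    genes by least squares and each gene's final dispersion is
    max(own estimate, trend value).

    With no group having two replicates the estimate falls back to
    pooling all samples as one group ("blind"), which confounds signal
    with noise and is logged as a warning.
    """
    sf = size_factors.reindex(m.sample_ids).to_numpy(dtype=float)
    z = m.counts.to_numpy(dtype=float) / sf
    col_pos = {s: j for j, s in enumerate(m.sample_ids)}
    idx_groups = [np.array([col_pos[s] for s in ss], dtype=int) for ss in groups.values()]

    try:
        mu, v = _pooled_moments(z, idx_groups)
    except ValueError:
        logger.warning(
            "no group with >= 2 replicates; falling back to blind dispersion "
            "estimation across all samples"
        )
        mu, v = _pooled_moments(z, [np.arange(z.shape[1])])

    xi = float(np.mean(1.0 / sf))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (v - mu * xi) / np.maximum(mu, 1e-300) ** 2, 0.0)
    raw = np.maximum(raw, 0.0)

    # parametric trend a0 + a1/mu, nonnegative coefficients
    ok = mu > 0
    if ok.sum() >= 2 and np.unique(mu[ok]).size >= 2:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        a0, a1 = np.maximum(coef, 0.0)
    else:
        a0, a1 = (float(raw[ok].mean()) if ok.any() else 0.0), 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(ok, a0 + a1 / np.maximum(mu, 1e-300), 0.0)

    alpha = np.maximum(raw, trend)
    method = np.where(raw >= trend, "per-gene", "trend-floored")
    return pd.DataFrame(
        {"alpha": alpha, "alpha_gene": raw, "base_mean": mu, "method": method},
        index=m.gene_ids,
    )


def _group_sum_logpmf(total: int, mu: float, var: float) -> np.ndarray:
    """log pmf of one group's sum on support 0..total.

    NB matched to (mu, var); Poisson when var <= mu (alpha = 0 limit).
    """
    x = np.arange(total + 1)
    if var <= mu * (1 + 1e-12):
        return stats.poisson.logpmf(x, mu)
    r = mu * mu / (var - mu)
    return stats.nbinom.logpmf(x, r, r / (r + mu))


def nb_exact_test(
    k_a: Sequence[int],
    k_b: Sequence[int],
    sf_a: Sequence[float],
    sf_b: Sequence[float],
    alpha: float,
) -> float:
    """Two-sided conditional exact test of equal normalized means.

    Conditions on the pooled total S = sum(k_a) + sum(k_b); sums over all
    splits (a, S - a) whose joint probability does not exceed the observed
    split's, under group-sum NB laws whose means are proportional to the
    summed size factors. Returns p in (0, 1]. An all-zero gene returns 1
    by convention.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    k_a = np.asarray(k_a, dtype=np.int64)
    k_b = np.asarray(k_b, dtype=np.int64)
    sfa = np.asarray(sf_a, dtype=float)
    sfb = np.asarray(sf_b, dtype=float)
    ka, kb = int(k_a.sum()), int(k_b.sum())
    total = ka + kb
    if total == 0:
        return 1.0

    # common normalized mean under the null
    q = float(np.concatenate([k_a / sfa, k_b / sfb]).mean())
    mu_ja, mu_jb = q * sfa, q * sfb
    mu_a, var_a = float(mu_ja.sum()), float((mu_ja + alpha * mu_ja**2).sum())
    mu_b, var_b = float(mu_jb.sum()), float((mu_jb + alpha * mu_jb**2).sum())

    logp = _group_sum_logpmf(total, mu_a, var_a) + _group_sum_logpmf(total, mu_b, var_b)[::-1]
    obs = logp[ka]
    denom = logsumexp(logp)
    keep = logp <= obs + np.log1p(_TIE_RTOL)
    p = float(np.exp(logsumexp(logp[keep]) - denom))
    return min(p, 1.0)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def de_test_two_groups(
    m: CountMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    size_factors: pd.Series | None = None,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Exact-test DE table for group B relative to group A.

    Returns one row per gene with normalized means, log2 fold change
    (b over a), raw and BH-adjusted p-values, and a call in {up, down, ns}
    at adjusted p < ``threshold``.
    """
    if size_factors is None:
        size_factors = size_factors_median_ratio(m)
    sfa = size_factors.reindex(list(samples_a)).to_numpy(dtype=float)
    sfb = size_factors.reindex(list(samples_b)).to_numpy(dtype=float)
    ka = m.counts.loc[:, list(samples_a)].to_numpy()
    kb = m.counts.loc[:, list(samples_b)].to_numpy()

    sub = m.subset_samples(list(samples_a) + list(samples_b))
    disp = estimate_dispersion(
        sub,
        {"a": list(samples_a), "b": list(samples_b)},
        size_factors.reindex(sub.sample_ids),
    )

    n = m.shape[0]
    pvals = np.empty(n)
    for i in range(n):
        pvals[i] = nb_exact_test(ka[i], kb[i], sfa, sfb, float(disp["alpha"].iloc[i]))

    mean_a = (ka / sfa).mean(axis=1)
    mean_b = (kb / sfb).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_b / mean_a)
    padj = bh_adjust(pvals)
    call = np.where(
        (padj < threshold) & (mean_b > mean_a),
        "up",
        np.where((padj < threshold) & (mean_b < mean_a), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "call": call,
        },
        index=m.gene_ids,
    )


def pairwise_trio_de(
    m: CountMatrix, d: TrioDesign, threshold: float = 0.05
) -> dict[str, pd.DataFrame]:
    """The three pairwise DE tables of one cross.

    Keys: ``f_vs_m`` (hybrid over maternal), ``f_vs_p`` (hybrid over
    paternal), ``p_vs_m`` (paternal over maternal). BH adjustment is
    applied within each comparison separately; size factors come from the
    full trio matrix.
    """
    d.validate_against(m)
    trio = m.subset_samples(list(d.all_samples))
    sf = size_factors_median_ratio(trio)
    pairs = {
        "f_vs_m": (d.maternal_samples, d.hybrid_samples),
        "f_vs_p": (d.paternal_samples, d.hybrid_samples),
        "p_vs_m": (d.maternal_samples, d.paternal_samples),
    }
    return {
        name: de_test_two_groups(trio, a, b, size_factors=sf, threshold=threshold)
        for name, (a, b) in pairs.items()
    }
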