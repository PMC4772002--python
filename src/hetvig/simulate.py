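"""Synthetic parent-parent-hybrid count data with known expression-class truth.

The generator emulates the design of a three-line inbred cross experiment:
for each cross, a maternal line, a paternal line and their F1 hybrid are
sequenced with a small number of biological replicates, and each gene
belongs to one of twelve expression classes (or is non-differential).
The class fixes the geometry of the three true means:

========  =========================  =====================================
category  classes                    hybrid mean
========  =========================  =====================================
additive  1 (m<p), 12 (m>p)          arithmetic mid-point of the parents
ELD-male  2 (p>m), 11 (p<m)          equal to the paternal mean
ELD-fem.  4 (m>p), 9 (m<p)           equal to the maternal mean
up        3 (m<p), 7 (m=p), 10 (m>p) fold_change x max(parents)
down      6 (m<p), 8 (m=p), 5 (m>p)  min(parents) / fold_change
========  =========================  =====================================

Counts are negative-binomial with variance mu + alpha*mu^2 around
size-factor-scaled true means; alpha = 0 falls back to Poisson. One
integer seed drives everything; per-gene sub-streams are derived
deterministically so output does not depend on gene order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CountMatrix, TrioDesign

__all__ = [
    "TruthSpec",
    "SyntheticTruth",
    "CLASS_LABELS",
    "CLASS_CATEGORY",
    "class_means",
    "simulate_trio_counts",
    "simulate_multi_cross",
    "simulate_body_weights",
    "make_annotation_fixture",
]

CLASS_LABELS = tuple(str(c) for c in range(1, 13)) + ("nonDEG",)

#: category of each true class, matching the classifier's vocabulary
CLASS_CATEGORY = {
    "1": "additive",
    "12": "additive",
    "2": "ELD-paternal-high",
    "11": "ELD-paternal-low",
    "4": "ELD-maternal-high",
    "9": "ELD-maternal-low",
    "3": "transgressive-up",
    "7": "transgressive-up",
    "10": "transgressive-up",
    "5": "transgressive-down",
    "6": "transgressive-down",
    "8": "transgressive-down",
    "nonDEG": "nonDEG",
}


def class_means(label: str, base_mean: float, fold_change: float) -> tuple[float, float, float]:
    """True (maternal, hybrid, paternal) means for one expression class.

    ``base_mean`` is the lower parental level; parents that differ do so
    by exactly ``fold_change``. Transgressive-up hybrids sit at
    fold_change x max(parents); transgressive-down at min(parents) /
    fold_change, keeping all means positive.
    """
    b, fc = float(base_mean), float(fold_change)
    lo, hi = b, b * fc
    table = {
        "nonDEG": (b, b, b),
        "1": (lo, (lo + hi) / 2, hi),
        "12": (hi, (lo + hi) / 2, lo),
        "2": (lo, hi, hi),
        "11": (hi, lo, lo),
        "4": (hi, hi, lo),
        "9": (lo, lo, hi),
        "3": (lo, fc * hi, hi),
        "7": (b, fc * b, b),
        "10": (hi, fc * hi, lo),
        "6": (lo, lo / fc, hi),
        "8": (b, b / fc, b),
        "5": (hi, lo / fc, lo),
    }
    if label not in table:
        raise ValueError(f"unknown expression class label {label!r}")
    return table[label]


@dataclass(frozen=True)
class TruthSpec:
    """Parameters of one synthetic cross.

    classes maps class label ('1'..'12' or 'nonDEG') to the proportion of
    genes in that class; proportions must sum to one. dispersion is the
    NB overdispersion alpha (variance = mu + alpha*mu^2).
    """

    n_genes: int
    classes: Mapping[str, float]
    base_mean: float = 200.0
    fold_change: float = 4.0
    dispersion: float = 0.01
    n_reps: int = 2
    size_factor_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for label in self.classes:
            if label not in CLASS_LABELS:
                raise ValueError(f"invalid class label in proportions: {label!r}")
        for label, p in self.classes.items():
            if p < 0:
                raise ValueError(f"negative proportion for class {label!r}")
        total = float(sum(self.classes.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total!r}, expected 1")
        if self.base_mean <= 0:
            raise ValueError("base_mean must be positive")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValueError("size_factor_range must be positive and ordered")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a simulated cross.

    ``table`` holds one row per gene: true class label and the true
    (maternal, hybrid, paternal) means in normalized units.
    ``size_factors`` holds the true per-sample scaling constants.
    """

    table: pd.DataFrame
    size_factors: pd.Series = field(repr=False)

    def classes(self) -> pd.Series:
        return self.table["class"]

    def categories(self) -> pd.Series:
        return self.table["class"].map(CLASS_CATEGORY).rename("category")


def _assign_classes(spec: TruthSpec) -> list[str]:
    """Deterministic largest-remainder allocation of genes to classes."""
    labels = [l for l in CLASS_LABELS if spec.classes.get(l, 0) > 0]
    raw = np.array([spec.classes[l] * spec.n_genes for l in labels])
    counts = np.floor(raw).astype(int)
    short = spec.n_genes - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(short):
        counts[order[i % len(labels)]] += 1
    out: list[str] = []
    for label, c in zip(labels, counts):
        out.extend([label] * c)
    return out[: spec.n_genes]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if alpha == 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


def simulate_trio_counts(
    spec: TruthSpec, cross_id: str = "cross1", _cross_index: int = 0
) -> tuple[CountMatrix, TrioDesign, SyntheticTruth]:
    """Simulate one cross: counts, design and ground truth.

    Sample columns are ordered maternal, paternal, hybrid with ``n_reps``
    replicates each. The same spec (same seed) reproduces the output
    exactly.
    """
    labels = _assign_classes(spec)
    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]

    root = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919, _cross_index]))
    n_samples = 3 * spec.n_reps
    lo, hi = spec.size_factor_range
    sf = root.uniform(lo, hi, size=n_samples)

    prefix = f"{cross_id}_"
    sample_ids = (
        [f"{prefix}m{r+1}" for r in range(spec.n_reps)]
        + [f"{prefix}p{r+1}" for r in range(spec.n_reps)]
        + [f"{prefix}f1_{r+1}" for r in range(spec.n_reps)]
    )
    design = TrioDesign(
        cross_id=cross_id,
        maternal_samples=tuple(sample_ids[: spec.n_reps]),
        paternal_samples=tuple(sample_ids[spec.n_reps : 2 * spec.n_reps]),
        hybrid_samples=tuple(sample_ids[2 * spec.n_reps :]),
    )

    mat = np.empty((spec.n_genes, n_samples), dtype=np.int64)
    mu_rows = np.empty((spec.n_genes, 3))
    for i, label in enumerate(labels):
        mu_m, mu_f, mu_p = class_means(label, spec.base_mean, spec.fold_change)
        mu_rows[i] = (mu_m, mu_f, mu_p)
        line_mu = np.repeat([mu_m, mu_p, mu_f], spec.n_reps)
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _cross_index, i]))
        mat[i] = _nb_draw(rng, sf * line_mu, spec.dispersion)

    counts = CountMatrix(
        pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    )
    truth_table = pd.DataFrame(
        {
            "class": labels,
            "mu_m": mu_rows[:, 0],
            "mu_f1": mu_rows[:, 1],
            "mu_p": mu_rows[:, 2],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth = SyntheticTruth(
        table=truth_table, size_factors=pd.Series(sf, index=sample_ids, name="size_factor")
    )
    return counts, design, truth


def simulate_multi_cross(
    spec: TruthSpec, n_crosses: int = 3
) -> list[tuple[CountMatrix, TrioDesign, SyntheticTruth]]:
    """Simulate several crosses sharing the same per-gene class assignment.

    Count noise and size factors are independent between crosses, so a
    gene's class is common to all crosses in truth but must be recovered
    from each cross's data separately — the setting in which a common
    dominance set is meaningful.
    """
    if n_crosses < 1:
        raise ValueError("n_crosses must be >= 1")
    return [
        simulate_trio_counts(spec, cross_id=f"cross{c+1}", _cross_index=c)
        for c in range(n_crosses)
    ]


def simulate_body_weights(
    mu_m: float, mu_p: float, mu_f1: float, sd: float, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normal body-weight samples for maternal line, paternal line and F1.

    Returns three vectors of length ``n``; their sample means converge to
    the specified true means. ``n`` must be at least 2 so a standard
    error is defined.
    """
    if n < 2:
        raise ValueError("need n >= 2 to define a standard error")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    m = rng.normal(mu_m, sd, size=n)
    p = rng.normal(mu_p, sd, size=n)
    f1 = rng.normal(mu_f1, sd, size=n)
    return m, p, f1


def make_annotation_fixture(
    n_genes: int,
    n_terms: int,
    genes_per_term: int,
    length_range: tuple[int, int],
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reproducible gene-length table and term -> gene annotation map.

    Stands in for GO/KEGG-style databases in a fully synthetic analysis:
    lengths are uniform over ``length_range`` (bp) and each term annotates
    ``genes_per_term`` distinct genes chosen at random.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if n_terms < 0:
        raise ValueError("n_terms must be nonnegative")
    if n_terms > 0 and not (1 <= genes_per_term <= n_genes):
        raise ValueError("genes_per_term must be in [1, n_genes]")
    lo, hi = length_range
    if not (0 < lo <= hi):
        raise ValueError(f"empty or invalid length range {length_range!r}")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 15485863]))
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    lengths = pd.DataFrame(
        {"gene_id": gene_ids, "length_bp": rng.integers(lo, hi + 1, size=n_genes)}
    )
    rows = []
    for t in range(n_terms):
        members = rng.choice(n_genes, size=genes_per_term, replace=False)
        for g in sorted(members):
            rows.append((f"T{t:04d}", gene_ids[g]))
    annotation = pd.DataFrame(rows, columns=["term_id", "gene_id"])
    return lengths, annotation
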