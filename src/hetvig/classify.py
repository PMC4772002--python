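"""Expression-pattern classification of hybrid/parent trios.

Each gene carries three pairwise DE calls — hybrid vs maternal (c_fm),
hybrid vs paternal (c_fp) and paternal vs maternal (c_mp), each in
{up, down, ns} with "up" meaning the second-named member is higher —
plus the three normalized means. The decision table maps every such
combination to exactly one of twelve classes or to nonDEG / conflicting:

* additive (classes 1, 12): all three comparisons significant and the
  hybrid strictly between the parents;
* expression-level dominance toward the paternal parent (2 high, 11 low):
  hybrid indistinguishable from the paternal line while the parents differ;
* dominance toward the maternal parent (4 high, 9 low): mirror image;
* transgressive up (3, 7, 10): hybrid significantly above both parents;
* transgressive down (6, 8, 5): hybrid significantly below both parents;
* any remaining combination is flagged conflicting.

Genes with zero counts across all replicates of at least one line are
set aside before classification (no within-line signal exists for them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import CountMatrix, ExpressionMatrix, TrioDesign

__all__ = [
    "TrioCalls",
    "PatternClass",
    "CATEGORY_OF_CLASS",
    "DOMINANCE_CLASSES",
    "exclude_zero_genes",
    "classify_gene",
    "classify_all",
    "venn_counts",
    "common_dominance_set",
    "hier_cluster",
]

Call = Literal["up", "down", "ns"]

CATEGORY_OF_CLASS = {
    "1": "additive",
    "12": "additive",
    "2": "ELD-paternal-high",
    "11": "ELD-paternal-low",
    "4": "ELD-maternal-high",
    "9": "ELD-maternal-low",
    "3": "transgressive-up",
    "7": "transgressive-up",
    "10": "transgressive-up",
    "6": "transgressive-down",
    "8": "transgressive-down",
    "5": "transgressive-down",
    "nonDEG": "nonDEG",
    "excluded": "excluded",
    "conflicting": "conflicting",
}

DOMINANCE_CLASSES = frozenset({"2", "4", "9", "11"})


@dataclass(frozen=True)
class TrioCalls:
    gene_id: str
    c_fm: Call
    c_fp: Call
    c_mp: Call
    mu_m: float
    mu_f: float
    mu_p: float


@dataclass(frozen=True)
class PatternClass:
    gene_id: str
    class_id: str
    category: str


def classify_gene(t: TrioCalls) -> PatternClass:
    """Map one gene's trio of calls (and means) to its expression class.

    Total and deterministic over all 27 call combinations and mean
    orderings; betweenness for the additive classes is checked on the
    means themselves.
    """
    fm, fp, mp = t.c_fm, t.c_fp, t.c_mp
    if fm == fp == mp == "ns":
        cls = "nonDEG"
    elif fm == "up" and fp == "up":
        cls = {"up": "3", "ns": "7", "down": "10"}[mp]
    elif fm == "down" and fp == "down":
        cls = {"up": "6", "ns": "8", "down": "5"}[mp]
    elif fp == "ns" and fm != "ns" and mp != "ns":
        cls = "2" if mp == "up" else "11"
    elif fm == "ns" and fp != "ns" and mp != "ns":
        cls = "4" if mp == "down" else "9"
    elif fm != "ns" and fp != "ns" and mp != "ns":
        # opposite-direction hybrid calls: additive if strictly between
        lo, hi = min(t.mu_m, t.mu_p), max(t.mu_m, t.mu_p)
        if lo < t.mu_f < hi:
            cls = "1" if mp == "up" else "12"
        else:
            cls = "conflicting"
    else:
        cls = "conflicting"
    return PatternClass(gene_id=t.gene_id, class_id=cls, category=CATEGORY_OF_CLASS[cls])


def exclude_zero_genes(m: CountMatrix, d: TrioDesign, rule: str = "line") -> set[str]:
    """Genes with no reads, to be set aside before classification.

    ``rule='line'`` (default): zero across all replicates of at least one
    line of the cross. ``rule='any'``: zero in any single sample.
    """
    d.validate_against(m)
    if rule == "line":
        zero = np.zeros(m.shape[0], dtype=bool)
        for samples in (d.maternal_samples, d.paternal_samples, d.hybrid_samples):
            zero |= (m.counts.loc[:, list(samples)] == 0).all(axis=1).to_numpy()
    elif rule == "any":
        zero = (m.counts.loc[:, list(d.all_samples)] == 0).any(axis=1).to_numpy()
    else:
        raise ValueError(f"unknown zero-exclusion rule {rule!r}")
    return set(m.gene_ids[zero])


def classify_all(
    de_tables: Mapping[str, pd.DataFrame],
    m: CountMatrix,
    d: TrioDesign,
    zero_rule: str = "line",
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every gene of one cross and summarize category proportions.

    ``de_tables`` must hold the three tables of :func:`pairwise_trio_de`
    (keys f_vs_m, f_vs_p, p_vs_m) over the same gene universe as ``m``.
    The DEG set is every gene significant in at least one comparison,
    minus the zero-excluded genes; proportions are over DEGs and sum to 1
    (an empty DEG set yields an empty, all-NaN summary).
    """
    required = {"f_vs_m", "f_vs_p", "p_vs_m"}
    if set(de_tables) != required:
        raise ValueError(f"expected DE tables {sorted(required)}, got {sorted(de_tables)}")
    fm, fp, pm = de_tables["f_vs_m"], de_tables["f_vs_p"], de_tables["p_vs_m"]
    for name, tab in de_tables.items():
        if not tab.index.equals(m.gene_ids):
            raise ValueError(f"gene universe of table {name!r} does not match the counts")

    excluded = exclude_zero_genes(m, d, rule=zero_rule)
    rows = []
    for g in m.gene_ids:
        if g in excluded:
            rows.append(("excluded", "excluded", np.nan, np.nan, np.nan, "ns", "ns", "ns"))
            continue
        t = TrioCalls(
            gene_id=g,
            c_fm=fm.at[g, "call"],
            c_fp=fp.at[g, "call"],
            c_mp=pm.at[g, "call"],
            mu_m=fm.at[g, "mean_a"],
            mu_f=fm.at[g, "mean_b"],
            mu_p=fp.at[g, "mean_a"],
        )
        pc = classify_gene(t)
        rows.append((pc.class_id, pc.category, t.mu_m, t.mu_f, t.mu_p, t.c_fm, t.c_fp, t.c_mp))
    table = pd.DataFrame(
        rows,
        index=m.gene_ids,
        columns=["class", "category", "mu_m", "mu_f1", "mu_p", "c_fm", "c_fp", "c_mp"],
    )

    deg = table.loc[~table["category"].isin(["nonDEG", "excluded"])]
    if len(deg) == 0:
        proportions = pd.Series(dtype=float, name="proportion")
    else:
        proportions = (
            deg["category"].value_counts(normalize=True).rename("proportion").sort_index()
        )
    return table, proportions


def venn_counts(set_a: Iterable[str], set_b: Iterable[str]) -> tuple[int, int, int]:
    """(only in A, in both, only in B) for two DEG sets."""
    a, b = set(set_a), set(set_b)
    return len(a - b), len(a & b), len(b - a)


def common_dominance_set(class_tables: Sequence[pd.DataFrame]) -> set[str]:
    """Genes in a dominance class (2, 4, 9, 11) in every provided cross."""
    if not class_tables:
        raise ValueError("need at least one classification table")
    sets = [
        set(tab.index[tab["class"].isin(DOMINANCE_CLASSES)]) for tab in class_tables
    ]
    return set.intersection(*sets)


def hier_cluster(e: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of samples on 1 - Pearson correlation.

    Returns the scipy linkage matrix and the deterministic leaf order
    (samples are sorted by identifier before clustering so ties break
    reproducibly). A sample with zero variance has no defined correlation
    and is rejected.
    """
    if e.values.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    order = sorted(e.sample_ids)
    x = e.values.loc[:, order].to_numpy(dtype=float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = [order[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant expression in samples {bad}; correlation undefined")
    corr = np.corrcoef(x, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(z)
    return z, [order[i] for i in leaves]
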