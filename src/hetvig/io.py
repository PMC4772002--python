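"""Tabular I/O for the pipeline and per-gene expression summaries.

All on-disk formats are plain TSV with a header row, UTF-8, no quoting.
``NA`` is forbidden in count matrices: readers reject rather than coerce
malformed input so that a round-trip (write then read) is bit-exact.
Paths may point at plain files or gzip-compressed files (pandas sniffs
the compression from the filename).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "TrioDesign",
    "ExpressionMatrix",
    "read_counts",
    "write_counts",
    "compute_rpkm",
    "read_sample_sheet",
    "read_gene_lengths",
    "read_annotation_map",
    "read_phenotypes",
]

ROLES = ("maternal", "paternal", "hybrid")


@dataclass(frozen=True)
class CountMatrix:
    """Integer gene x sample expression counts.

    ``counts`` is a genes-by-samples DataFrame whose index holds gene
    identifiers and whose columns hold sample identifiers. Identifiers
    must be unique and every entry a non-negative integer.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        if not all(np.issubdtype(dt, np.integer) for dt in df.dtypes):
            bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.integer)]
            raise ValueError(f"non-integer counts in columns: {bad[:5]}")
        if (df.to_numpy() < 0).any():
            rows = df.index[(df.to_numpy() < 0).any(axis=1)].tolist()
            raise ValueError(f"negative counts at genes: {rows[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        missing = [s for s in samples if s not in self.counts.columns]
        if missing:
            raise KeyError(f"samples not in count matrix: {missing}")
        return CountMatrix(self.counts.loc[:, list(samples)])


@dataclass(frozen=True)
class TrioDesign:
    """Sample assignment for one cross: maternal line, paternal line, F1 hybrid."""

    cross_id: str
    maternal_samples: tuple[str, ...]
    paternal_samples: tuple[str, ...]
    hybrid_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = {
            "maternal": set(self.maternal_samples),
            "paternal": set(self.paternal_samples),
            "hybrid": set(self.hybrid_samples),
        }
        for role, s in sets.items():
            if not s:
                raise ValueError(f"cross {self.cross_id}: no {role} samples")
        roles = list(sets)
        for i, a in enumerate(roles):
            for b in roles[i + 1 :]:
                overlap = sets[a] & sets[b]
                if overlap:
                    raise ValueError(
                        f"cross {self.cross_id}: samples {sorted(overlap)} "
                        f"assigned to both {a} and {b}"
                    )

    @property
    def all_samples(self) -> tuple[str, ...]:
        return self.maternal_samples + self.paternal_samples + self.hybrid_samples

    def validate_against(self, m: CountMatrix) -> None:
        missing = [s for s in self.all_samples if s not in m.sample_ids]
        if missing:
            raise ValueError(
                f"cross {self.cross_id}: samples {missing} absent from count matrix"
            )


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized expression values (RPKM) with their provenance.

    ``values[i, j] = counts[i, j] * 1e9 / (totals[j] * lengths[i])`` —
    reads per kilobase of gene model per million mapped reads. A value
    is zero exactly when the underlying count is zero.
    """

    values: pd.DataFrame
    lengths: pd.Series = field(repr=False)
    totals: pd.Series = field(repr=False)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV (first column ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a gene_id column plus at least one sample")
    gene_col = df.columns[0]
    genes = df[gene_col]
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated gene row {dup!r}")
    body = df.drop(columns=gene_col)
    if body.isna().any().any():
        r, c = np.argwhere(body.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at gene {genes.iloc[r]!r}, sample {body.columns[c]!r}"
        )
    mat = np.empty(body.shape, dtype=np.int64)
    for j, col in enumerate(body.columns):
        try:
            vals = body[col].astype(np.int64)
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}: non-integer count in column {col!r}: {err}") from None
        # reject floats masquerading as ints only if they truly differ
        as_float = body[col].astype(float)
        if not np.array_equal(as_float, vals.astype(float)):
            raise ValueError(f"{path}: non-integral count in column {col!r}")
        mat[:, j] = vals
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=body.columns)
    return CountMatrix(counts)


def write_counts(m: CountMatrix, path: str | Path) -> None:
    df = m.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def compute_rpkm(
    m: CountMatrix,
    lengths: Mapping[str, float] | pd.Series,
    totals: Mapping[str, float] | pd.Series | None = None,
) -> ExpressionMatrix:
    """Compute RPKM from raw counts, gene lengths (bp) and per-sample totals.

    When ``totals`` is omitted the column sums of the count matrix are
    used as the per-sample mapped-read totals.
    """
    lengths = pd.Series(lengths, dtype=float)
    missing = m.gene_ids.difference(lengths.index)
    if len(missing):
        raise KeyError(f"no length for genes: {missing[:5].tolist()}")
    L = lengths.reindex(m.gene_ids)
    if (L <= 0).any():
        bad = L.index[L <= 0].tolist()
        raise ValueError(f"non-positive gene length for: {bad[:5]}")

    if totals is None:
        N = m.counts.sum(axis=0).astype(float)
    else:
        N = pd.Series(totals, dtype=float)
        missing = m.sample_ids.difference(N.index)
        if len(missing):
            raise KeyError(f"no read total for samples: {missing[:5].tolist()}")
        N = N.reindex(m.sample_ids)
    if (N <= 0).any():
        bad = N.index[N <= 0].tolist()
        raise ValueError(f"non-positive read total for samples: {bad[:5]}")

    vals = m.counts.to_numpy(dtype=float) * 1e9 / np.outer(L.to_numpy(), N.to_numpy())
    values = pd.DataFrame(vals, index=m.gene_ids, columns=m.sample_ids)
    return ExpressionMatrix(values=values, lengths=L, totals=N)


def read_sample_sheet(path: str | Path) -> list[TrioDesign]:
    """Read a sample sheet (``sample_id  line  role  cross``) into TrioDesigns.

    Roles must be one of maternal / paternal / hybrid; a sample may appear
    in several crosses (parental lines are shared between crosses) but only
    once per cross.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "line", "role", "cross"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: sample sheet needs columns {sorted(required)}")
    bad_roles = sorted(set(df["role"]) - set(ROLES))
    if bad_roles:
        raise ValueError(f"{path}: unknown roles {bad_roles}; expected one of {ROLES}")
    designs = []
    for cross_id, grp in df.groupby("cross", sort=True):
        if grp["sample_id"].duplicated().any():
            dup = grp["sample_id"][grp["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"{path}: sample {dup!r} assigned twice in cross {cross_id!r}")
        by_role = {r: tuple(grp.loc[grp["role"] == r, "sample_id"]) for r in ROLES}
        designs.append(
            TrioDesign(
                cross_id=str(cross_id),
                maternal_samples=by_role["maternal"],
                paternal_samples=by_role["paternal"],
                hybrid_samples=by_role["hybrid"],
            )
        )
    return designs


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Read a ``gene_id  length_bp`` TSV into a Series."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "length_bp"}.issubset(df.columns):
        raise ValueError(f"{path}: need columns gene_id, length_bp")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated gene {dup!r}")
    s = df.set_index("gene_id")["length_bp"].astype(float)
    if (s <= 0).any():
        raise ValueError(f"{path}: non-positive lengths present")
    return s


def read_annotation_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column ``term_id  gene_id`` TSV into term -> gene-set."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"term_id", "gene_id"}.issubset(df.columns):
        raise ValueError(f"{path}: need columns term_id, gene_id")
    out: dict[str, set[str]] = {}
    for term, grp in df.groupby("term_id", sort=True):
        out[str(term)] = set(grp["gene_id"])
    return out


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype summary TSV (``line_id  mean  se  n``)."""
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str})
    required = {"line_id", "mean", "se", "n"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return df.set_index("line_id")
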