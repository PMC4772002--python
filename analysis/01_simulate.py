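#!/usr/bin/env python
"""Generate the synthetic three-cross dataset used by the downstream stages.

Three crosses share one per-gene class assignment (1200 genes, equal mass
on the twelve expression classes plus nonDEG) but have independent count
noise: fold change 4, NB dispersion 0.01, 3 replicates per line. Also
writes the gene-length table and the term->gene annotation fixture used
by the enrichment stage.

Outputs under results/data/.
"""

from pathlib import Path

import pandas as pd

from hetvig import CountMatrix, TruthSpec, make_annotation_fixture, simulate_multi_cross
from hetvig.simulate import CLASS_LABELS

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = TruthSpec(
        n_genes=1200,
        classes={label: 1.0 / len(CLASS_LABELS) for label in CLASS_LABELS},
        base_mean=200, fold_change=4, dispersion=0.01, n_reps=3, seed=SEED,
    )
    crosses = simulate_multi_cross(spec, n_crosses=3)

    combined = pd.concat([m.counts for m, _, _ in crosses], axis=1)
    CountMatrix(combined).counts.to_csv(OUT / "counts.tsv", sep="\t")

    sheet_rows = []
    for m, d, truth in crosses:
        for role, samples in [("maternal", d.maternal_samples),
                              ("paternal", d.paternal_samples),
                              ("hybrid", d.hybrid_samples)]:
            for s in samples:
                sheet_rows.append((s, f"{d.cross_id}_{role[0]}", role, d.cross_id))
        truth.table.to_csv(OUT / f"truth_{d.cross_id}.tsv", sep="\t")
    pd.DataFrame(sheet_rows, columns=["sample_id", "line", "role", "cross"]).to_csv(
        OUT / "samples.tsv", sep="\t", index=False
    )

    lengths, annotation = make_annotation_fixture(
        n_genes=spec.n_genes, n_terms=50, genes_per_term=20,
        length_range=(300, 8000), seed=SEED,
    )
    lengths.to_csv(OUT / "gene_lengths.tsv", sep="\t", index=False)
    annotation.to_csv(OUT / "annotation.tsv", sep="\t", index=False)

    print(f"simulated {spec.n_genes} genes x {combined.shape[1]} samples "
          f"(3 crosses, {spec.n_reps} replicates per line) -> {OUT}")
    print(f"true class counts:\n{crosses[0][2].table['class'].value_counts().sort_index()}")


if __name__ == "__main__":
    main()
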