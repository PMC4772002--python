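#!/usr/bin/env python
"""Length-bias-aware enrichment of each cross's dominance gene set.

Tests every annotation term for over-representation among the genes in a
dominance class (2, 4, 9, 11), correcting for gene-length selection bias
via the probability weighting function and the Wallenius noncentral
hypergeometric tail; BH across terms at adjusted p < 0.05. Because the
annotation fixture assigns terms independently of expression class, the
expected number of flagged terms is near zero — this stage demonstrates
calibration, not discovery. Writes results/enrichment/.
"""

from pathlib import Path

import pandas as pd

from hetvig import enrich_terms, read_annotation_map, read_gene_lengths
from hetvig.classify import DOMINANCE_CLASSES

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "enrichment"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    lengths = read_gene_lengths(BASE / "data" / "gene_lengths.tsv")
    annotation = read_annotation_map(BASE / "data" / "annotation.tsv")

    for path in sorted((BASE / "classification").glob("classes_*.tsv")):
        cross_id = path.stem.removeprefix("classes_")
        table = pd.read_csv(path, sep="\t", index_col=0)
        dominance = set(table.index[table["class"].astype(str).isin(DOMINANCE_CLASSES)])
        background = set(table.index[table["category"] != "excluded"])
        res = enrich_terms(
            annotation, dominance, background,
            lengths=lengths, method="wallenius", threshold=0.05,
        )
        res.to_csv(OUT / f"{cross_id}.tsv", sep="\t", float_format="%.10g")
        print(f"{cross_id}: {len(dominance)} dominance genes, "
              f"{int(res['flag'].sum())} of {len(res)} terms flagged "
              f"(min padj {res['padj'].min():.3f})")


if __name__ == "__main__":
    main()
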