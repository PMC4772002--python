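#!/usr/bin/env python
"""Pairwise differential expression for each cross.

For every cross: hybrid vs maternal, hybrid vs paternal and paternal vs
maternal, using median-of-ratios size factors, the NB conditional exact
test and BH adjustment at padj < 0.05. Writes one DE table per comparison
under results/de/ and prints the number of significant genes.
"""

from pathlib import Path

from hetvig import pairwise_trio_de, read_counts, read_sample_sheet

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "de"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    m = read_counts(BASE / "data" / "counts.tsv")
    designs = read_sample_sheet(BASE / "data" / "samples.tsv")

    for d in designs:
        trio = m.subset_samples(list(d.all_samples))
        tables = pairwise_trio_de(trio, d, threshold=0.05)
        for name, tab in tables.items():
            tab.to_csv(OUT / f"{d.cross_id}_{name}.tsv", sep="\t",
                       float_format="%.10g")
        calls = {name: int((tab["call"] != "ns").sum())
                 for name, tab in tables.items()}
        print(f"{d.cross_id}: significant genes per comparison {calls}")


if __name__ == "__main__":
    main()
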