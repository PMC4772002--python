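#!/usr/bin/env python
"""Expression-pattern classification, set algebra and sample clustering.

Maps each gene's trio of DE calls to its expression class per cross,
summarizes category proportions over DEGs, computes the venn partition of
the two hybrid-vs-parent DEG sets, the common dominance set across all
crosses, the recovery rate against the simulated truth, and the
average-linkage sample dendrogram on RPKM. Writes results/classification/.
"""

import json
from pathlib import Path

import pandas as pd

from hetvig import (
    classify_all,
    common_dominance_set,
    compute_rpkm,
    hier_cluster,
    read_counts,
    read_gene_lengths,
    read_sample_sheet,
    venn_counts,
)
from hetvig.simulate import CLASS_CATEGORY

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "classification"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    m = read_counts(BASE / "data" / "counts.tsv")
    designs = read_sample_sheet(BASE / "data" / "samples.tsv")
    lengths = read_gene_lengths(BASE / "data" / "gene_lengths.tsv")

    summary = {}
    class_tables = []
    for d in designs:
        trio = m.subset_samples(list(d.all_samples))
        de = {
            name: pd.read_csv(BASE / "de" / f"{d.cross_id}_{name}.tsv",
                              sep="\t", index_col=0)
            for name in ("f_vs_m", "f_vs_p", "p_vs_m")
        }
        table, props = classify_all(de, trio, d)
        class_tables.append(table)
        table.to_csv(OUT / f"classes_{d.cross_id}.tsv", sep="\t",
                     float_format="%.10g")

        truth = pd.read_csv(BASE / "data" / f"truth_{d.cross_id}.tsv",
                            sep="\t", index_col=0)
        recovery = float((table["category"] == truth["class"].astype(str)
                          .map(CLASS_CATEGORY)).mean())

        fm_deg = set(table.index[table["c_fm"] != "ns"])
        fp_deg = set(table.index[table["c_fp"] != "ns"])
        only_m, both, only_p = venn_counts(fm_deg, fp_deg)

        rpkm = compute_rpkm(trio, lengths)
        _, leaf_order = hier_cluster(rpkm)

        n_deg = int((~table["category"].isin(["nonDEG", "excluded"])).sum())
        summary[d.cross_id] = {
            "n_deg": n_deg,
            "category_proportions": {k: round(float(v), 4) for k, v in props.items()},
            "venn": {"only_f_vs_m": only_m, "both": both, "only_f_vs_p": only_p},
            "category_recovery": round(recovery, 4),
            "cluster_leaf_order": leaf_order,
        }
        print(f"{d.cross_id}: {n_deg} DEGs, recovery {recovery:.1%}, "
              f"venn {only_m}/{both}/{only_p}, leaves {' '.join(leaf_order)}")

    common = common_dominance_set(class_tables)
    summary["common_dominance"] = {"n": len(common), "genes": sorted(common)}
    print(f"common dominance genes across the three crosses: {len(common)}")

    with open(OUT / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
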