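#!/usr/bin/env python
"""Body-weight heterosis statistics for the three crosses.

Computes the mid-parent value, the rate of heterosis and the mid-parent
significance contrast from the published line summaries (mean, SE, n in
data/fly_body_weight.tsv), using the table convention of a 2-dp-rounded
MPV. Writes results/phenotype/heterosis.tsv and prints the table.
"""

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from hetvig import PhenotypeSummary, heterosis_table_row, read_phenotypes
from hetvig.pheno import round_half_up

REPO = Path(__file__).resolve().parent.parent
OUT = REPO / "results" / "phenotype"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ph = read_phenotypes(REPO / "data" / "fly_body_weight.tsv")
    with open(REPO / "data" / "crosses.yaml") as fh:
        crosses = yaml.safe_load(fh)["crosses"]

    summaries = {
        line: PhenotypeSummary(line, float(r["mean"]), float(r["se"]), int(r["n"]))
        for line, r in ph.iterrows()
    }
    rows = []
    for c in crosses:
        row = heterosis_table_row(
            c["cross_id"], summaries[c["f1"]], summaries[c["father"]],
            summaries[c["mother"]], round_mpv=True,
        )
        rows.append(asdict(row))
        print(f"{row.cross_id}: MPV {round_half_up(row.mpv):.2f} ug, "
              f"RH {round_half_up(row.rh):.2f}% {row.mark} "
              f"(z = {row.statistic:.2f})")

    pd.DataFrame(rows).set_index("cross_id").to_csv(
        OUT / "heterosis.tsv", sep="\t", float_format="%.10g"
    )


if __name__ == "__main__":
    main()
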