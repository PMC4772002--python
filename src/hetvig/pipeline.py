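"""End-to-end orchestration: simulate/load -> DE -> classify -> enrich -> phenotype.

A single :class:`PipelineConfig` drives one run. Exactly one input source
is allowed: either a simulation block (a TruthSpec plus annotation-fixture
parameters) or paths to real tables (counts, sample sheet, lengths,
annotation, phenotypes). Every paper-style cutoff is surfaced: the DE
adjusted-p threshold, the enrichment threshold, the zero-read exclusion
rule and the mid-parent-value rounding convention.

Outputs are plain TSV/JSON files in a run directory plus a manifest
recording the config hash, the seed and per-stage row counts; the same
config and seed reproduce the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import diffexpr as _de
from . import enrich as _enrich
from . import io as _io
from . import pheno as _pheno
from . import simulate as _sim

__all__ = ["PipelineConfig", "run_pipeline", "summarize_run"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run (simulated or real inputs)."""

    simulate: dict | None = None
    counts: str | None = None
    sample_sheet: str | None = None
    lengths: str | None = None
    annotation: str | None = None
    phenotypes: str | None = None
    pheno_crosses: list[dict] = field(default_factory=list)
    padj_threshold: float = 0.05
    enrich_threshold: float = 0.05
    zero_rule: str = "line"
    round_mpv: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        has_sim = self.simulate is not None
        has_real = self.counts is not None
        if has_sim == has_real:
            raise ValueError(
                "exactly one of a simulation block or a counts path must be given"
            )
        if has_real and self.sample_sheet is None:
            raise ValueError("real counts need a sample sheet")
        for name in ("padj_threshold", "enrich_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _simulate_inputs(cfg: PipelineConfig, outdir: Path) -> dict[str, Any]:
    block = dict(cfg.simulate or {})
    n_crosses = int(block.pop("n_crosses", 3))
    ann = block.pop("annotation", {"n_terms": 50, "genes_per_term": 20, "length_range": [300, 8000]})
    block.setdefault("seed", cfg.seed)
    if "classes" not in block:
        # equal mass on all twelve classes plus nonDEG
        block["classes"] = {l: 1.0 / 13 for l in _sim.CLASS_LABELS}
    spec = _sim.TruthSpec(**block)
    crosses = _sim.simulate_multi_cross(spec, n_crosses=n_crosses)

    lengths_df, ann_df = _sim.make_annotation_fixture(
        n_genes=spec.n_genes,
        n_terms=int(ann.get("n_terms", 50)),
        genes_per_term=int(ann.get("genes_per_term", 20)),
        length_range=tuple(ann.get("length_range", (300, 8000))),
        seed=spec.seed,
    )
    lengths = lengths_df.set_index("gene_id")["length_bp"].astype(float)
    annotation = {t: set(g["gene_id"]) for t, g in ann_df.groupby("term_id")}

    for m, d, truth in crosses:
        _io.write_counts(m, outdir / f"counts_{d.cross_id}.tsv")
        _write_tsv(truth.table, outdir / f"truth_{d.cross_id}.tsv")
    lengths_df.to_csv(outdir / "gene_lengths.tsv", sep="\t", index=False)
    ann_df.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    return {
        "crosses": [(m, d) for m, d, _ in crosses],
        "truths": {d.cross_id: t for _, d, t in crosses},
        "lengths": lengths,
        "annotation": annotation,
    }


def _load_inputs(cfg: PipelineConfig) -> dict[str, Any]:
    m = _io.read_counts(cfg.counts)
    designs = _io.read_sample_sheet(cfg.sample_sheet)
    for d in designs:
        d.validate_against(m)
    out: dict[str, Any] = {
        "crosses": [(m.subset_samples(list(d.all_samples)), d) for d in designs],
        "truths": {},
        "lengths": _io.read_gene_lengths(cfg.lengths) if cfg.lengths else None,
        "annotation": _io.read_annotation_map(cfg.annotation) if cfg.annotation else None,
    }
    return out


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage and write TSV/JSON outputs plus a manifest.

    Returns the run directory. Any stage error aborts the run with the
    stage name attached to the exception message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }

    stage = "inputs"
    try:
        inputs = _simulate_inputs(cfg, outdir) if cfg.simulate else _load_inputs(cfg)
        manifest["stages"][stage] = {
            "n_crosses": len(inputs["crosses"]),
            "n_genes": int(inputs["crosses"][0][0].shape[0]),
        }

        stage = "differential_expression"
        de_by_cross: dict[str, dict[str, pd.DataFrame]] = {}
        for m, d in inputs["crosses"]:
            tables = _de.pairwise_trio_de(m, d, threshold=cfg.padj_threshold)
            de_by_cross[d.cross_id] = tables
            for name, tab in tables.items():
                _write_tsv(tab, outdir / f"de_{d.cross_id}_{name}.tsv")
        manifest["stages"][stage] = {
            c: {n: int((t["call"] != "ns").sum()) for n, t in tabs.items()}
            for c, tabs in de_by_cross.items()
        }

        stage = "classification"
        class_tables: dict[str, pd.DataFrame] = {}
        summary: dict[str, Any] = {}
        for m, d in inputs["crosses"]:
            table, props = _classify.classify_all(
                de_by_cross[d.cross_id], m, d, zero_rule=cfg.zero_rule
            )
            class_tables[d.cross_id] = table
            _write_tsv(table, outdir / f"classes_{d.cross_id}.tsv")
            counts = table["category"].value_counts().to_dict()
            fm_deg = set(table.index[(table["c_fm"] != "ns")])
            fp_deg = set(table.index[(table["c_fp"] != "ns")])
            only_a, both, only_b = _classify.venn_counts(fm_deg, fp_deg)
            deg = table.loc[~table["category"].isin(["nonDEG", "excluded"])]
            summary[d.cross_id] = {
                "n_deg": int(len(deg)),
                "category_counts": {k: int(v) for k, v in sorted(counts.items())},
                "category_proportions": {k: float(v) for k, v in props.items()},
                "venn_f_vs_parents": {"only_f_vs_m": only_a, "both": both, "only_f_vs_p": only_b},
            }
        common = _classify.common_dominance_set(list(class_tables.values()))
        summary["common_dominance"] = {"n": len(common), "genes": sorted(common)}
        manifest["stages"][stage] = {c: summary[c]["n_deg"] for c in class_tables}

        stage = "clustering"
        if inputs["lengths"] is not None:
            leaf_orders = {}
            for m, d in inputs["crosses"]:
                rpkm = _io.compute_rpkm(m, inputs["lengths"])
                _, leaves = _classify.hier_cluster(rpkm)
                leaf_orders[d.cross_id] = leaves
            summary["cluster_leaf_order"] = leaf_orders
            manifest["stages"][stage] = {c: len(v) for c, v in leaf_orders.items()}

        stage = "enrichment"
        if inputs["annotation"] is not None and inputs["lengths"] is not None:
            for cross_id, table in class_tables.items():
                dom = set(table.index[table["class"].isin(_classify.DOMINANCE_CLASSES)])
                bg = set(table.index[table["category"] != "excluded"])
                if dom:
                    res = _enrich.enrich_terms(
                        inputs["annotation"], dom, bg,
                        lengths=inputs["lengths"], method="wallenius",
                        threshold=cfg.enrich_threshold,
                    )
                    _write_tsv(res, outdir / f"enrichment_{cross_id}.tsv")
                    manifest["stages"].setdefault(stage, {})[cross_id] = int(res["flag"].sum())

        stage = "recovery"
        if inputs["truths"]:
            recov = {}
            for cross_id, table in class_tables.items():
                truth = inputs["truths"][cross_id]
                pred = table["category"]
                true = truth.categories()
                recov[cross_id] = float((pred == true).mean())
            summary["category_recovery"] = recov
            manifest["stages"][stage] = recov

        stage = "phenotype"
        if cfg.phenotypes:
            ph = _io.read_phenotypes(cfg.phenotypes)
            rows = []
            for spec in cfg.pheno_crosses:
                get = lambda line: _pheno.PhenotypeSummary(
                    line_id=line,
                    mean=float(ph.at[line, "mean"]),
                    se=float(ph.at[line, "se"]),
                    n=int(ph.at[line, "n"]),
                )
                res = _pheno.heterosis_table_row(
                    spec["cross_id"], get(spec["f1"]), get(spec["father"]),
                    get(spec["mother"]), round_mpv=cfg.round_mpv,
                )
                rows.append(asdict(res))
            pheno_df = pd.DataFrame(rows).set_index("cross_id")
            _write_tsv(pheno_df, outdir / "heterosis.tsv")
            manifest["stages"][stage] = {"n_crosses": len(rows)}
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def summarize_run(run_dir: str | Path) -> str:
    """Human-readable report of a completed run, consistent with its files."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    manifest_path = run_dir / "manifest.json"
    for p in (summary_path, manifest_path):
        if not p.exists():
            raise FileNotFoundError(f"missing pipeline output: {p}")
    with open(summary_path) as fh:
        summary = json.load(fh)
    with open(manifest_path) as fh:
        manifest = json.load(fh)

    lines = [f"run {manifest['config_hash']} (seed {manifest['seed']})"]
    total_deg = 0
    for cross_id, block in sorted(summary.items()):
        if not isinstance(block, dict) or "n_deg" not in block:
            continue
        total_deg += block["n_deg"]
        if block["n_deg"] == 0:
            lines.append(f"  {cross_id}: zero DEGs")
            continue
        props = block["category_proportions"]
        dom = sum(v for k, v in props.items() if k.startswith("ELD-"))
        venn = block["venn_f_vs_parents"]
        lines.append(
            f"  {cross_id}: {block['n_deg']} DEGs; dominance {100*dom:.1f}%; "
            f"venn (f-vs-m only / both / f-vs-p only) = "
            f"{venn['only_f_vs_m']}/{venn['both']}/{venn['only_f_vs_p']}"
        )
    lines.append(f"  total DEGs across crosses: {total_deg}")
    if "common_dominance" in summary:
        lines.append(f"  common dominance genes: {summary['common_dominance']['n']}")
    if "category_recovery" in summary:
        rec = summary["category_recovery"]
        avg = float(np.mean(list(rec.values())))
        lines.append(f"  category recovery vs truth: mean {avg:.3f}")
    pheno_path = run_dir / "heterosis.tsv"
    if pheno_path.exists():
        ph = pd.read_csv(pheno_path, sep="\t")
        for _, row in ph.iterrows():
            lines.append(
                f"  {row['cross_id']}: MPV {row['mpv']:.2f}, RH {row['rh']:.2f}% {row['mark']}"
            )
    return "\n".join(lines)
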