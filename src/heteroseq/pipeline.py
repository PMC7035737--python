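"""End-to-end orchestration of the trio heterosis analysis.

``run_pipeline`` drives the stages in dependency order — simulate (or
load), QC, differential expression per (hybrid, tissue) contrast, trio
classification, additivity partition, summaries, and the optional
phenotype/QTL/annotation/qPCR stages — writing TSV/JSON outputs to a run
directory.  Every table is reproducible from the configuration and a
single seed; missing optional inputs mark their stage "skipped" rather
than failing the run.  ``fixture_report`` reproduces the printed-summary
arithmetic from externally supplied count cells alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, de, heterosis, io, qpcr, qtl, simulate, trio


@dataclass
class RunConfig:
    out_dir: str = "heteroseq_run"
    seed: int = 0
    # inputs; None -> simulate (counts) or skip (optional stages)
    counts_path: str | None = None
    sheet_path: str | None = None
    catalog_path: str | None = None
    qtl_path: str | None = None
    trait_path: str | None = None
    annotation_path: str | None = None
    ct_path: str | None = None
    ct_calibrator: str | None = None
    # analysis parameters
    de_fdr: float = 0.01
    de_lfc: float = 1.0
    degfu_rule: str = "both_parents"
    additivity_fdr: float = 0.05
    additivity_lfc: float = 1.0
    overlap_rule: str = "any_overlap"
    qc_threshold: float = 0.8
    trait_directions: dict = field(default_factory=dict)
    # simulation parameters (used when counts_path is None)
    sim: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("de_fdr", "de_lfc", "additivity_fdr", "additivity_lfc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _derived_seed(seed: int, stage: str) -> int:
    """Per-stage seed: sha256(seed:stage) folded below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _stage_contrasts(sheet: pd.DataFrame, hybrid: str, tissue: str) -> dict[str, tuple[list, list]]:
    cond = sheet[(sheet["hybrid"] == hybrid) & (sheet["tissue"] == tissue)]
    by_geno = {
        g: grp.sort_values("replicate")["sample_id"].tolist()
        for g, grp in cond.groupby("genotype")
    }
    return {
        "P1_vs_P2": (by_geno["P1"], by_geno["P2"]),
        "F1_vs_P1": (by_geno["P1"], by_geno["F1"]),
        "F1_vs_P2": (by_geno["P2"], by_geno["F1"]),
    }


def classify_trio(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    de_fdr: float = 0.01,
    de_lfc: float = 1.0,
    degfu_rule: str = "both_parents",
    additivity_fdr: float = 0.05,
    additivity_lfc: float = 1.0,
    write_de_to: Path | None = None,
) -> tuple[list[trio.DEGSetBundle], pd.DataFrame, dict]:
    """DE + trio set algebra + additivity for every (hybrid, tissue) context.

    Returns (bundles, additivity table, degfu_sp_by_context).  This is the
    library-level core that both the CLI pipeline and the recovery
    experiments call.
    """
    bundles: dict[tuple[str, str], trio.DEGSetBundle] = {}
    degfu_by_hybrid: dict[str, dict[str, set]] = {}
    for hybrid in sheet["hybrid"].unique():
        degfu_by_hybrid[hybrid] = {}
        for tissue in sheet.loc[sheet["hybrid"] == hybrid, "tissue"].unique():
            calls = {}
            for label, (a, b) in _stage_contrasts(sheet, hybrid, tissue).items():
                res = de.de_contrast(
                    counts, a, b, fdr_threshold=de_fdr, lfc_threshold=de_lfc
                )
                calls[label] = res.index[res["call"]].tolist()
                if write_de_to is not None:
                    de.write_de_results(
                        res, write_de_to / f"{hybrid}_{tissue}_{label}.de.tsv"
                    )
            bundle = trio.build_trio_sets(calls, hybrid, tissue)
            trio.derive_degfu(bundle, degfu_rule)
            bundles[(hybrid, tissue)] = bundle
            degfu_by_hybrid[hybrid][tissue] = bundle.degfu

    degfu_sp_by_context: dict[tuple[str, str], set] = {}
    for hybrid, by_tissue in degfu_by_hybrid.items():
        sp = trio.derive_degfu_sp(by_tissue)
        for tissue, genes in sp.items():
            bundles[(hybrid, tissue)].degfu_sp = genes
            degfu_sp_by_context[(hybrid, tissue)] = genes

    add_tables = []
    for (hybrid, tissue), genes in degfu_sp_by_context.items():
        if not genes:
            continue
        add_tables.append(
            trio.additivity_test(
                counts, sheet, genes, hybrid, tissue,
                fdr=additivity_fdr, lfc=additivity_lfc,
            )
        )
    additivity = (
        pd.concat(add_tables, ignore_index=True)
        if add_tables
        else pd.DataFrame(
            columns=["hybrid", "tissue", "gene_id", "log2_f1_mpv", "p", "flag", "fdr", "class"]
        )
    )
    return list(bundles.values()), additivity, degfu_sp_by_context


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the report bundle as a dict.

    Writes tables under ``config.out_dir`` and a ``report.json`` carrying
    per-stage status, record counts, the resolved configuration and its
    hash.  Optional stages without inputs report status "skipped".
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    report: dict = {"config_hash": chash, "seed": config.seed, "stages": {}, "config": asdict(config)}

    def stage(name, status, **info):
        report["stages"][name] = {"status": status, **info}

    # ---- inputs ----------------------------------------------------------
    truth = None
    if config.counts_path is None:
        sim_cfg = simulate.SimConfig(
            **{**config.sim, "seed": _derived_seed(config.seed, "simulate")}
        )
        catalog = simulate.simulate_annotation(sim_cfg)
        counts, sheet, truth = simulate.simulate_trio_counts(catalog, sim_cfg)
        io.write_counts(counts, sheet.drop(columns=["true_size_factor"]),
                        out / "counts.tsv", out / "samples.tsv")
        io.write_catalog(catalog, out / "genes.tsv")
        io.write_catalog_bed(catalog, out / "genes.bed")
        simulate.write_truth(truth, out / "truth.tsv")
        stage("simulate", "ok", n_genes=len(catalog), n_samples=counts.shape[1])
    else:
        counts, sheet = io.read_counts(config.counts_path, config.sheet_path)
        catalog = io.read_catalog(config.catalog_path) if config.catalog_path else None
        stage("simulate", "skipped", reason="counts supplied")

    # ---- QC --------------------------------------------------------------
    if catalog is not None:
        fpkm = io.compute_fpkm(counts, catalog)
        qc = io.replicate_qc(fpkm, sheet, threshold=config.qc_threshold)
        io.write_qc_report(qc, out / "qc.tsv", out / "qc.json")
        stage("qc", "ok", n_pairs=len(qc), n_flagged=int(qc["flagged"].sum()))
    else:
        stage("qc", "skipped", reason="no gene catalogue for FPKM")

    # ---- DE + trio classification ---------------------------------------
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    bundles, additivity, degfu_sp = classify_trio(
        counts, sheet,
        de_fdr=config.de_fdr, de_lfc=config.de_lfc, degfu_rule=config.degfu_rule,
        additivity_fdr=config.additivity_fdr, additivity_lfc=config.additivity_lfc,
        write_de_to=de_dir,
    )
    trio.write_bundles(bundles, out / "trio_sets.tsv")
    additivity.to_csv(out / "additivity.tsv", sep="\t", index=False)
    summary = trio.summarize(bundles, additivity)
    summary.set_counts.to_csv(out / "summary_sets.tsv", sep="\t", index=False)
    summary.ndeg_counts.to_csv(out / "summary_ndeg.tsv", sep="\t", index=False)
    summary.tissue_percent.to_csv(out / "summary_percent.tsv", sep="\t", index=False)
    stage("classify", "ok", **summary.totals)
    report["summary_totals"] = summary.totals

    # ---- recovery metrics (when truth exists) ----------------------------
    if truth is not None:
        recovery = trio.evaluate_recovery(truth, degfu_sp, additivity)
        report["recovery"] = recovery
        stage("recovery", "ok")
    else:
        stage("recovery", "skipped", reason="no planted truth")

    # ---- phenotypes ------------------------------------------------------
    if config.trait_path:
        obs = heterosis.read_trait_table(config.trait_path)
        het = heterosis.heterosis_table(obs, config.trait_directions)
        het.to_csv(out / "heterosis.tsv", sep="\t", index=False)
        stage("heterosis", "ok", n_rows=len(het))
    else:
        stage("heterosis", "skipped", reason="no phenotype table")

    # ---- QTL mapping -----------------------------------------------------
    if config.qtl_path and catalog is not None:
        qtls = qtl.read_qtl_catalog(config.qtl_path)
        index = qtl.build_index(qtls)
        hits_by_hybrid = {}
        for hybrid in sheet["hybrid"].unique():
            genes = set().union(
                *(degfu_sp.get((hybrid, t), set()) for t in sheet["tissue"].unique())
            )
            sub = catalog[catalog["gene_id"].isin(genes)]
            hits_by_hybrid[hybrid] = qtl.map_genes(
                sub, index, config.overlap_rule, source_label=hybrid
            )
        traits_present = tuple(
            t for t in simulate.YIELD_TRAITS if t in set(qtls["trait"])
        ) or tuple(sorted(set(qtls["trait"])))
        inter = qtl.filter_and_intersect(
            hits_by_hybrid, traits=traits_present, valid_traits=set(qtls["trait"])
        )
        pd.concat(inter["filtered"].values(), ignore_index=True).to_csv(
            out / "qtl_hits.tsv", sep="\t", index=False
        )
        tally = qtl.per_chromosome_tally(qtls, inter["common_qtls"])
        tally.to_csv(out / "qtl_common_tally.tsv", sep="\t", index=False)
        stage("qtlmap", "ok", n_common=len(inter["common_qtls"]))
    else:
        stage("qtlmap", "skipped", reason="no QTL catalogue")

    # ---- annotation ------------------------------------------------------
    if config.annotation_path:
        ann = annotate.read_annotations(config.annotation_path)
        cats = annotate.keyword_categorize(ann)
        cats.to_csv(out / "categories.tsv", sep="\t", index=False)
        stage("annotate", "ok", n_assignments=len(cats))
    else:
        stage("annotate", "skipped", reason="no annotation table")

    # ---- qPCR ------------------------------------------------------------
    if config.ct_path and config.ct_calibrator:
        ct = qpcr.read_ct_table(config.ct_path)
        rq = qpcr.ddct(ct, config.ct_calibrator)
        rq.to_csv(out / "qpcr_rq.tsv", sep="\t", index=False)
        stage("qpcr", "ok", n_rows=len(rq))
    else:
        stage("qpcr", "skipped", reason="no Ct table or calibrator")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


# ---------------------------------------------------------------------------
# fixture-mode summary arithmetic

def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("1.00"), ROUND_HALF_UP))


def fixture_report(table2_cells: pd.DataFrame, table4_cells: pd.DataFrame) -> dict:
    """Printed-summary arithmetic from count cells alone.

    ``table2_cells`` needs columns hybrid, tissue, degfu_sp (8 tissues x 2
    hybrids); ``table4_cells`` needs hybrid, tissue, up, down.  Returns
    per-hybrid DEGFu-sp totals, the grand total, per-tissue-type sums
    (leaf/sheath/spikelet/panicle_axis pooled over stage and hybrid),
    non-additive totals, per-tissue-type non-additive sums, and percent =
    100 * sum NDEG / sum DEGFu-sp per tissue context rounded half-up to 2
    decimals (undefined, not 0, on empty denominators).
    """
    from .tables import TISSUE_TYPES

    for df, cols, label in (
        (table2_cells, {"hybrid", "tissue", "degfu_sp"}, "table2"),
        (table4_cells, {"hybrid", "tissue", "up", "down"}, "table4"),
    ):
        if not cols <= set(df.columns):
            raise ValueError(f"{label} cells need columns {sorted(cols)}")
    n_hybrids = table2_cells["hybrid"].nunique()
    if len(table2_cells) != 8 * n_hybrids or len(table4_cells) != 8 * n_hybrids:
        raise ValueError("expected 8 tissue cells per hybrid in both fixtures")

    t2 = table2_cells.set_index(["hybrid", "tissue"])["degfu_sp"]
    t4 = table4_cells.set_index(["hybrid", "tissue"])
    ndeg_total = t4["up"] + t4["down"]

    per_hybrid = t2.groupby("hybrid").sum()
    by_type_fu = {
        name: int(sum(t2.xs(t, level="tissue").sum() for t in tissues))
        for name, tissues in TISSUE_TYPES.items()
    }
    by_type_ndeg = {
        name: int(sum(ndeg_total.xs(t, level="tissue").sum() for t in tissues))
        for name, tissues in TISSUE_TYPES.items()
    }
    percent = {}
    for tissue in table2_cells["tissue"].unique():
        denom = int(t2.xs(tissue, level="tissue").sum())
        num = int(ndeg_total.xs(tissue, level="tissue").sum())
        percent[tissue] = _round2(100.0 * num / denom) if denom else None
    return {
        "degfu_sp_by_hybrid": {str(h): int(v) for h, v in per_hybrid.items()},
        "degfu_sp_total": int(t2.sum()),
        "degfu_sp_by_tissue_type": by_type_fu,
        "ndeg_total": int(ndeg_total.sum()),
        "ndeg_up": int(t4["up"].sum()),
        "ndeg_down": int(t4["down"].sum()),
        "ndeg_by_tissue_type": by_type_ndeg,
        "ndeg_percent_by_tissue": percent,
    }
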