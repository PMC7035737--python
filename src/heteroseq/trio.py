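"""Trio (P1, P2, F1) DEG set algebra and additive/non-additive partitioning.

Per (hybrid, tissue) three DEG sets are built from the pairwise contrasts:
DEG2P (parent vs parent), DEGP1 (F1 vs P1) and DEGP2 (F1 vs P2).  Genes
differentially expressed in the F1 against both parents, while the parents
do not differ from each other, form the F1-unique set DEGFu; restricting
DEGFu to genes that appear in exactly one tissue context within a hybrid
gives the tissue-specific set DEGFu-sp.

DEGFu-sp genes are then partitioned by a mid-parent deviation test: the F1
replicate values are compared to per-replicate-pair mid-parent constructs
(P1_r + P2_r) / 2 on the log2 normalized-count scale with a Welch t-test;
genes with FDR < 0.05 and |log2(F1 / MPV)| >= 1 are non-additive (signed
up/down), the remainder additive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust, estimate_size_factors

CONTRAST_LABELS = ("P1_vs_P2", "F1_vs_P1", "F1_vs_P2")
DEGFU_RULES = ("both_parents", "either_parent")


@dataclass
class DEGSetBundle:
    hybrid: str
    tissue: str
    deg2p: set = field(default_factory=set)
    degp1: set = field(default_factory=set)
    degp2: set = field(default_factory=set)
    degfu: set = field(default_factory=set)
    degfu_sp: set = field(default_factory=set)
    degfu_rule: str = "both_parents"


def build_trio_sets(de_calls: dict[str, list], hybrid: str, tissue: str) -> DEGSetBundle:
    """Assemble the three DEG sets from per-contrast call lists.

    ``de_calls`` maps contrast label (P1_vs_P2, F1_vs_P1, F1_vs_P2) to an
    iterable of called gene ids; duplicates are removed with a warning.
    """
    missing = [lab for lab in CONTRAST_LABELS if lab not in de_calls]
    if missing:
        raise KeyError(f"missing contrast(s) for ({hybrid}, {tissue}): {missing}")
    sets = {}
    for lab in CONTRAST_LABELS:
        genes = list(de_calls[lab])
        if len(genes) != len(set(genes)):
            warnings.warn(
                f"duplicate gene ids in {lab} calls for ({hybrid}, {tissue}); deduplicated",
                RuntimeWarning,
                stacklevel=2,
            )
        sets[lab] = set(genes)
    return DEGSetBundle(
        hybrid=hybrid,
        tissue=tissue,
        deg2p=sets["P1_vs_P2"],
        degp1=sets["F1_vs_P1"],
        degp2=sets["F1_vs_P2"],
    )


def derive_degfu(bundle: DEGSetBundle, rule: str = "both_parents") -> set:
    """F1-unique DEG set under the configured rule.

    both_parents (default, the stricter reading of "uniquely belonging to
    F1"): (DEGP1 intersect DEGP2) minus DEG2P.  either_parent:
    (DEGP1 union DEGP2) minus DEG2P.
    """
    if rule not in DEGFU_RULES:
        raise ValueError(f"unknown DEGFu rule {rule!r}; valid: {DEGFU_RULES}")
    if rule == "both_parents":
        fu = (bundle.degp1 & bundle.degp2) - bundle.deg2p
    else:
        fu = (bundle.degp1 | bundle.degp2) - bundle.deg2p
    bundle.degfu = fu
    bundle.degfu_rule = rule
    return fu


def derive_degfu_sp(degfu_by_tissue: dict[str, set], tissue_specific: bool = True) -> dict[str, set]:
    """Tissue-specific DEGFu: keep a gene only in the single tissue context
    where it occurs; genes in the DEGFu of two or more tissues are dropped
    from all of them.  With ``tissue_specific=False`` the sets pass through
    unchanged (shared genes allowed)."""
    if not degfu_by_tissue:
        raise ValueError("at least one tissue required")
    if not tissue_specific:
        return {t: set(s) for t, s in degfu_by_tissue.items()}
    counts: dict[str, int] = {}
    for genes in degfu_by_tissue.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return {
        t: {g for g in genes if counts[g] == 1} for t, genes in degfu_by_tissue.items()
    }


# ---------------------------------------------------------------------------
# additivity

def additivity_test(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    degfu_sp: set,
    hybrid: str,
    tissue: str,
    size_factors: pd.Series | None = None,
    fdr: float = 0.05,
    lfc: float = 1.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Mid-parent deviation test for the DEGFu-sp genes of one context.

    Welch t of log2(F1 normalized counts + 0.5) against log2 of the
    per-replicate-pair mid-parent constructs; BH across tested genes;
    non-additive iff FDR < ``fdr`` and |log2(F1/MPV)| >= ``lfc``, with the
    sign of the effect deciding up vs down.  A gene whose F1 and mid-parent
    values are all zero is classified additive and flagged uninformative.
    """
    cond = sheet[(sheet["hybrid"] == hybrid) & (sheet["tissue"] == tissue)]
    groups = {
        geno: grp.sort_values("replicate")["sample_id"].tolist()
        for geno, grp in cond.groupby("genotype")
    }
    for geno in ("P1", "P2", "F1"):
        if len(groups.get(geno, [])) < 2:
            raise ValueError(f"need >= 2 {geno} replicates in ({hybrid}, {tissue})")
    samples = groups["P1"] + groups["P2"] + groups["F1"]
    if size_factors is None:
        size_factors = estimate_size_factors(counts[samples])
    genes = sorted(degfu_sp)
    q = counts.loc[genes, samples] / size_factors[samples]
    n_pairs = min(len(groups["P1"]), len(groups["P2"]))
    qp1 = q[groups["P1"][:n_pairs]].to_numpy()
    qp2 = q[groups["P2"][:n_pairs]].to_numpy()
    qf1 = q[groups["F1"]].to_numpy()
    mpv_reps = (qp1 + qp2) / 2.0

    rows = []
    for i, g in enumerate(genes):
        f1_vals = qf1[i]
        mp_vals = mpv_reps[i]
        effect = float(
            np.log2((f1_vals.mean() + pseudocount) / (mp_vals.mean() + pseudocount))
        )
        if f1_vals.max() == 0 and mp_vals.max() == 0:
            rows.append((g, effect, np.nan, "uninformative"))
            continue
        t = stats.ttest_ind(
            np.log2(f1_vals + pseudocount), np.log2(mp_vals + pseudocount), equal_var=False
        )
        rows.append((g, effect, float(t.pvalue), ""))
    res = pd.DataFrame(rows, columns=["gene_id", "log2_f1_mpv", "p", "flag"])
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    nonadd = (res["fdr"] < fdr) & (res["log2_f1_mpv"].abs() >= lfc)
    nonadd = nonadd.fillna(False)
    res["class"] = np.where(
        ~nonadd, "additive", np.where(res["log2_f1_mpv"] > 0, "nonadditive_up", "nonadditive_down")
    )
    res.insert(0, "tissue", tissue)
    res.insert(0, "hybrid", hybrid)
    return res


# ---------------------------------------------------------------------------
# summaries

def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("1." + "0" * ndigits), ROUND_HALF_UP))


@dataclass
class ClassificationSummary:
    set_counts: pd.DataFrame      # per (hybrid, tissue): |DEG2P|, |DEGP1|, |DEGP2|, |DEGFu_sp|
    ndeg_counts: pd.DataFrame     # per (hybrid, tissue): NDEG total / up / down
    tissue_percent: pd.DataFrame  # per tissue pooled over hybrids: percent NDEG of DEGFu-sp
    totals: dict


def summarize(
    bundles: list[DEGSetBundle],
    additivity: pd.DataFrame | None = None,
) -> ClassificationSummary:
    """Tabulate the trio classification: per-context set sizes, per-context
    non-additive counts, and per-tissue NDEG percentages pooled over hybrids
    (percent = 100 * sum NDEG / sum DEGFu-sp)."""
    set_rows = [
        (b.hybrid, b.tissue, len(b.deg2p), len(b.degp1), len(b.degp2), len(b.degfu_sp))
        for b in bundles
    ]
    set_counts = pd.DataFrame(
        set_rows, columns=["hybrid", "tissue", "deg2p", "degp1", "degp2", "degfu_sp"]
    )
    if additivity is not None and len(additivity):
        grp = additivity.groupby(["hybrid", "tissue"])["class"]
        ndeg_counts = pd.DataFrame(
            {
                "up": grp.apply(lambda s: int((s == "nonadditive_up").sum())),
                "down": grp.apply(lambda s: int((s == "nonadditive_down").sum())),
            }
        ).reset_index()
    else:
        ndeg_counts = set_counts[["hybrid", "tissue"]].copy()
        ndeg_counts["up"] = 0
        ndeg_counts["down"] = 0
    ndeg_counts["total"] = ndeg_counts["up"] + ndeg_counts["down"]
    return _finish_summary(set_counts, ndeg_counts)


def summarize_cells(table2_cells: pd.DataFrame, table4_cells: pd.DataFrame) -> ClassificationSummary:
    """Fixture mode: recompute the summary arithmetic from externally supplied
    count cells, without gene-level data.

    ``table2_cells``: columns hybrid, tissue, deg2p, degp1, degp2, degfu_sp.
    ``table4_cells``: columns hybrid, tissue, up, down.
    """
    set_counts = table2_cells.copy()
    ndeg_counts = table4_cells.copy()
    ndeg_counts["total"] = ndeg_counts["up"] + ndeg_counts["down"]
    if set(map(tuple, set_counts[["hybrid", "tissue"]].values)) != set(
        map(tuple, ndeg_counts[["hybrid", "tissue"]].values)
    ):
        raise ValueError("table2/table4 cells cover different (hybrid, tissue) keys")
    return _finish_summary(set_counts, ndeg_counts)


def _finish_summary(set_counts: pd.DataFrame, ndeg_counts: pd.DataFrame) -> ClassificationSummary:
    merged = set_counts.merge(ndeg_counts, on=["hybrid", "tissue"], how="outer").fillna(0)
    per_tissue = merged.groupby("tissue", sort=False).agg(
        degfu_sp=("degfu_sp", "sum"), ndeg=("total", "sum")
    )
    percent = []
    for tissue, row in per_tissue.iterrows():
        if row["degfu_sp"] > 0:
            percent.append((tissue, int(row["ndeg"]), int(row["degfu_sp"]),
                            _round_half_up(100.0 * row["ndeg"] / row["degfu_sp"])))
        else:
            percent.append((tissue, int(row["ndeg"]), 0, np.nan))
    tissue_percent = pd.DataFrame(
        percent, columns=["tissue", "ndeg", "degfu_sp", "percent"]
    )
    per_hybrid = set_counts.groupby("hybrid", sort=False)["degfu_sp"].sum()
    totals = {
        "degfu_sp_by_hybrid": {str(k): int(v) for k, v in per_hybrid.items()},
        "degfu_sp_total": int(set_counts["degfu_sp"].sum()),
        "ndeg_total": int(ndeg_counts["total"].sum()),
        "ndeg_up": int(ndeg_counts["up"].sum()),
        "ndeg_down": int(ndeg_counts["down"].sum()),
    }
    return ClassificationSummary(set_counts, ndeg_counts, tissue_percent, totals)


# ---------------------------------------------------------------------------
# recovery scoring against planted truth

def _precision_recall(predicted: set, truth_pos: set, excluded: set = frozenset()) -> dict:
    denom_pred = predicted - excluded
    tp = len(predicted & truth_pos)
    precision = tp / len(denom_pred) if denom_pred else np.nan
    recall = tp / len(truth_pos) if truth_pos else np.nan
    return {"precision": precision, "recall": recall,
            "n_predicted": len(predicted), "n_truth": len(truth_pos)}


def evaluate_recovery(
    truth: pd.DataFrame,
    degfu_sp_by_context: dict[tuple[str, str], set],
    additivity: pd.DataFrame | None = None,
) -> dict:
    """Precision/recall of the pipeline against the planted truth.

    F1-unique recovery compares the DEGFu-sp sets to planted genes whose
    class is F1-unique-like (f1_unique, nonadd_up, nonadd_down) in exactly
    one tissue context of the hybrid (genes planted in several contexts are
    unrecoverable by the tissue-specific rule and are excluded from the
    recall denominator).

    Non-additive up/down recovery scores the additivity partition, whose
    universe is the DEGFu-sp set it operates on: ``recall`` is measured
    among planted nonadd genes that entered the tested set, and the
    unconditional product of both stages is reported alongside as
    ``recall_end_to_end``.  Genes planted as f1_unique are excluded from
    the precision denominator because their expression pattern is
    indistinguishable from a non-additive one.
    """
    from .simulate import F1_UNIQUE_CLASSES  # local import to avoid cycle

    t = truth.copy()
    t["is_fu"] = t["class"].isin(F1_UNIQUE_CLASSES)
    fu_counts = (
        t[t["is_fu"]].groupby(["hybrid", "gene_id"])["tissue"].nunique().rename("n_fu_tissues")
    )
    t = t.merge(fu_counts, on=["hybrid", "gene_id"], how="left")
    t["n_fu_tissues"] = t["n_fu_tissues"].fillna(0)

    key = lambda row: (row.hybrid, row.tissue, row.gene_id)
    eligible = t[t["is_fu"] & (t["n_fu_tissues"] == 1)]
    truth_fu = {key(r) for r in eligible.itertuples()}
    pred_fu = {
        (hyb, tis, g)
        for (hyb, tis), genes in degfu_sp_by_context.items()
        for g in genes
    }
    out = {"f1_unique": _precision_recall(pred_fu, truth_fu)}

    if additivity is not None and len(additivity):
        tested = {
            (r.hybrid, r.tissue, r.gene_id) for r in additivity.itertuples()
        }
        f1u_excluded = {
            key(r) for r in eligible[eligible["class"] == "f1_unique"].itertuples()
        }
        for direction, cls in (("nonadd_up", "nonadditive_up"), ("nonadd_down", "nonadditive_down")):
            truth_pos = {
                key(r) for r in eligible[eligible["class"] == direction].itertuples()
            }
            pred = {
                (r.hybrid, r.tissue, r.gene_id)
                for r in additivity[additivity["class"] == cls].itertuples()
            }
            scores = _precision_recall(pred, truth_pos & tested, excluded=f1u_excluded)
            scores["n_truth"] = len(truth_pos)
            scores["n_truth_tested"] = len(truth_pos & tested)
            scores["recall_end_to_end"] = (
                len(pred & truth_pos) / len(truth_pos) if truth_pos else np.nan
            )
            out[direction] = scores
    return out


def write_bundles(bundles: list[DEGSetBundle], path) -> None:
    rows = []
    for b in bundles:
        for name, genes in (
            ("DEG2P", b.deg2p), ("DEGP1", b.degp1), ("DEGP2", b.degp2),
            ("DEGFu", b.degfu), ("DEGFu_sp", b.degfu_sp),
        ):
            for g in sorted(genes):
                rows.append((b.hybrid, b.tissue, name, g))
    df = pd.DataFrame(rows, columns=["#hybrid", "tissue", "set", "gene_id"])
    df.to_csv(path, sep="\t", index=False)
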