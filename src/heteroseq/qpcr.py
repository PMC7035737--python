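"""Relative qPCR quantification by the 2^-ddCt (Livak) method.

Replicate Ct values are averaged on the Ct scale; dCt = mean target Ct -
mean reference Ct per (sample, gene); ddCt = dCt_sample - dCt_calibrator;
RQ = 2**-ddCt.  Amplification efficiency is fixed at 2 (no correction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CT_COLUMNS = ["sample_id", "gene_id", "ct_target", "ct_reference", "replicate"]


def ddct(ct: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Relative quantities for a long Ct table against a calibrator sample.

    ``ct`` needs columns sample_id, gene_id, ct_target, ct_reference,
    replicate.  Returns one row per (sample, gene) with delta_ct, the
    replicate SD of dCt, ddct and rq; the calibrator's own RQ is 1 for
    every gene.  Missing reference Ct values raise per (sample, gene).
    """
    miss = ct[ct["ct_reference"].isna() | ct["ct_target"].isna()]
    if len(miss):
        first = miss.iloc[0]
        raise ValueError(
            f"missing Ct for sample {first['sample_id']!r}, gene {first['gene_id']!r}"
        )
    grp = ct.groupby(["sample_id", "gene_id"])
    per = grp.agg(
        ct_target=("ct_target", "mean"),
        ct_reference=("ct_reference", "mean"),
        n_replicates=("replicate", "size"),
    ).reset_index()
    per["delta_ct"] = per["ct_target"] - per["ct_reference"]
    dct_sd = grp.apply(
        lambda g: float(np.std(g["ct_target"] - g["ct_reference"], ddof=1))
        if len(g) > 1 else 0.0,
        include_groups=False,
    ).rename("delta_ct_sd")
    per = per.merge(dct_sd, on=["sample_id", "gene_id"])
    cal = per[per["sample_id"] == calibrator].set_index("gene_id")["delta_ct"]
    missing_cal = set(per["gene_id"]) - set(cal.index)
    if missing_cal:
        raise ValueError(f"calibrator {calibrator!r} missing for genes: {sorted(missing_cal)}")
    per["ddct"] = per["delta_ct"] - per["gene_id"].map(cal)
    per["rq"] = 2.0 ** (-per["ddct"])
    return per


def concordance(rq: pd.DataFrame, rnaseq_lfc: pd.DataFrame) -> dict:
    """Direction agreement between qPCR log2(RQ) and RNA-seq log2 fold change.

    Both inputs need a gene_id column; ``rq`` needs rq and ``rnaseq_lfc``
    needs log2fc.  Genes with a zero on either scale are uninformative and
    skipped.  Returns per-gene agreement and the overall fraction.
    """
    merged = rq.merge(rnaseq_lfc, on="gene_id", how="inner")
    if merged.empty:
        raise ValueError("no shared genes between qPCR and RNA-seq tables")
    log_rq = np.log2(merged["rq"].to_numpy(float))
    lfc = merged["log2fc"].to_numpy(float)
    informative = (log_rq != 0) & (lfc != 0)
    agree = np.sign(log_rq) == np.sign(lfc)
    per_gene = pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "log2_rq": log_rq,
            "log2fc": lfc,
            "agree": agree & informative,
            "informative": informative,
        }
    )
    n_inf = int(informative.sum())
    return {
        "per_gene": per_gene,
        "agreement": float(agree[informative].mean()) if n_inf else float("nan"),
        "n_informative": n_inf,
    }


def read_ct_table(path) -> pd.DataFrame:
    ct = pd.read_csv(path, sep="\t")
    ct.columns = [c.lstrip("#") for c in ct.columns]
    bad = ct[(ct["ct_target"] <= 0) | (ct["ct_target"] > 45)]
    if len(bad):
        first = bad.iloc[0]
        raise ValueError(
            f"Ct out of range (0, 45] for sample {first['sample_id']!r}, "
            f"gene {first['gene_id']!r}"
        )
    return ct[CT_COLUMNS]
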