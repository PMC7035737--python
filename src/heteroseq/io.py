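"""Reading and writing expression data, FPKM computation, and replicate QC.

Count matrices are plain tab-delimited text with gene rows and sample
columns; sample sheets bind each column to a (hybrid, genotype, tissue,
replicate) condition.  Gene catalogues carry 1-based inclusive coordinates
internally (GFF3 convention); BED files are converted at the boundary.
"""

from __future__ import annotations

import json
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPES = ("P1", "P2", "F1")

#: default tissue codes: four tissues at flowering (0-) and 5 days after (5-);
#: L flag leaf, S leaf sheath, P spikelet, Z main panicle axis
DEFAULT_TISSUES = ("0-L", "0-S", "0-P", "0-Z", "5-L", "5-S", "5-P", "5-Z")

SHEET_COLUMNS = ["sample_id", "hybrid", "genotype", "tissue", "replicate"]
CATALOG_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "length"]


class FormatError(ValueError):
    """Malformed input file (non-integer counts, bad coordinates, ...)."""


class ConsistencyError(ValueError):
    """Sample sheet and count matrix disagree."""


class AnnotationError(KeyError):
    """A gene referenced by the counts is missing from the catalogue."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but statistically unusable (e.g. empty library)."""


# ---------------------------------------------------------------------------
# counts + sample sheet I/O

def read_counts(path, sheet_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a count matrix and its sample sheet; validate their consistency.

    Returns ``(counts, sheet)`` where counts is a genes x samples integer
    DataFrame and sheet has one row per sample.  Raises :class:`FormatError`
    for non-integer or negative counts and :class:`ConsistencyError` when
    sheet sample ids and matrix columns differ (the error names offenders).
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    raw.index.name = "gene_id"
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.floor(vals))
        if bad.any():
            gene = raw.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"non-integer or negative count at gene {gene!r}, sample {col!r}: "
                f"{raw.loc[gene, col]!r}"
            )
    counts = raw.astype(np.int64)
    sheet = read_sample_sheet(sheet_path)
    validate_counts_sheet(counts, sheet)
    return counts, sheet


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    sheet.columns = [c.lstrip("#") for c in sheet.columns]
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    bad_geno = set(sheet["genotype"]) - set(GENOTYPES)
    if bad_geno:
        raise FormatError(f"unknown genotypes in sample sheet: {sorted(bad_geno)}")
    key = sheet[["hybrid", "genotype", "tissue", "replicate"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise ConsistencyError(f"duplicate (hybrid, genotype, tissue, replicate): {dup}")
    return sheet[SHEET_COLUMNS]


def validate_counts_sheet(counts: pd.DataFrame, sheet: pd.DataFrame) -> None:
    matrix_ids = set(counts.columns)
    sheet_ids = set(sheet["sample_id"])
    if matrix_ids != sheet_ids:
        only_matrix = sorted(matrix_ids - sheet_ids)
        only_sheet = sorted(sheet_ids - matrix_ids)
        raise ConsistencyError(
            f"sample sheet / count matrix mismatch: only in matrix {only_matrix}, "
            f"only in sheet {only_sheet}"
        )


def write_counts(counts: pd.DataFrame, sheet: pd.DataFrame, path, sheet_path) -> None:
    out = counts.copy()
    out.index.name = "#gene_id"
    out.to_csv(path, sep="\t")
    s = sheet.copy()
    s.columns = ["#sample_id"] + list(s.columns[1:])
    s.to_csv(sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene catalogue I/O

def _validate_catalog(cat: pd.DataFrame) -> pd.DataFrame:
    if cat["gene_id"].duplicated().any():
        dup = cat.loc[cat["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene id in catalogue: {dup!r}")
    if (cat["start"] > cat["end"]).any():
        bad = cat[cat["start"] > cat["end"]].iloc[0]
        raise FormatError(f"start > end for gene {bad['gene_id']!r}")
    if (cat["length"] < 1).any():
        bad = cat[cat["length"] < 1].iloc[0]
        raise FormatError(f"length < 1 for gene {bad['gene_id']!r}")
    return cat.reset_index(drop=True)


def read_catalog(path) -> pd.DataFrame:
    """Read a gene catalogue TSV (1-based inclusive coordinates)."""
    cat = pd.read_csv(path, sep="\t")
    cat.columns = [c.lstrip("#") for c in cat.columns]
    if "length" not in cat.columns:
        cat["length"] = cat["end"] - cat["start"] + 1
    return _validate_catalog(cat[CATALOG_COLUMNS])


def write_catalog(cat: pd.DataFrame, path) -> None:
    out = cat[CATALOG_COLUMNS].copy()
    out.columns = ["#gene_id"] + CATALOG_COLUMNS[1:]
    out.to_csv(path, sep="\t", index=False)


def read_catalog_bed(path) -> pd.DataFrame:
    """Read a 6-column BED (0-based half-open) into 1-based inclusive records."""
    bed = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    cat = pd.DataFrame(
        {
            "gene_id": bed["gene_id"],
            "chrom": bed["chrom"],
            "start": bed["start"] + 1,
            "end": bed["end"],
            "strand": bed["strand"],
        }
    )
    cat["length"] = cat["end"] - cat["start"] + 1
    return _validate_catalog(cat[CATALOG_COLUMNS])


def write_catalog_bed(cat: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": cat["chrom"],
            "start": cat["start"] - 1,  # to 0-based half-open
            "end": cat["end"],
            "gene_id": cat["gene_id"],
            "score": 0,
            "strand": cat["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_catalog_gff3(path) -> pd.DataFrame:
    """Read gene-level features from a GFF3 file (type == 'gene')."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("Name")
            if gid is None:
                raise FormatError(f"gene feature without ID attribute: {line!r}")
            rows.append((gid, f[0], int(f[3]), int(f[4]), f[6]))
    cat = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    cat["length"] = cat["end"] - cat["start"] + 1
    return _validate_catalog(cat[CATALOG_COLUMNS])


# ---------------------------------------------------------------------------
# FPKM

def compute_fpkm(counts: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """FPKM[g, s] = counts[g, s] * 1e9 / (length_g * total_counts_s).

    Every gene row must have a catalogue length (AnnotationError otherwise);
    a sample with zero total counts is a degenerate input.
    """
    lengths = catalog.set_index("gene_id")["length"]
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise AnnotationError(
            f"{len(missing)} genes missing from catalogue, e.g. {list(missing[:5])}"
        )
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise DegenerateInputError(f"zero library size for samples: {list(zero.index)}")
    L = lengths.reindex(counts.index).to_numpy()[:, None].astype(float)
    fpkm = counts.to_numpy(dtype=float) * 1e9 / (L * totals.to_numpy()[None, :])
    return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# replicate QC

def replicate_qc(expr: pd.DataFrame, sheet: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Within-condition replicate correlation on log2(FPKM + 1).

    For every (hybrid, genotype, tissue) with >= 2 replicates, Pearson r is
    computed for each replicate pair; pairs with r strictly below ``threshold``
    are flagged.  Constant (zero-variance) vectors yield an undefined r and
    are flagged with reason ``"zero variance"``.

    Returns a long DataFrame with one row per replicate pair and columns
    hybrid, genotype, tissue, sample_a, sample_b, r, flagged, reason.
    """
    logged = np.log2(expr + 1.0)
    rows = []
    for (hyb, geno, tissue), grp in sheet.groupby(["hybrid", "genotype", "tissue"]):
        samples = list(grp["sample_id"])
        for a, b in combinations(samples, 2):
            x, y = logged[a].to_numpy(), logged[b].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append((hyb, geno, tissue, a, b, np.nan, True, "zero variance"))
                continue
            r = stats.pearsonr(x, y).statistic
            flagged = bool(r < threshold)
            rows.append(
                (hyb, geno, tissue, a, b, r, flagged, "low correlation" if flagged else "")
            )
    return pd.DataFrame(
        rows,
        columns=["hybrid", "genotype", "tissue", "sample_a", "sample_b", "r", "flagged", "reason"],
    )


def qc_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Min/median r per condition from a replicate_qc report."""
    return (
        report.groupby(["hybrid", "genotype", "tissue"])["r"]
        .agg(min_r="min", median_r="median", n_pairs="size")
        .reset_index()
    )


def write_qc_report(report: pd.DataFrame, tsv_path, json_path=None) -> None:
    out = report.copy()
    out.columns = ["#hybrid"] + list(out.columns[1:])
    out.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        summary = qc_summary(report)
        payload = {
            "n_pairs": int(len(report)),
            "n_flagged": int(report["flagged"].sum()),
            "conditions": summary.to_dict(orient="records"),
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
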