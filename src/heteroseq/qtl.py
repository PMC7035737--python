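"""Gene-to-QTL interval mapping.

QTL catalogues are tables of (id, trait category, chromosome, start, end)
with 1-based inclusive coordinates.  Genes are mapped onto an interval
index; the default rule counts any shared base pair as a hit, with a
full-containment alternative.  Hits can be filtered to a trait list (for
yield-related analyses) and intersected across experiments.
"""

from __future__ import annotations

import warnings

import pandas as pd
from intervaltree import IntervalTree

from .simulate import YIELD_TRAITS

QTL_COLUMNS = ["qtl_id", "trait", "chrom", "start", "end"]


def normalize_chrom(name: str) -> str:
    """Case-insensitive chromosome naming with optional 'chr' prefix stripped
    and numeric names zero-padding removed ('Chr01' == 'chr1' == '1')."""
    s = str(name).lower()
    if s.startswith("chr"):
        s = s[3:]
    return s.lstrip("0") or s


class QTLIndex:
    """Interval index over a QTL catalogue; queries return overlapping records."""

    def __init__(self, qtls: pd.DataFrame):
        if qtls["qtl_id"].duplicated().any():
            dup = qtls.loc[qtls["qtl_id"].duplicated(), "qtl_id"].iloc[0]
            raise ValueError(f"duplicate QTL id {dup!r}")
        if (qtls["start"] > qtls["end"]).any():
            bad = qtls[qtls["start"] > qtls["end"]].iloc[0]
            raise ValueError(f"start > end for QTL {bad['qtl_id']!r}")
        self.records = qtls.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for row in self.records.itertuples():
            tree = self._trees.setdefault(normalize_chrom(row.chrom), IntervalTree())
            # inclusive coordinates -> half-open for the tree
            tree.addi(row.start, row.end + 1, (row.qtl_id, row.trait))

    def query(self, chrom: str, start: int, end: int) -> list[tuple[str, str]]:
        """QTLs overlapping [start, end] (1-based inclusive) by >= 1 bp."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end + 1)))

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)


def build_index(qtls: pd.DataFrame) -> QTLIndex:
    return QTLIndex(qtls)


def map_genes(
    genes: pd.DataFrame,
    index: QTLIndex,
    overlap_rule: str = "any_overlap",
    source_label: str = "",
) -> pd.DataFrame:
    """Map a gene catalogue subset onto the QTL index.

    Returns one row per hit QTL: qtl_id, trait, n_genes, genes (semicolon-
    joined, sorted), source.  Genes on chromosomes absent from the catalogue
    are left unmapped with a warning.
    """
    if overlap_rule not in ("any_overlap", "contained"):
        raise ValueError(f"unknown overlap rule {overlap_rule!r}")
    missing_chroms = {
        c for c in genes["chrom"].unique() if normalize_chrom(c) not in index.chromosomes
    }
    if missing_chroms:
        warnings.warn(
            f"chromosomes absent from QTL catalogue, genes unmapped: {sorted(missing_chroms)}",
            RuntimeWarning,
            stacklevel=2,
        )
    bounds = {
        row.qtl_id: (row.start, row.end) for row in index.records.itertuples()
    }
    traits = dict(zip(index.records["qtl_id"], index.records["trait"]))
    hits: dict[str, set] = {}
    for row in genes.itertuples():
        for qtl_id, _trait in index.query(row.chrom, row.start, row.end):
            if overlap_rule == "contained":
                qs, qe = bounds[qtl_id]
                if not (qs <= row.start and row.end <= qe):
                    continue
            hits.setdefault(qtl_id, set()).add(row.gene_id)
    rows = [
        (qtl_id, traits[qtl_id], len(gset), ";".join(sorted(gset)), source_label)
        for qtl_id, gset in sorted(hits.items())
    ]
    return pd.DataFrame(rows, columns=["qtl_id", "trait", "n_genes", "genes", "source"])


def filter_and_intersect(
    hits_by_experiment: dict[str, pd.DataFrame],
    traits: tuple[str, ...] = YIELD_TRAITS,
    valid_traits: set[str] | None = None,
) -> dict:
    """Restrict hits to a trait list and intersect QTL ids across experiments.

    Returns a dict with the filtered hits, the common QTL id set, and a
    per-chromosome tally of the common QTLs (requires the original records
    via ``valid_traits``/... to be embedded in the hit tables' traits).
    """
    if not hits_by_experiment:
        raise ValueError("at least one experiment required")
    if valid_traits is not None:
        unknown = set(traits) - set(valid_traits)
        if unknown:
            raise ValueError(
                f"unknown trait(s) {sorted(unknown)}; valid: {sorted(valid_traits)}"
            )
    filtered = {
        name: df[df["trait"].isin(traits)].reset_index(drop=True)
        for name, df in hits_by_experiment.items()
    }
    id_sets = [set(df["qtl_id"]) for df in filtered.values()]
    common = set.intersection(*id_sets) if id_sets else set()
    return {"filtered": filtered, "common_qtls": sorted(common)}


def per_chromosome_tally(qtls: pd.DataFrame, qtl_ids) -> pd.DataFrame:
    """Count QTLs per chromosome for a set of ids (Fig.-3-style tally)."""
    sub = qtls[qtls["qtl_id"].isin(set(qtl_ids))]
    tally = sub.groupby("chrom", sort=True).size().rename("n_qtls").reset_index()
    return tally


def read_qtl_catalog(path) -> pd.DataFrame:
    qtls = pd.read_csv(path, sep="\t")
    qtls.columns = [c.lstrip("#") for c in qtls.columns]
    return qtls[QTL_COLUMNS]
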