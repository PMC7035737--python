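"""Keyword-based functional categorization, gene-list overlaps, and
hypergeometric over-representation tests.

The categorizer assigns genes to functional categories (kinase, synthase,
disease resistance, transcription factor by default) by case-insensitive
whole-word keyword matching on free-text descriptions; a gene receives
every matching category.  Term enrichment is a one-sided (upper-tail)
hypergeometric test with BH correction across terms.
"""

from __future__ import annotations

from itertools import combinations
import re

import pandas as pd
from scipy import stats

from .de import bh_adjust

DEFAULT_CATEGORIES: dict[str, list[str]] = {
    "kinase": ["kinase"],
    "synthase": ["synthase"],
    "resistance": ["NBS-LRR", "disease resistance", "LRR receptor"],
    "transcription_factor": ["transcription factor"],
}


def _keyword_pattern(keywords: list[str]) -> re.Pattern:
    alts = "|".join(re.escape(k) for k in keywords)
    return re.compile(rf"\b(?:{alts})\b", re.IGNORECASE)


def keyword_categorize(
    annotations: pd.DataFrame,
    categories: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Multi-label keyword categorization of gene descriptions.

    ``annotations`` needs columns gene_id, description (unique ids).
    Returns a long DataFrame (gene_id, category), one row per assignment;
    per-category counts are available via ``value_counts("category")``.
    """
    categories = categories if categories is not None else DEFAULT_CATEGORIES
    for name, kws in categories.items():
        if not kws:
            raise ValueError(f"empty keyword list for category {name!r}")
    if annotations["gene_id"].duplicated().any():
        dup = annotations.loc[annotations["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id in annotations: {dup!r}")
    patterns = {name: _keyword_pattern(kws) for name, kws in categories.items()}
    rows = []
    for row in annotations.itertuples():
        desc = str(row.description)
        for name, pat in patterns.items():
            if pat.search(desc):
                rows.append((row.gene_id, name))
    return pd.DataFrame(rows, columns=["gene_id", "category"])


def set_overlap(lists: dict[str, set]) -> dict:
    """Venn-style overlap report for named gene lists.

    Returns sizes, all pairwise (and higher-order) intersection counts keyed
    by the sorted tuple of list names, and per-gene membership flags.
    """
    names = sorted(lists)
    sets = {n: set(lists[n]) for n in names}
    inter: dict[tuple[str, ...], int] = {}
    for k in range(2, len(names) + 1):
        for combo in combinations(names, k):
            inter[combo] = len(set.intersection(*(sets[n] for n in combo)))
    universe = sorted(set.union(*sets.values())) if sets else []
    membership = pd.DataFrame(
        {n: [g in sets[n] for g in universe] for n in names},
        index=pd.Index(universe, name="gene_id"),
    )
    return {
        "sizes": {n: len(sets[n]) for n in names},
        "intersections": inter,
        "membership": membership,
    }


def hypergeom_enrich(
    query: set,
    universe: set,
    term2gene: dict[str, set],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per term.

    P(X >= k) with k the query/term overlap, drawn from a universe of size M
    containing n term genes, sampling N = |query|.  BH-adjusted across
    terms; sorted by FDR then term id.
    """
    query, universe = set(query), set(universe)
    outside = query - universe
    if outside:
        raise ValueError(f"query genes outside universe: {sorted(outside)[:5]}")
    M, N = len(universe), len(query)
    rows = []
    for term, genes in term2gene.items():
        genes = set(genes) & universe
        k = len(query & genes)
        p = float(stats.hypergeom.sf(k - 1, M, len(genes), N))
        rows.append((term, len(genes), k, p))
    res = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"])
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    return res.sort_values(["fdr", "term"], kind="stable").reset_index(drop=True)


def read_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    ann.columns = [c.lstrip("#") for c in ann.columns]
    return ann[["gene_id", "description"]]


def read_term2gene(path) -> dict[str, set]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["term", "gene_id"])
    return {term: set(grp["gene_id"]) for term, grp in df.groupby("term")}
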