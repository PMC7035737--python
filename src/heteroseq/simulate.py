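"""Synthetic trio expression experiments with planted ground truth.

The generator emulates a two-hybrid rice heterosis design: for each hybrid,
the two parents (P1, P2) and their F1 are profiled in eight tissue contexts
(four tissues at flowering and five days after) with three biological
replicates, and counts follow a negative-binomial model
``var = mu + alpha * mu**2``.

Planted expression classes per (hybrid, tissue, gene):

``null``
    mu_P1 = mu_P2 = mu_F1 (no signal).
``parent_diff``
    parents differ by the planted effect (mu_P1 / mu_P2 = 2**e); the F1
    follows P1 (dominance toward one parent).
``additive``
    parents differ by the planted effect and the F1 sits exactly at the
    mid-parent value (mu_P1 + mu_P2) / 2.
``f1_unique``
    parents equal, F1 deviates from both by the planted effect (sign
    alternating).  Because the parents are equal, these genes necessarily
    also deviate from the mid-parent value; they are therefore excluded
    from the additive/non-additive scoring truth (an F1-unique gene cannot
    be distinguished from a non-additive one at the expression level).
``nonadd_up`` / ``nonadd_down``
    parents equal, F1 = mid-parent * 2**(+/- e).

Class labels are allocated deterministically by largest-remainder rounding
of the configured fractions, so planted counts per tissue are exact.  The
block of effect genes is rotated between tissue contexts; consecutive
contexts share a configurable fraction of their effect block so that
tissue-specific (exactly-one-context) and shared F1-unique genes both occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DEFAULT_TISSUES

CLASS_ORDER = ("parent_diff", "additive", "f1_unique", "nonadd_up", "nonadd_down")
F1_UNIQUE_CLASSES = frozenset({"f1_unique", "nonadd_up", "nonadd_down"})

DEFAULT_CLASS_FRACTIONS = {
    "null": 0.70,
    "parent_diff": 0.10,
    "additive": 0.04,
    "f1_unique": 0.06,
    "nonadd_up": 0.05,
    "nonadd_down": 0.05,
}

#: the seven yield-related QTL trait categories
YIELD_TRAITS = ("TBIOMYLD", "BIOMYLD", "FGRNB", "GRNB", "PNNB", "SDSPCENT", "TGRWT")

TRUTH_COLUMNS = [
    "hybrid", "tissue", "gene_id", "class",
    "log2_p1_p2", "log2_f1_mpv", "mu_p1", "mu_p2", "mu_f1",
]


class SizingError(ValueError):
    """Requested genes do not fit on the chromosomes at minimum spacing."""


class DesignError(ValueError):
    """Invalid experimental design parameters."""


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 2000
    n_chromosomes: int = 12
    chrom_length: int = 30_000_000
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    hybrids: tuple[str, ...] = ("H1xH8", "T485xH8")
    n_replicates: int = 3
    nb_mean_log_range: tuple[float, float] = (1.5, 3.0)  # log10 mean counts
    nb_dispersion: float = 0.1
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    effect_log2fc: float = 2.0
    shared_across_tissues: float = 0.1
    libsize_range: tuple[float, float] = (0.5, 2.0)
    min_gene_length: int = 200
    max_gene_length: int = 5000
    min_gap: int = 100
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions sum to {total}, expected 1")
        unknown = set(self.class_fractions) - ({"null"} | set(CLASS_ORDER))
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")
        if self.n_replicates < 2:
            raise DesignError("n_replicates must be >= 2")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        if not 0 <= self.shared_across_tissues <= 1:
            raise ValueError("shared_across_tissues must be in [0, 1]")


def largest_remainder_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Integer allocation of n items by largest-remainder rounding (deterministic)."""
    keys = sorted(fractions)
    quotas = np.array([fractions[k] * n for k in keys])
    base = np.floor(quotas).astype(int)
    leftover = n - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    for i in order[:leftover]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


# ---------------------------------------------------------------------------
# annotation

def simulate_annotation(config: SimConfig) -> pd.DataFrame:
    """Non-overlapping single-exon genes on n_chromosomes, 1-based inclusive.

    Deterministic for a fixed seed; raises :class:`SizingError` when the
    genes cannot fit at minimum length and spacing.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(config.seed)
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    rows = []
    gid = 0
    for ci in range(config.n_chromosomes):
        k = int(per_chrom[ci])
        chrom = f"chr{ci + 1:02d}"
        if k == 0:
            continue
        min_needed = k * (config.min_gene_length + config.min_gap) + config.min_gap
        if min_needed > config.chrom_length:
            raise SizingError(
                f"{k} genes do not fit on {chrom} "
                f"({min_needed} bp needed, {config.chrom_length} available)"
            )
        lengths = rng.integers(config.min_gene_length, config.max_gene_length + 1, k)
        slack = config.chrom_length - int(lengths.sum()) - (k + 1) * config.min_gap
        if slack < 0:
            # drawn lengths overshoot: shrink uniformly toward the minimum
            lengths = np.full(k, config.min_gene_length)
            slack = config.chrom_length - int(lengths.sum()) - (k + 1) * config.min_gap
        extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
        pos = 1
        for j in range(k):
            pos += config.min_gap + int(extra[j])
            start = pos
            end = start + int(lengths[j]) - 1
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"g{gid:05d}", chrom, start, end, strand, end - start + 1))
            pos = end + 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "length"])


# ---------------------------------------------------------------------------
# trio counts

def _class_labels(config: SimConfig, n_genes: int, context_index: int) -> np.ndarray:
    """Deterministic class label vector for one (hybrid, tissue) context."""
    counts = largest_remainder_counts(config.class_fractions, n_genes)
    effect_block = []
    for cls in CLASS_ORDER:
        effect_block.extend([cls] * counts.get(cls, 0))
    n_eff = len(effect_block)
    labels = np.array(["null"] * n_genes, dtype=object)
    if n_eff == 0:
        return labels
    stride = max(1, int(round(n_eff * (1.0 - config.shared_across_tissues))))
    offset = (context_index * stride) % n_genes
    idx = (offset + np.arange(n_eff)) % n_genes
    labels[idx] = effect_block
    return labels


def _class_means(cls: str, mu: float, e: float, rank: int) -> tuple[float, float, float]:
    """Planted (mu_p1, mu_p2, mu_f1) for one gene; rank alternates f1_unique sign."""
    if cls == "null":
        return mu, mu, mu
    if cls == "parent_diff":
        p1, p2 = mu * 2 ** (e / 2), mu * 2 ** (-e / 2)
        return p1, p2, p1  # dominance toward P1
    if cls == "additive":
        p1, p2 = mu * 2 ** (e / 2), mu * 2 ** (-e / 2)
        return p1, p2, (p1 + p2) / 2
    if cls == "f1_unique":
        sign = 1.0 if rank % 2 == 0 else -1.0
        return mu, mu, mu * 2 ** (sign * e)
    if cls == "nonadd_up":
        return mu, mu, mu * 2 ** e
    if cls == "nonadd_down":
        return mu, mu, mu * 2 ** (-e)
    raise ValueError(f"unknown class {cls!r}")


def simulate_trio_counts(
    catalog: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (counts, sample_sheet, truth) for the full trio design.

    Counts are NB(size-factor x planted mean, alpha) draws; the sample sheet
    carries the true per-sample size factor in ``true_size_factor`` for
    oracle checks.  Truth has one row per (hybrid, tissue, gene) with the
    planted class, the planted log2 effects, and the planted means.
    """
    if len(catalog) == 0:
        raise ValueError("empty gene catalogue")
    rng = np.random.default_rng(config.seed + 1)
    genes = catalog["gene_id"].to_numpy()
    n = len(genes)
    alpha = config.nb_dispersion
    lo, hi = config.nb_mean_log_range

    sheet_rows, truth_rows, blocks, sample_ids = [], [], [], []
    context = 0
    for hybrid in config.hybrids:
        for tissue in config.tissues:
            labels = _class_labels(config, n, context)
            context += 1
            mu = 10 ** rng.uniform(lo, hi, n)
            rank_in_class: dict[str, int] = {}
            mu_p1 = np.empty(n)
            mu_p2 = np.empty(n)
            mu_f1 = np.empty(n)
            for i in range(n):
                cls = labels[i]
                r = rank_in_class.get(cls, 0)
                rank_in_class[cls] = r + 1
                mu_p1[i], mu_p2[i], mu_f1[i] = _class_means(
                    cls, mu[i], config.effect_log2fc, r
                )
            mpv = (mu_p1 + mu_p2) / 2
            for gi in range(n):
                truth_rows.append(
                    (
                        hybrid, tissue, genes[gi], labels[gi],
                        np.log2(mu_p1[gi] / mu_p2[gi]),
                        np.log2(mu_f1[gi] / mpv[gi]),
                        mu_p1[gi], mu_p2[gi], mu_f1[gi],
                    )
                )
            for geno, mu_g in (("P1", mu_p1), ("P2", mu_p2), ("F1", mu_f1)):
                for rep in range(1, config.n_replicates + 1):
                    sid = f"{hybrid}_{geno}_{tissue}_r{rep}"
                    s = np.exp(rng.uniform(*np.log(config.libsize_range)))
                    m = s * mu_g
                    if alpha > 0:
                        r_nb = 1.0 / alpha
                        col = rng.negative_binomial(r_nb, r_nb / (r_nb + m))
                    else:
                        col = rng.poisson(m)
                    blocks.append(col)
                    sample_ids.append(sid)
                    sheet_rows.append((sid, hybrid, geno, tissue, rep, s))

    counts = pd.DataFrame(
        np.column_stack(blocks), index=pd.Index(genes, name="gene_id"), columns=sample_ids
    )
    sheet = pd.DataFrame(
        sheet_rows,
        columns=["sample_id", "hybrid", "genotype", "tissue", "replicate", "true_size_factor"],
    )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return counts, sheet, truth


# ---------------------------------------------------------------------------
# phenotypes

def simulate_traits(
    crosses: list[str],
    effects: dict[str, dict],
    n_plants: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-plant Gaussian trait tables with planted heterosis.

    ``effects`` maps trait name to a dict with keys ``p1_mean``, ``p2_mean``,
    ``cv`` (SD/mean, may be 0) and either ``mph_pct`` or ``hph_pct``; the F1
    population mean is chosen so the planted heterosis holds exactly.
    Returns a long DataFrame (cross, role, trait, plant, value).
    """
    if n_plants < 3:
        raise DesignError("n_plants must be >= 3")
    rng = np.random.default_rng(seed)
    rows = []
    for cross in crosses:
        for trait, spec in effects.items():
            p1, p2 = float(spec["p1_mean"]), float(spec["p2_mean"])
            if p1 <= 0 or p2 <= 0:
                raise ValueError(f"parent means must be positive for {trait!r}")
            if "mph_pct" in spec:
                f1 = (p1 + p2) / 2 * (1 + spec["mph_pct"] / 100.0)
            elif "hph_pct" in spec:
                f1 = max(p1, p2) * (1 + spec["hph_pct"] / 100.0)
            else:
                raise ValueError(f"effect for {trait!r} needs mph_pct or hph_pct")
            if f1 <= 0:
                raise ValueError(f"planted effect gives non-positive F1 mean for {trait!r}")
            cv = float(spec.get("cv", 0.0))
            for role, mean in (("P1", p1), ("P2", p2), ("F1", f1)):
                vals = mean + rng.normal(0.0, cv * mean, n_plants)
                for i, v in enumerate(vals, 1):
                    rows.append((cross, role, trait, i, v))
    return pd.DataFrame(rows, columns=["cross", "role", "trait", "plant", "value"])


# ---------------------------------------------------------------------------
# QTL catalogue

def simulate_qtl_catalog(
    catalog: pd.DataFrame,
    n_qtl: int,
    traits: tuple[str, ...] = YIELD_TRAITS,
    seed: int = 0,
    max_genes_per_qtl: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """QTL intervals each covering a known run of consecutive genes.

    Interval ends are placed inside the intergenic gaps flanking the chosen
    gene run, so the set of overlapping genes is exactly the recorded
    membership.  Returns (qtl_catalog, membership) where membership has one
    row per (qtl_id, gene_id).
    """
    if len(catalog) == 0:
        raise ValueError("empty gene catalogue")
    if n_qtl < 1:
        raise ValueError("n_qtl must be >= 1")
    if not traits:
        raise ValueError("traits must be non-empty")
    rng = np.random.default_rng(seed)
    cat = catalog.sort_values(["chrom", "start"]).reset_index(drop=True)
    qtl_rows, member_rows = [], []
    for i in range(n_qtl):
        j = int(rng.integers(len(cat)))
        chrom = cat.at[j, "chrom"]
        same = cat[cat["chrom"] == chrom]
        k = int(rng.integers(1, max_genes_per_qtl + 1))
        pos = same.index.get_loc(j)
        run = same.iloc[pos : pos + k]
        first, last = run.iloc[0], run.iloc[-1]
        prev_end = same.iloc[pos - 1]["end"] if pos > 0 else 0
        next_start = (
            same.iloc[pos + len(run)]["start"]
            if pos + len(run) < len(same)
            else last["end"] + 10_000
        )
        start = int(rng.integers(prev_end + 1, first["start"] + 1))
        end = int(rng.integers(last["end"], next_start))
        qid = f"AQ{i + 1:04d}"
        qtl_rows.append((qid, traits[i % len(traits)], chrom, start, end))
        for g in run["gene_id"]:
            member_rows.append((qid, g))
    qtls = pd.DataFrame(qtl_rows, columns=["qtl_id", "trait", "chrom", "start", "end"])
    members = pd.DataFrame(member_rows, columns=["qtl_id", "gene_id"])
    return qtls, members


# ---------------------------------------------------------------------------
# qPCR Ct tables

def simulate_qpcr(
    truth: pd.DataFrame,
    hybrid: str,
    tissue: str,
    genes: list[str] | None = None,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    ref_ct: float = 20.0,
    base_ct: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct tables whose 2^-ddCt inverts to the planted expression ratios.

    For each of the samples P1, P2, F1 of one (hybrid, tissue) context the
    target Ct is ``base_ct - log2(planted mean)`` plus a per-sample drift
    (which cancels in dCt) and optional Gaussian replicate noise; the
    reference gene Ct is constant apart from the same drift.  With
    ``noise_sd = 0`` the relative quantity of sample s versus a calibrator c
    equals mu_s / mu_c exactly.
    """
    rng = np.random.default_rng(seed)
    sub = truth[(truth["hybrid"] == hybrid) & (truth["tissue"] == tissue)]
    if genes is None:
        genes = sub.loc[sub["class"] != "null", "gene_id"].head(8).tolist()
    sub = sub.set_index("gene_id").loc[genes]
    rows = []
    for sample, col in (("P1", "mu_p1"), ("P2", "mu_p2"), ("F1", "mu_f1")):
        drift = rng.uniform(-1.0, 1.0)
        for g in genes:
            target = base_ct - np.log2(sub.at[g, col]) + drift
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (
                        sample, g,
                        target + rng.normal(0.0, noise_sd),
                        ref_ct + drift + rng.normal(0.0, noise_sd),
                        rep,
                    )
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "gene_id", "ct_target", "ct_reference", "replicate"]
    )


# ---------------------------------------------------------------------------
# writers (all text, tab-delimited, '#'-prefixed headers)

def _write_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.columns = ["#" + str(out.columns[0])] + [str(c) for c in out.columns[1:]]
    out.to_csv(path, sep="\t", index=False)


write_truth = _write_tsv
write_qtl_catalog = _write_tsv
write_trait_table = _write_tsv
write_ct_table = _write_tsv
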