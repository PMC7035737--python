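"""Two-group differential expression on counts.

The call rule follows the study design this package targets: a gene is
differentially expressed when its Benjamini-Hochberg FDR is strictly below
0.01 and the absolute fold change is at least 2 (|log2FC| >= 1).

The test itself is an exact conditional negative-binomial test: counts are
normalized by median-of-ratios size factors, rounded to pseudo-counts, and
summed per group; conditional on the two-group total T, the probability of
each split (a, T - a) under the null of equal means depends only on the
group sizes and the common dispersion alpha (the NB success probability
cancels), giving a beta-binomial-shaped conditional distribution

    P(a | T)  proportional to  C(a + rA - 1, a) * C(T - a + rB - 1, T - a)

with rA = nA / alpha, rB = nB / alpha.  At alpha = 0 this reduces to the
binomial conditional (Poisson) test.  The two-sided p-value sums every split
whose conditional probability does not exceed that of the observed split
(within a fixed 1e-8 relative tolerance that absorbs floating-point ties at
exactly symmetric splits).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

#: relative tolerance in the "as or more extreme" comparison; part of the
#: test's definition (absorbs float ties at mathematically equal splits)
EXTREME_RTOL = 1e-8


class NormalizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# normalization

def estimate_size_factors(counts: pd.DataFrame, allow_fallback: bool = True) -> pd.Series:
    """Median-of-ratios size factors against the per-gene geometric mean.

    Genes with a zero in any sample are excluded from the reference.  If no
    gene is positive in every sample the estimator falls back (with a
    warning) to total-count ratios normalized to geometric mean 1, or raises
    when ``allow_fallback`` is False.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        if not allow_fallback:
            raise NormalizationError("no gene is nonzero in every sample")
        warnings.warn(
            "no all-nonzero gene; falling back to total-count normalization",
            RuntimeWarning,
            stacklevel=2,
        )
        totals = mat.sum(axis=0)
        if (totals == 0).any():
            raise NormalizationError("sample with zero total count")
        f = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(f, index=counts.columns, name="size_factor")
    ref = mat[all_pos]
    log_geo = np.mean(np.log(ref), axis=1)  # per-gene geometric mean, log scale
    log_ratio = np.log(ref) - log_geo[:, None]
    f = np.exp(np.median(log_ratio, axis=0))
    return pd.Series(f, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    groups: list[list[str]],
    trim: float = 0.05,
) -> float:
    """Common NB dispersion alpha by pooled method of moments.

    Per gene, the within-group variance of normalized counts is averaged
    over groups and compared to the overall normalized mean m via the NB
    moment relation var = m + alpha * m**2.  Per-gene estimates (clipped at
    0) are combined by a symmetric trimmed mean across genes; the trim is
    kept light (5% per side) because the per-gene moment estimates are
    right-skewed at few replicates and heavier symmetric trimming biases
    the pooled estimate downward.
    """
    q = counts / size_factors
    means, variances = [], []
    for g in groups:
        sub = q[g].to_numpy(dtype=float)
        means.append(sub.mean(axis=1))
        variances.append(sub.var(axis=1, ddof=1))
    m = np.mean(means, axis=0)
    v = np.mean(variances, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_g = (v - m) / (m * m)
    alpha_g = alpha_g[np.isfinite(alpha_g) & (m > 0)]
    if alpha_g.size == 0:
        return 0.0
    return float(max(stats.trim_mean(np.clip(alpha_g, 0.0, None), trim), 0.0))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (counts are non-negative here)."""
    return np.floor(np.abs(x) + 0.5) * np.sign(x)


# ---------------------------------------------------------------------------
# exact conditional test

def _conditional_log_weights(T: int, n_a: int, n_b: int, alpha: float) -> np.ndarray:
    """Unnormalized log conditional probabilities of splits a = 0..T."""
    a = np.arange(T + 1, dtype=float)
    if alpha > 0:
        r_a = n_a / alpha
        r_b = n_b / alpha
        lw = (
            gammaln(a + r_a) - gammaln(a + 1.0)
            + gammaln(T - a + r_b) - gammaln(T - a + 1.0)
        )
    else:  # Poisson limit: binomial(T, n_a / (n_a + n_b))
        p = n_a / (n_a + n_b)
        lw = (
            gammaln(T + 1.0) - gammaln(a + 1.0) - gammaln(T - a + 1.0)
            + a * np.log(p) + (T - a) * np.log1p(-p)
        )
    return lw


def nb_exact_pvalue(k_a: int, k_b: int, n_a: int, n_b: int, alpha: float) -> float:
    """Exact conditional two-sided p-value for one gene.

    ``k_a``/``k_b`` are group sums of normalized pseudo-counts, ``n_a``/``n_b``
    the group sizes.  Returns 1.0 for an all-zero gene.
    """
    if alpha < 0:
        raise ValueError("dispersion alpha must be >= 0")
    T = int(k_a) + int(k_b)
    if T == 0:
        return 1.0
    lw = _conditional_log_weights(T, n_a, n_b, alpha)
    w = np.exp(lw - lw.max())
    p_obs = w[int(k_a)]
    return float(w[w <= p_obs * (1.0 + EXTREME_RTOL)].sum() / w.sum())


def nb_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    size_factors: pd.Series,
    alpha: float,
) -> pd.DataFrame:
    """Per-gene exact conditional NB test of group A vs group B.

    Returns a DataFrame indexed by gene with columns ``p`` and ``untested``
    (True for all-zero genes, whose p is 1 by convention).
    """
    qa = _round_half_away(counts_a.to_numpy(float) / size_factors[counts_a.columns].to_numpy())
    qb = _round_half_away(counts_b.to_numpy(float) / size_factors[counts_b.columns].to_numpy())
    ka = qa.sum(axis=1).astype(np.int64)
    kb = qb.sum(axis=1).astype(np.int64)
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    p = np.ones(len(ka))
    untested = (ka + kb) == 0
    for i in np.flatnonzero(~untested):
        p[i] = nb_exact_pvalue(ka[i], kb[i], n_a, n_b, alpha)
    return pd.DataFrame({"p": p, "untested": untested}, index=counts_a.index)


# ---------------------------------------------------------------------------
# multiple testing and calling

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, position-stable, clipped at 1.

    NaN inputs propagate to NaN outputs (with a warning) and do not count
    toward the number of tests.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    nan = np.isnan(p)
    if nan.any():
        warnings.warn("NaN p-values propagated through BH adjustment", RuntimeWarning,
                      stacklevel=2)
    valid = ~nan
    if valid.any():
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return out


def call_deg(
    results: pd.DataFrame,
    fdr_threshold: float = 0.01,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Apply the DE call rule: FDR strictly < threshold AND |log2FC| >= threshold.

    Adds boolean ``call`` and string ``direction`` ('up' when B > A, 'down'
    otherwise, '' when not called) columns; returns a new DataFrame.
    """
    if fdr_threshold <= 0 or lfc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    res = results.copy()
    fdr = res["fdr"].to_numpy(float)
    lfc = res["log2fc"].to_numpy(float)
    call = (fdr < fdr_threshold) & (np.abs(lfc) >= lfc_threshold)
    call &= ~np.isnan(fdr) & ~np.isnan(lfc)
    res["call"] = call
    res["direction"] = np.where(~call, "", np.where(lfc > 0, "up", "down"))
    return res


def de_contrast(
    counts: pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
    size_factors: pd.Series | None = None,
    alpha: float | None = None,
    fdr_threshold: float = 0.01,
    lfc_threshold: float = 1.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Full two-group DE analysis: normalize, test, adjust, call.

    ``log2fc`` is B over A on size-factor-normalized group means with a
    0.5 pseudocount in numerator and denominator.  Size factors default to
    median-of-ratios over the union of the two groups; alpha defaults to the
    pooled method-of-moments estimate.
    """
    if set(samples_a) & set(samples_b):
        raise ValueError("groups must be disjoint")
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    sub = counts[list(samples_a) + list(samples_b)]
    if size_factors is None:
        size_factors = estimate_size_factors(sub)
    if alpha is None:
        alpha = estimate_dispersion(sub, size_factors, [list(samples_a), list(samples_b)])
    qa = counts[list(samples_a)] / size_factors[list(samples_a)]
    qb = counts[list(samples_b)] / size_factors[list(samples_b)]
    mean_a = qa.mean(axis=1)
    mean_b = qb.mean(axis=1)
    tested = nb_test(counts[list(samples_a)], counts[list(samples_b)], size_factors, alpha)
    res = pd.DataFrame(
        {
            "base_mean": (mean_a * len(samples_a) + mean_b * len(samples_b))
            / (len(samples_a) + len(samples_b)),
            "log2fc": np.log2((mean_b + pseudocount) / (mean_a + pseudocount)),
            "p": tested["p"],
            "untested": tested["untested"],
        },
        index=counts.index,
    )
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    res = call_deg(res, fdr_threshold, lfc_threshold)
    res.attrs["alpha"] = alpha
    return res


def write_de_results(res: pd.DataFrame, path) -> None:
    out = res[["base_mean", "log2fc", "p", "fdr", "call", "direction"]].copy()
    out.index.name = "#gene_id"
    out.to_csv(path, sep="\t")
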