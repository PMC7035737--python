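"""Mid-parent and high-parent heterosis with significance testing.

MPH = (F1 - MP) / MP * 100 with MP the parental average; HPH =
(F1 - HP) / HP * 100 with HP the better parent for the trait's direction
(larger_is_better by default).  Significance combines a one-way ANOVA
across the three lines with Welch t-tests of the F1 against the high
parent (for HPH) and against a per-replicate mid-parent construct
(P1_i + P2_i) / 2 (for MPH), flagged at the 0.05 and 0.01 levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def mph_hph(
    f1_mean: float,
    p1_mean: float,
    p2_mean: float,
    direction: str = "larger_is_better",
) -> tuple[float, float]:
    """Mid-parent and high-parent heterosis percentages.

    Returns (MPH%, HPH%); NaN with a raised ValueError avoided — a zero
    mid-parent or high-parent mean makes the ratio undefined and raises.
    """
    mp = (p1_mean + p2_mean) / 2.0
    if direction == "larger_is_better":
        hp = max(p1_mean, p2_mean)
    elif direction == "smaller_is_better":
        hp = min(p1_mean, p2_mean)
    else:
        raise ValueError(f"unknown trait direction {direction!r}")
    if mp == 0 or hp == 0:
        raise ZeroDivisionError("mid-parent or high-parent mean is zero; heterosis undefined")
    mph = (f1_mean - mp) / mp * 100.0
    hph = (f1_mean - hp) / hp * 100.0
    return mph, hph


def _welch_from_stats(m1, s1, n1, m2, s2, n2) -> float:
    if n1 < 2 or n2 < 2:
        raise ValueError("insufficient replication for Welch t-test")
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    return float(res.pvalue)


def _anova_from_stats(means, sds, ns) -> float:
    """One-way ANOVA F-test from group summaries (algebraically identical to
    scipy.stats.f_oneway on the raw data)."""
    means, sds, ns = map(np.asarray, (means, sds, ns))
    if (ns < 2).any():
        raise ValueError("insufficient replication for ANOVA")
    grand = np.sum(ns * means) / np.sum(ns)
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds**2))
    df_b = len(means) - 1
    df_w = int(np.sum(ns) - len(means))
    if ss_within == 0:
        return 1.0 if ss_between == 0 else 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(stats.f.sf(F, df_b, df_w))


def trait_significance(
    p1, p2, f1,
    direction: str = "larger_is_better",
    summary: bool = False,
) -> dict:
    """Per-trait tests across the {P1, P2, F1} groups.

    With ``summary=False`` each of p1/p2/f1 is an array of per-plant values;
    with ``summary=True`` each is a (mean, sd, n) triple.  Returns ANOVA p,
    Welch p of F1 vs the high parent, Welch p of F1 vs the mid-parent
    construct, and boolean flags at 0.05/0.01 for MPH and HPH.
    """
    if summary:
        (m1, s1, n1), (m2, s2, n2), (mf, sf, nf) = p1, p2, f1
        anova_p = _anova_from_stats([m1, m2, mf], [s1, s2, sf], [n1, n2, nf])
        hp_stats = (m1, s1, n1) if (m1 >= m2) == (direction == "larger_is_better") else (m2, s2, n2)
        hph_p = _welch_from_stats(mf, sf, nf, *hp_stats)
        # mid-parent construct from summaries: mean (m1+m2)/2, var (s1^2+s2^2)/4
        mp_mean = (m1 + m2) / 2.0
        mp_sd = np.sqrt((s1**2 + s2**2) / 4.0)
        mph_p = _welch_from_stats(mf, sf, nf, mp_mean, mp_sd, min(n1, n2))
    else:
        p1, p2, f1 = (np.asarray(x, dtype=float) for x in (p1, p2, f1))
        if min(len(p1), len(p2), len(f1)) < 2:
            raise ValueError("insufficient replication")
        anova_p = float(stats.f_oneway(p1, p2, f1).pvalue)
        if np.isnan(anova_p):  # identical groups: F = 0/0
            anova_p = 1.0
        hp = p1 if (p1.mean() >= p2.mean()) == (direction == "larger_is_better") else p2
        hph_p = float(stats.ttest_ind(f1, hp, equal_var=False).pvalue)
        n_pair = min(len(p1), len(p2))
        mp_vals = (p1[:n_pair] + p2[:n_pair]) / 2.0
        mph_p = float(stats.ttest_ind(f1, mp_vals, equal_var=False).pvalue)
    return {
        "anova_p": anova_p,
        "mph_p": mph_p,
        "hph_p": hph_p,
        "mph_sig_05": mph_p < 0.05,
        "mph_sig_01": mph_p < 0.01,
        "hph_sig_05": hph_p < 0.05,
        "hph_sig_01": hph_p < 0.01,
    }


def heterosis_table(
    obs: pd.DataFrame,
    directions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Heterosis report for a long per-plant trait table.

    ``obs`` needs columns cross, role (P1/P2/F1), trait, value; optional
    ``season`` columns are analyzed pooled (plain concatenation).
    ``directions`` overrides the larger_is_better default per trait.
    Returns one row per (cross, trait) with means, MPH%, HPH% and flags.
    """
    directions = directions or {}
    rows = []
    for (cross, trait), grp in obs.groupby(["cross", "trait"]):
        direction = directions.get(trait, "larger_is_better")
        vals = {role: sub["value"].to_numpy() for role, sub in grp.groupby("role")}
        missing = {"P1", "P2", "F1"} - set(vals)
        if missing:
            raise ValueError(f"({cross}, {trait}) missing roles: {sorted(missing)}")
        m1, m2, mf = vals["P1"].mean(), vals["P2"].mean(), vals["F1"].mean()
        try:
            mph, hph = mph_hph(mf, m1, m2, direction)
        except ZeroDivisionError:
            rows.append((cross, trait, m1, m2, mf, np.nan, np.nan,
                         False, False, False, False, "undefined: zero parent mean"))
            continue
        if np.all(vals["P1"] == vals["P1"][0]) and np.all(vals["F1"] == vals["F1"][0]) \
                and np.all(vals["P2"] == vals["P2"][0]):
            sig = {"mph_sig_05": False, "mph_sig_01": False,
                   "hph_sig_05": False, "hph_sig_01": False}
        else:
            sig = trait_significance(vals["P1"], vals["P2"], vals["F1"], direction)
        rows.append((cross, trait, m1, m2, mf, mph, hph,
                     sig["mph_sig_05"], sig["mph_sig_01"],
                     sig["hph_sig_05"], sig["hph_sig_01"], ""))
    return pd.DataFrame(
        rows,
        columns=["cross", "trait", "p1_mean", "p2_mean", "f1_mean", "mph_pct", "hph_pct",
                 "mph_sig_05", "mph_sig_01", "hph_sig_05", "hph_sig_01", "note"],
    )


def read_trait_table(path) -> pd.DataFrame:
    obs = pd.read_csv(path, sep="\t")
    obs.columns = [c.lstrip("#") for c in obs.columns]
    return obs
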