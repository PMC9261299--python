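"""Nutrient and prescription-drug screens against the delta-age statistic.

Nutrients: for every dietary component and every decade of life, the
Pearson correlation between intake and delta_age, BH-adjusted within each
decade bin.  Nutrient correlation profiles across bins are grouped by
agglomerative hierarchical clustering (Euclidean distance, complete
linkage), and individual nutrients can be tested by comparing intake
between the extreme delta_age groups (< -10 vs > +10 years).

Drugs: restricted to advanced age (70 to 85+), each drug's users'
delta_age distribution is compared with the whole subset's distribution
(users included — the conservative reading) by a two-sample
Kolmogorov-Smirnov test, BH-adjusted across drugs, and ranked by

    rank_score = log10(ks_p) * sign(median_shift).

Since log10(p) < 0, drugs whose users have *negative* median shift
(decelerated aging) receive *positive* scores; "most decelerating" means
the largest rank_score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError
from .mortality import DECADE_LABELS, assign_decade

logger = logging.getLogger(__name__)

EXTREME_CUT_YEARS = 10.0
DRUG_MIN_AGE = 70.0


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nutrient_screen(
    intakes: pd.DataFrame,
    delta_ages: pd.Series,
    ages: pd.Series,
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson r of intake vs delta_age per nutrient x decade bin.

    ``intakes`` is a participants x nutrients matrix (NaN = not surveyed).
    Cells with fewer than ``min_n`` participants or zero intake variance
    are left missing (logged), never imputed.  BH adjustment is applied
    within each decade bin across the nutrients tested in that bin.
    """
    common = intakes.index.intersection(delta_ages.index)
    intakes = intakes.loc[common]
    delta = delta_ages.loc[common]
    decades = assign_decade(ages.loc[common])
    rows = []
    for label in DECADE_LABELS:
        in_bin = decades == label
        for nutrient in intakes.columns:
            x = intakes.loc[in_bin, nutrient].dropna()
            if len(x) < min_n:
                logger.debug("%s / %s: only %d values", nutrient, label, len(x))
                rows.append(dict(nutrient=nutrient, decade=label, n=len(x),
                                 r=np.nan, p=np.nan))
                continue
            if x.nunique() == 1:
                logger.info("%s / %s: zero intake variance", nutrient, label)
                rows.append(dict(nutrient=nutrient, decade=label, n=len(x),
                                 r=np.nan, p=np.nan))
                continue
            res = stats.pearsonr(x.to_numpy(), delta.loc[x.index].to_numpy())
            rows.append(dict(nutrient=nutrient, decade=label, n=len(x),
                             r=float(res.statistic), p=float(res.pvalue)))
    df = pd.DataFrame(rows)
    df["adj_p"] = np.nan
    for label in DECADE_LABELS:
        sel = (df["decade"] == label) & df["p"].notna()
        if sel.any():
            df.loc[sel, "adj_p"] = bh_adjust(df.loc[sel, "p"].to_numpy())
    return df


def nutrient_profiles(screen_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the screen table to a nutrients x decade-bins matrix of r."""
    prof = screen_table.pivot(index="nutrient", columns="decade", values="r")
    return prof.reindex(columns=DECADE_LABELS)


def cluster_nutrients(
    profiles: pd.DataFrame, k: int = 5
) -> tuple[pd.Series, list[str]]:
    """Hierarchical clustering of nutrient correlation profiles.

    Euclidean distance, complete linkage, cut into ``k`` flat clusters.
    Rows containing missing cells are dropped (logged).  Returns cluster
    ids (1..k) per nutrient and the dendrogram leaf order.
    """
    full = profiles.dropna(axis=0)
    dropped = profiles.index.difference(full.index)
    if len(dropped):
        logger.info("dropping %d nutrient(s) with missing cells: %s",
                    len(dropped), list(dropped))
    if len(full) < k:
        raise ParameterError(f"need at least k={k} complete rows, got {len(full)}")
    linkage = hierarchy.linkage(full.to_numpy(), method="complete",
                                metric="euclidean")
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    order = hierarchy.leaves_list(linkage)
    assignments = pd.Series(labels, index=full.index, name="cluster_id")
    leaf_order = [full.index[i] for i in order]
    return assignments, leaf_order


def extreme_group_test(
    intake: pd.Series, delta_ages: pd.Series, cut: float = EXTREME_CUT_YEARS
) -> dict:
    """Student's t-test of intake between strongly decelerated and
    strongly accelerated participants (delta < -cut vs delta > +cut)."""
    common = intake.dropna().index.intersection(delta_ages.index)
    x = intake.loc[common]
    d = delta_ages.loc[common]
    low = x[d < -cut]  # decelerated aging
    high = x[d > cut]  # accelerated aging
    result = {
        "n_decelerated": len(low),
        "n_accelerated": len(high),
        "mean_decelerated": float(low.mean()) if len(low) else np.nan,
        "mean_accelerated": float(high.mean()) if len(high) else np.nan,
        "testable": len(low) >= 2 and len(high) >= 2,
    }
    if result["testable"]:
        if np.var(np.concatenate([low, high])) == 0:
            # identical constant intake on both sides: no evidence either way
            result.update(t=0.0, p=1.0)
        else:
            t, p = stats.ttest_ind(low, high, equal_var=True)
            result.update(t=float(t), p=float(p))
    else:
        result.update(t=np.nan, p=np.nan)
    return result


def drug_screen(
    drugs: pd.DataFrame,
    delta_ages: pd.Series,
    ages: pd.Series,
    min_age: float = DRUG_MIN_AGE,
    comparison: str = "all",
) -> pd.DataFrame:
    """KS screen of each drug's users against the elderly population.

    ``drugs`` is a long (participant_id, drug) table.  Participants with
    age >= min_age form the analysis subset; each participant contributes
    their delta_age once per distinct drug they use.  ``comparison`` is
    "all" (users compared to the entire subset, users included) or
    "nonusers".  Rows carry median_shift, ks_p, BH-adjusted p across all
    drugs tested, and rank_score (see module docstring).
    """
    if comparison not in {"all", "nonusers"}:
        raise ParameterError("comparison must be 'all' or 'nonusers'")
    elderly = delta_ages[ages.loc[delta_ages.index] >= min_age]
    if elderly.empty:
        raise ValidationError(f"no participants with age >= {min_age}")
    pop = elderly.to_numpy()
    rows = []
    for drug, grp in drugs.groupby("drug"):
        user_ids = elderly.index.intersection(grp["participant_id"].unique())
        if len(user_ids) == 0:
            continue
        users = elderly.loc[user_ids].to_numpy()
        if comparison == "all":
            ref = pop
        else:
            ref = elderly.drop(user_ids).to_numpy()
            if ref.size == 0:
                continue
        ks = stats.ks_2samp(users, ref)
        shift = float(np.median(users) - np.median(ref))
        rows.append(
            {
                "drug": drug,
                "n_users": len(user_ids),
                "median_shift": shift,
                "ks_stat": float(ks.statistic),
                "ks_p": float(min(ks.pvalue, 1.0)),
            }
        )
    df = pd.DataFrame(
        rows, columns=["drug", "n_users", "median_shift", "ks_stat", "ks_p"]
    )
    if df.empty:
        df["adj_p"] = []
        df["rank_score"] = []
        return df
    df["adj_p"] = bh_adjust(df["ks_p"].to_numpy())
    df["rank_score"] = np.log10(df["ks_p"]) * np.sign(df["median_shift"])
    # most decelerating first
    return df.sort_values("rank_score", ascending=False).reset_index(drop=True)


def volcano_table(screen_table: pd.DataFrame) -> pd.DataFrame:
    """x/y columns for a volcano layout: median shift vs -log10 KS p."""
    out = screen_table[["drug", "n_users", "median_shift"]].copy()
    out["neg_log10_p"] = -np.log10(screen_table["ks_p"])
    return out
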