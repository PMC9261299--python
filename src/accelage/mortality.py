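"""Aging-rate classes from delta-age quartiles and mortality association.

Participants (age >= 60 for the headline test) are split on the quartiles
of their delta_age distribution: top quartile = accelerated aging, bottom
quartile = decelerated, middle half = normal.  Association with vital
status is tested three ways: a chi-square test of equal death proportions
across the three classes (the 3-sample test for equality of proportions,
no continuity correction), per-decade two-sample t-tests of delta_age in
deceased vs alive, and per cause-of-death group mean shifts vs the alive.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

ACCELERATED = "accelerated"
NORMAL = "normal"
DECELERATED = "decelerated"

#: Half-open decade bins partitioning adult ages; the ordinal follows the
#: convention that [30, 40) is the "4th decade of life".  The top bin
#: absorbs the 85+ top-code.
DECADE_EDGES = [18, 30, 40, 50, 60, 70, 80, np.inf]
DECADE_LABELS = ["18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80-85+"]
DECADE_ORDINALS = {label: DECADE_EDGES[i] // 10 + 1 for i, label in enumerate(DECADE_LABELS)}


def assign_decade(ages: pd.Series) -> pd.Series:
    """Map each adult age to its decade bin label."""
    if (ages < DECADE_EDGES[0]).any():
        raise ValidationError("decade bins are defined for ages >= 18")
    out = pd.cut(
        ages, bins=DECADE_EDGES, labels=DECADE_LABELS, right=False, include_lowest=True
    )
    return out.astype(object).rename("decade")


def classify_aging(
    delta_ages: pd.Series,
    ages: pd.Series,
    min_age: float = 60.0,
) -> tuple[pd.Series, tuple[float, float]]:
    """Quartile-based aging classes on the min_age-filtered subset.

    Returns (classes, (q1, q3)).  Quartiles use linear interpolation; ties
    at a cutpoint go to the extreme class (delta >= Q3 accelerated,
    delta <= Q1 decelerated), which keeps the extreme classes nonempty.
    """
    ages = ages.loc[delta_ages.index]
    sub = delta_ages[ages >= min_age]
    if len(sub) < 4:
        raise ParameterError(
            f"need >= 4 participants above age {min_age}, got {len(sub)}"
        )
    if sub.nunique() == 1:
        raise DegenerateInputError("all delta_ages identical; quartiles undefined")
    q1, q3 = np.quantile(sub.to_numpy(), [0.25, 0.75])
    classes = pd.Series(NORMAL, index=sub.index, name="aging_class", dtype=object)
    classes[sub >= q3] = ACCELERATED
    classes[sub <= q1] = DECELERATED
    return classes, (float(q1), float(q3))


def proportion_test(
    classes: pd.Series, vital_status: pd.Series
) -> dict:
    """Chi-square test of equal death proportions across the three classes.

    Pearson chi-square on the 3x2 class-by-status contingency table with no
    continuity correction (df = 2).  Participants with unknown vital status
    are excluded (and counted in the log).
    """
    status = vital_status.loc[classes.index]
    known = status.isin(["alive", "deceased"])
    if (~known).any():
        logger.info("excluding %d participants with unknown vital status",
                    int((~known).sum()))
    classes, status = classes[known], status[known]
    counts = {}
    for cls in (ACCELERATED, NORMAL, DECELERATED):
        sel = classes == cls
        if not sel.any():
            raise ValidationError(f"aging class {cls!r} has no members")
        counts[cls] = (
            int((status[sel] == "deceased").sum()),
            int(sel.sum()),
        )
    table = np.array(
        [[d, n - d] for d, n in counts.values()], dtype=float
    )
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        # all alive or all deceased: proportions trivially equal
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    proportions = {cls: d / n for cls, (d, n) in counts.items()}
    return {
        "chi2": float(chi2),
        "p": float(p),
        "df": 2,
        "proportions": proportions,
        "counts": counts,
    }


def decade_tests(
    delta_ages: pd.Series, vital_status: pd.Series, ages: pd.Series
) -> pd.DataFrame:
    """Per-decade equal-variance t-tests of delta_age, deceased vs alive.

    Bins with fewer than two members on either side are reported as
    untestable rather than erroring.
    """
    status = vital_status.loc[delta_ages.index]
    decades = assign_decade(ages.loc[delta_ages.index])
    rows = []
    for label in DECADE_LABELS:
        sel = decades == label
        dead = delta_ages[sel & (status == "deceased")]
        alive = delta_ages[sel & (status == "alive")]
        row = {
            "decade": label,
            "ordinal": DECADE_ORDINALS[label],
            "n_alive": len(alive),
            "n_deceased": len(dead),
            "testable": len(dead) >= 2 and len(alive) >= 2,
        }
        if row["testable"]:
            t, p = stats.ttest_ind(dead, alive, equal_var=True)
            row.update(t=float(t), p=float(p),
                       mean_shift=float(dead.mean() - alive.mean()))
        else:
            row.update(t=np.nan, p=np.nan, mean_shift=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def cause_tests(
    delta_ages: pd.Series, cause_group: pd.Series, vital_status: pd.Series
) -> pd.DataFrame:
    """Mean delta_age shift of each cause-of-death group vs the alive.

    "Alive" here is presumed-alive: participants not recorded deceased, plus
    deceased participants without a cause group.  Groups need >= 2 members;
    the table is sorted by shift, largest (most accelerated) first.
    """
    status = vital_status.loc[delta_ages.index]
    causes = cause_group.loc[delta_ages.index]
    dead_with_cause = (status == "deceased") & causes.notna()
    alive = delta_ages[~dead_with_cause & (status != "unknown")]
    rows = []
    for cause in sorted(causes[dead_with_cause].dropna().unique()):
        grp = delta_ages[dead_with_cause & (causes == cause)]
        if len(grp) < 2:
            continue
        t, p = stats.ttest_ind(grp, alive, equal_var=True)
        rows.append(
            {
                "cause_group": cause,
                "n": len(grp),
                "mean_shift": float(grp.mean() - alive.mean()),
                "t": float(t),
                "p": float(p),
            }
        )
    df = pd.DataFrame(rows, columns=["cause_group", "n", "mean_shift", "t", "p"])
    return df.sort_values("mean_shift", ascending=False).reset_index(drop=True)
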