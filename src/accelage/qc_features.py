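"""Quality-control filters and hourly feature summarisation.

Inclusion rules for a participant's week of accelerometry:

a. the device was calibrated for every record of the week,
b. all 7 days are complete (1440 minutes each),
c. every day has at least 10% of its minutes with intensity > 0
   (>= 144 of 1440, evaluated per day),
d. the participant is aged 18 or older.

A retained week is reduced to 336 features: for each of the 7 x 24
(day, hour) cells, the maximum intensity and the sample variance
(denominator n-1) of that hour's 60 minute counts.  Feature order is
fixed: all ``max_d{day}_h{hour}`` columns (day-major, hour-minor,
day 1-7, hour 0-23), then all ``var_d{day}_h{hour}`` columns.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError
from .nhanes_io import ActivityWeek, Participant, DAYS_PER_WEEK

HOURS_PER_DAY = 24
MINUTES_PER_HOUR = 60
N_FEATURES = DAYS_PER_WEEK * HOURS_PER_DAY * 2  # 336

MIN_NONZERO_MINUTES = 144  # 10% of 1440, ties pass
MIN_AGE_YEARS = 18

RULE_CALIBRATED = "not_calibrated"
RULE_COMPLETE = "incomplete_week"
RULE_NONZERO = "insufficient_nonzero_minutes"
RULE_AGE = "under_18"


def feature_names() -> list[str]:
    """The fixed, documented ordering of the 336 feature columns."""
    names = [
        f"{kind}_d{day}_h{hour}"
        for kind in ("max", "var")
        for day in range(1, DAYS_PER_WEEK + 1)
        for hour in range(HOURS_PER_DAY)
    ]
    return names


def qc_filter(
    weeks: Mapping[int, ActivityWeek],
    participants: Mapping[int, Participant],
    min_age: int = MIN_AGE_YEARS,
    min_nonzero_minutes: int = MIN_NONZERO_MINUTES,
) -> tuple[dict[int, ActivityWeek], pd.DataFrame]:
    """Apply the inclusion rules; return retained weeks and an exclusion log.

    The log has one row per dropped week with the first rule that fired
    (checked in the order calibration, completeness, nonzero fraction, age).
    Idempotent: re-filtering the retained set drops nothing.
    """
    retained: dict[int, ActivityWeek] = {}
    log_rows: list[dict] = []
    for pid, week in weeks.items():
        part = participants.get(pid)
        if part is None:
            raise ValidationError(f"activity week {pid} has no matching participant")
        rule = None
        if not week.calibrated:
            rule = RULE_CALIBRATED
        elif not week.complete:
            rule = RULE_COMPLETE
        elif ((week.counts > 0).sum(axis=1) < min_nonzero_minutes).any():
            rule = RULE_NONZERO
        elif part.age_years < min_age:
            rule = RULE_AGE
        if rule is None:
            retained[pid] = week
        else:
            log_rows.append({"participant_id": pid, "rule": rule})
    log = pd.DataFrame(log_rows, columns=["participant_id", "rule"])
    return retained, log


def summarize_week(week: ActivityWeek) -> pd.Series:
    """Reduce one complete week to its 336 hourly max/variance features."""
    if not week.complete:
        raise ContractError(
            f"week {week.participant_id} has missing minutes; run qc_filter first"
        )
    hourly = week.counts.reshape(DAYS_PER_WEEK, HOURS_PER_DAY, MINUTES_PER_HOUR)
    hmax = hourly.max(axis=2)
    hvar = hourly.var(axis=2, ddof=1)
    values = np.concatenate([hmax.ravel(), hvar.ravel()])
    return pd.Series(values, index=feature_names(), name=week.participant_id)


def _hourly_features(grids: np.ndarray) -> np.ndarray:
    """(n, 7, 1440) count grids -> (n, 336) max-then-var feature block.

    Processes in chunks to keep the transient float64 intermediates small.
    """
    n = len(grids)
    out = np.empty((n, N_FEATURES), dtype=np.float64)
    cells = DAYS_PER_WEEK * HOURS_PER_DAY
    for start in range(0, n, 512):
        chunk = grids[start : start + 512].astype(np.float64, copy=False)
        hourly = chunk.reshape(len(chunk), cells, MINUTES_PER_HOUR)
        out[start : start + 512, :cells] = hourly.max(axis=2)
        out[start : start + 512, cells:] = hourly.var(axis=2, ddof=1)
    return out


def feature_matrix(weeks: Mapping[int, ActivityWeek]) -> pd.DataFrame:
    """Stack summarize_week over participants: rows = participants, 336 cols."""
    if not weeks:
        return pd.DataFrame(columns=feature_names())
    ids = sorted(weeks)
    for pid in ids:
        if not weeks[pid].complete:
            raise ContractError(
                "feature_matrix requires complete weeks; run qc_filter"
            )
    grids = np.stack([weeks[pid].counts for pid in ids])
    mat = _hourly_features(grids)
    return pd.DataFrame(mat, index=pd.Index(ids, name="participant_id"),
                        columns=feature_names())


def counts_feature_matrix(counts: np.ndarray, ids) -> pd.DataFrame:
    """Feature matrix straight from a complete (n, 7, 1440) count array.

    Fast path for generated cohorts, skipping per-week object construction.
    """
    counts = np.asarray(counts)
    if counts.ndim != 3 or counts.shape[1:] != (DAYS_PER_WEEK, 1440):
        raise ContractError("counts must have shape (n, 7, 1440)")
    mat = _hourly_features(counts)
    return pd.DataFrame(mat, index=pd.Index(list(ids), name="participant_id"),
                        columns=feature_names())
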