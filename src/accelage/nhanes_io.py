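"""Readers and writers for the five NHANES-style input tables.

The pipeline consumes minute-level physical activity monitor records
(PAXRAW schema), demographics (DEMO), daily dietary totals (DR1TOT),
prescription medications (RXQ_RX) and linked mortality follow-up.  Each
table can arrive either as a SAS transport (XPT) file — the format NHANES
distributes — or as a CSV with the same column names.  Reading either
dialect yields identical canonical objects.

Canonical activity layout: day 1–7, minute-of-day 0–1439 (half-open hour
convention: hour ``h`` covers minutes ``[60h, 60h+60)``).  Files that use
the sequential minute index ``PAXN`` (1–10080) are converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .xport import read_xport, write_xport

logger = logging.getLogger(__name__)

DAYS_PER_WEEK = 7
MINUTES_PER_DAY = 1440

#: NHANES salt/ester suffixes stripped when normalising drug names.
SALT_SUFFIXES = frozenset(
    {
        "MESYLATE",
        "HYDROCHLORIDE",
        "HCL",
        "SODIUM",
        "POTASSIUM",
        "CALCIUM",
        "SULFATE",
        "TARTRATE",
        "BITARTRATE",
        "MALEATE",
        "CITRATE",
        "ACETATE",
        "BESYLATE",
        "FUMARATE",
        "SUCCINATE",
        "PHOSPHATE",
    }
)


@dataclass
class ActivityWeek:
    """One participant's week of minute-level accelerometer intensity counts.

    ``counts`` is a 7 x 1440 grid (day x minute-of-day) of device intensity
    counts; cells that were absent from the input are NaN and make the week
    incomplete.  ``calibrated`` is True only if every record of the week
    carried the calibrated status code.
    """

    participant_id: int
    calibrated: bool
    counts: np.ndarray  # float array, shape (7, 1440); NaN = missing cell

    @property
    def complete(self) -> bool:
        return bool(np.isfinite(self.counts).all())

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (DAYS_PER_WEEK, MINUTES_PER_DAY):
            raise ValidationError(
                f"counts grid must be {DAYS_PER_WEEK} x {MINUTES_PER_DAY}, "
                f"got {self.counts.shape}"
            )
        if np.nanmin(self.counts, initial=0.0) < 0:
            raise ValidationError("intensity counts must be nonnegative")


@dataclass
class Participant:
    """Demographics plus optional diet, prescription and mortality linkage."""

    participant_id: int
    age_years: int  # top-coded: 85 means 85+
    vital_status: str = "unknown"  # {"alive", "deceased", "unknown"}
    cause_group: Optional[str] = None  # ICD-10 chapter label, deceased only
    nutrient_intakes: dict = field(default_factory=dict)
    drugs: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValidationError("age_years must be nonnegative")
        if self.vital_status not in {"alive", "deceased", "unknown"}:
            raise ValidationError(f"bad vital_status {self.vital_status!r}")
        if self.cause_group is not None and self.vital_status != "deceased":
            raise ValidationError("cause_group only allowed for the deceased")


def normalize_drug_name(name: str) -> str:
    """Uppercase, trim and strip a trailing salt suffix from a drug name."""
    tokens = str(name).upper().strip().split()
    if len(tokens) > 1 and tokens[-1] in SALT_SUFFIXES:
        tokens = tokens[:-1]
    return " ".join(tokens)


#: canonical column names longer than the 8-character SAS v5 limit and the
#: short alias used inside XPT files
_XPT_ALIASES = {"UCOD_LEADING": "UCOD"}


def _read_table(path: str | PathLike, fmt: str) -> pd.DataFrame:
    if fmt == "xpt":
        df = read_xport(path)
        return df.rename(columns={v: k for k, v in _XPT_ALIASES.items()})
    if fmt == "csv":
        return pd.read_csv(path)
    raise SchemaError(f"unknown format {fmt!r}; expected 'xpt' or 'csv'")


def write_table(
    frame: pd.DataFrame, path: str | PathLike, fmt: str = "csv", name: str = "DATA"
) -> None:
    """Write a canonical table as CSV or XPT (long names aliased in XPT)."""
    if fmt == "xpt":
        write_xport(frame.rename(columns=_XPT_ALIASES), path, name=name)
    elif fmt == "csv":
        frame.to_csv(path, index=False)
    else:
        raise SchemaError(f"unknown format {fmt!r}; expected 'xpt' or 'csv'")


def _require(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    for col in cols:
        if col not in df.columns:
            raise SchemaError(f"{table} table is missing required column {col!r}")


def weeks_from_frame(df: pd.DataFrame) -> dict[int, ActivityWeek]:
    """Build ActivityWeek objects from a long-format activity table.

    Requires SEQN, PAXCAL, PAXDAY, PAXINTEN and a minute coordinate: either
    the sequential PAXN (1..10080) or PAXHOUR + PAXMINUT.
    """
    _require(df, ["SEQN", "PAXCAL", "PAXDAY", "PAXINTEN"], "activity")
    if "PAXN" in df.columns:
        minute = (df["PAXN"].to_numpy(dtype=np.int64) - 1) % MINUTES_PER_DAY
    elif "PAXHOUR" in df.columns and "PAXMINUT" in df.columns:
        minute = (
            df["PAXHOUR"].to_numpy(dtype=np.int64) * 60
            + df["PAXMINUT"].to_numpy(dtype=np.int64)
        )
    else:
        raise SchemaError(
            "activity table is missing required column 'PAXN' "
            "(or 'PAXHOUR'+'PAXMINUT')"
        )
    day = df["PAXDAY"].to_numpy(dtype=np.int64) - 1
    if ((day < 0) | (day >= DAYS_PER_WEEK)).any():
        raise ValidationError("PAXDAY must be in 1..7")
    if ((minute < 0) | (minute >= MINUTES_PER_DAY)).any():
        raise ValidationError("minute-of-day out of range 0..1439")

    seqn = df["SEQN"].to_numpy()
    ids, idx = np.unique(seqn, return_inverse=True)
    grids = np.full((len(ids), DAYS_PER_WEEK, MINUTES_PER_DAY), np.nan, dtype=np.float32)
    grids[idx, day, minute] = df["PAXINTEN"].to_numpy(dtype=np.float32)

    cal = df["PAXCAL"].to_numpy(dtype=float) == 1
    if "PAXSTAT" in df.columns:
        cal &= df["PAXSTAT"].to_numpy(dtype=float) == 1
    # a week is calibrated only if *every* record says so
    cal_all = np.ones(len(ids), dtype=bool)
    np.logical_and.at(cal_all, idx, cal)

    return {
        int(ids[i]): ActivityWeek(
            participant_id=int(ids[i]),
            calibrated=bool(cal_all[i]),
            counts=grids[i].astype(float),
        )
        for i in range(len(ids))
    }


def read_activity(path: str | PathLike, fmt: str = "xpt") -> dict[int, ActivityWeek]:
    """Read a PAXRAW-style file into one ActivityWeek per participant.

    Partial weeks are returned with missing cells marked NaN; the QC stage
    decides their fate.  Row order in the file does not affect the result.
    """
    return weeks_from_frame(_read_table(path, fmt))


def participants_from_frames(
    demo: pd.DataFrame,
    diet: Optional[pd.DataFrame] = None,
    rx: Optional[pd.DataFrame] = None,
    mortality: Optional[pd.DataFrame] = None,
) -> dict[int, Participant]:
    """Assemble Participant records from already-loaded canonical tables."""
    _require(demo, ["SEQN", "RIDAGEYR"], "demographics")
    seqn = demo["SEQN"].astype(np.int64)
    if seqn.duplicated().any():
        dups = seqn[seqn.duplicated()].tolist()
        raise ValidationError(f"duplicate participant id(s) in demographics: {dups}")

    participants: dict[int, Participant] = {}
    for pid, age in zip(seqn, demo["RIDAGEYR"].astype(float)):
        participants[int(pid)] = Participant(
            participant_id=int(pid), age_years=int(age)
        )

    if mortality is not None:
        _require(mortality, ["SEQN", "MORTSTAT"], "mortality")
        cause_col = "UCOD_LEADING" if "UCOD_LEADING" in mortality.columns else None
        dropped = 0
        for _, row in mortality.iterrows():
            pid = int(row["SEQN"])
            part = participants.get(pid)
            if part is None:
                dropped += 1
                continue
            stat = row["MORTSTAT"]
            if pd.isna(stat):
                part.vital_status = "unknown"
            elif int(stat) == 1:
                part.vital_status = "deceased"
                if cause_col is not None and isinstance(row[cause_col], str):
                    cause = row[cause_col].strip()
                    part.cause_group = cause or None
            else:
                part.vital_status = "alive"
        if dropped:
            logger.warning("dropped %d unmatched mortality rows", dropped)

    if diet is not None:
        _require(diet, ["SEQN"], "diet")
        nutrient_cols = [c for c in diet.columns if c != "SEQN"]
        dropped = 0
        for _, row in diet.iterrows():
            part = participants.get(int(row["SEQN"]))
            if part is None:
                dropped += 1
                continue
            part.nutrient_intakes = {
                c: float(row[c]) for c in nutrient_cols if not pd.isna(row[c])
            }
        if dropped:
            logger.warning("dropped %d unmatched diet rows", dropped)

    if rx is not None:
        _require(rx, ["SEQN", "RXDDRUG"], "prescriptions")
        dropped = 0
        for pid, name in zip(rx["SEQN"], rx["RXDDRUG"]):
            part = participants.get(int(pid))
            if part is None:
                dropped += 1
                continue
            if isinstance(name, str) and name.strip():
                part.drugs.add(normalize_drug_name(name))
        if dropped:
            logger.warning("dropped %d unmatched prescription rows", dropped)

    return participants


def read_participants(
    demo_path: str | PathLike,
    diet_path: Optional[str | PathLike] = None,
    rx_path: Optional[str | PathLike] = None,
    mortality_path: Optional[str | PathLike] = None,
    fmt: str = "xpt",
) -> dict[int, Participant]:
    """Read demographics (mandatory) plus optional diet / rx / mortality.

    Absent optional files leave the corresponding Participant fields empty;
    rows whose SEQN has no demographics match are logged and dropped.
    """
    demo = _read_table(demo_path, fmt)
    diet = _read_table(diet_path, fmt) if diet_path is not None else None
    rx = _read_table(rx_path, fmt) if rx_path is not None else None
    mort = _read_table(mortality_path, fmt) if mortality_path is not None else None
    return participants_from_frames(demo, diet, rx, mort)


def participants_frame(participants: Mapping[int, Participant]) -> pd.DataFrame:
    """Flatten Participant records into a DataFrame indexed by participant id."""
    rows = [
        {
            "participant_id": p.participant_id,
            "age_years": p.age_years,
            "vital_status": p.vital_status,
            "cause_group": p.cause_group,
        }
        for p in participants.values()
    ]
    return pd.DataFrame(rows).set_index("participant_id").sort_index()


def nutrient_frame(participants: Mapping[int, Participant]) -> pd.DataFrame:
    """Participants x nutrients intake matrix (NaN where not surveyed)."""
    data = {
        p.participant_id: p.nutrient_intakes for p in participants.values()
    }
    df = pd.DataFrame.from_dict(data, orient="index").sort_index()
    df.index.name = "participant_id"
    return df


def drug_frame(participants: Mapping[int, Participant]) -> pd.DataFrame:
    """Long (participant_id, drug) table of normalised prescription names."""
    rows = [
        {"participant_id": p.participant_id, "drug": d}
        for p in participants.values()
        for d in sorted(p.drugs)
    ]
    return pd.DataFrame(rows, columns=["participant_id", "drug"])
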