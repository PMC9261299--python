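"""Random-forest chronological-age regression and the delta-age statistic.

The clock is a random forest trained on centered and scaled hourly
movement features to predict chronological age.  Because tree ensembles
compress the age range (overpredicting the young, underpredicting the
old), raw predictions are rescaled against peers: an individual's raw
prediction is divided by the median raw prediction of people of similar
chronological age and multiplied by their own chronological age.  The
residual

    delta_age = normalized predicted age - chronological age

is the age-acceleration statistic: positive means faster-than-peers
biological aging, negative slower.

Feature importance is reported as %IncMSE — the percent increase of the
held-out mean squared error when a feature's column is permuted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from os import PathLike
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from .errors import DegenerateInputError, ParameterError, SchemaError

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 500
DEFAULT_PEER_WINDOW = 2.0


@dataclass
class AgeClock:
    """A fitted age regressor plus its frozen standardization parameters."""

    forest: RandomForestRegressor
    feature_names: list[str]
    center: np.ndarray  # per-feature training mean
    scale: np.ndarray  # per-feature training SD (1.0 where constant)
    seed: int

    def standardize(self, features: pd.DataFrame) -> np.ndarray:
        if list(features.columns) != self.feature_names:
            raise SchemaError("feature columns do not match the training layout")
        return (features.to_numpy(dtype=float) - self.center) / self.scale

    def save(self, path: str | PathLike) -> None:
        """Persist as <path> (joblib forest) + <path>.json sidecar."""
        path = Path(path)
        joblib.dump(self.forest, path)
        sidecar = {
            "feature_names": self.feature_names,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "seed": self.seed,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | PathLike) -> "AgeClock":
        path = Path(path)
        forest = joblib.load(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            forest=forest,
            feature_names=meta["feature_names"],
            center=np.asarray(meta["center"], dtype=float),
            scale=np.asarray(meta["scale"], dtype=float),
            seed=meta["seed"],
        )


def split_train_test(
    features: pd.DataFrame,
    ages: pd.Series,
    train_fraction: float = 0.70,
    seed: int = 0,
    n_age_bins: int = 5,
) -> tuple[pd.Index, pd.Index]:
    """Deterministic train/test split stratified on age-quantile bins.

    Stratification guarantees both subsets cover the age range.  Returns
    disjoint, exhaustive index sets (train_ids, test_ids).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError("train_fraction must be in (0, 1)")
    if len(features) < 10:
        raise ParameterError("need at least 10 participants to split")
    ages = ages.loc[features.index]
    bins = pd.qcut(ages, q=min(n_age_bins, ages.nunique()), duplicates="drop")
    n_train = int(round(train_fraction * len(features)))
    train_ids, test_ids = train_test_split(
        features.index,
        train_size=n_train,
        random_state=seed,
        stratify=bins,
    )
    return pd.Index(sorted(train_ids)), pd.Index(sorted(test_ids))


def train_rf(
    features: pd.DataFrame,
    ages: pd.Series,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> AgeClock:
    """Fit the random forest on centered/scaled training features.

    Standardization statistics come from the training set only and are
    stored on the clock for unchanged reuse at prediction time.  Each tree
    considers a third of the features per split (the classic regression
    default).  Constant features get scale 1.0 with a logged warning.
    """
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ParameterError("training features contain missing values")
    y = ages.loc[features.index].to_numpy(dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    constant = scale == 0.0
    if constant.any():
        logger.warning(
            "%d constant feature(s); scale set to 1", int(constant.sum())
        )
        scale = np.where(constant, 1.0, scale)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=1 / 3,
        random_state=seed,
        n_jobs=1,
        oob_score=True,
    )
    forest.fit((X - center) / scale, y)
    return AgeClock(
        forest=forest,
        feature_names=list(features.columns),
        center=center,
        scale=scale,
        seed=seed,
    )


def predict_age(clock: AgeClock, features: pd.DataFrame) -> pd.Series:
    """Raw predicted age (years) per participant; row-order independent."""
    preds = clock.forest.predict(clock.standardize(features))
    return pd.Series(preds, index=features.index, name="age_pred_raw")


def importance(
    clock: AgeClock,
    features: pd.DataFrame,
    ages: pd.Series,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance as %IncMSE on held-out data.

    For each feature the column is shuffled ``n_repeats`` times and the
    mean resulting increase of MSE is expressed as a percentage of the
    unpermuted MSE.
    """
    if n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    X = clock.standardize(features)
    y = ages.loc[features.index].to_numpy(dtype=float)
    base_mse = float(np.mean((clock.forest.predict(X) - y) ** 2))
    result = permutation_importance(
        clock.forest,
        X,
        y,
        scoring="neg_mean_squared_error",
        n_repeats=n_repeats,
        random_state=seed,
        n_jobs=1,
    )
    pct = 100.0 * result.importances_mean / base_mse
    return pd.Series(pct, index=clock.feature_names, name="pct_inc_mse")


def normalize_predictions(
    age_pred_raw: pd.Series,
    age_chron: pd.Series,
    peer_window: float = DEFAULT_PEER_WINDOW,
) -> pd.Series:
    """Peer-median rescaling of raw predictions.

    norm_i = raw_i / median({raw_j : |chron_j - chron_i| <= peer_window})
             * chron_i

    Peers include the individual themself, so every window is nonempty.
    With ``peer_window = 0`` peers are exactly the same-age group and the
    median delta_age within every such group is forced to zero.
    """
    chron = age_chron.loc[age_pred_raw.index].to_numpy(dtype=float)
    raw = age_pred_raw.to_numpy(dtype=float)
    norm = np.empty_like(raw)
    # participants sharing a chronological age share a peer set
    for a in np.unique(chron):
        sel = chron == a
        peer_median = float(np.median(raw[np.abs(chron - a) <= peer_window]))
        if peer_median <= 0:
            raise DegenerateInputError(
                f"peer median {peer_median} <= 0 at chronological age {a}"
            )
        norm[sel] = raw[sel] / peer_median * a
    return pd.Series(norm, index=age_pred_raw.index, name="age_pred_norm")


def delta_age(age_pred_norm: pd.Series, age_chron: pd.Series) -> pd.Series:
    """Age acceleration in years: positive = accelerated aging."""
    out = age_pred_norm - age_chron.loc[age_pred_norm.index]
    out.name = "delta_age"
    return out


def evaluate(age_pred: pd.Series, age_chron: pd.Series) -> tuple[float, float]:
    """Pearson r and RMSE (years) between predictions and chronological age."""
    pred = np.asarray(age_pred, dtype=float)
    chron = np.asarray(age_chron.loc[age_pred.index] if isinstance(age_chron, pd.Series) else age_chron, dtype=float)
    if len(pred) < 3:
        raise ParameterError("need at least 3 pairs to evaluate")
    if np.std(pred) == 0 or np.std(chron) == 0:
        raise DegenerateInputError("Pearson r undefined on a zero-variance vector")
    r = float(stats.pearsonr(pred, chron).statistic)
    rmse = float(np.sqrt(np.mean((pred - chron) ** 2)))
    return r, rmse


def age_records(
    age_chron: pd.Series,
    age_pred_raw: pd.Series,
    age_pred_norm: pd.Series,
) -> pd.DataFrame:
    """Assemble the per-participant age table (chron, raw, norm, delta)."""
    df = pd.DataFrame(
        {
            "age_chron": age_chron.loc[age_pred_raw.index],
            "age_pred_raw": age_pred_raw,
            "age_pred_norm": age_pred_norm,
        }
    )
    df["delta_age"] = df["age_pred_norm"] - df["age_chron"]
    df.index.name = "participant_id"
    return df
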