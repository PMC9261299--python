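"""End-to-end orchestration: io -> qc/features -> clock -> mortality -> screens.

A run is described by a :class:`RunConfig` (loadable from YAML).  Two input
modes exist:

* synthetic — generate a model-building cohort and a separate validation
  cohort (mirroring a two-survey-cycle design): the clock is trained on
  70% of the first cohort, benchmarked on the held-out 30%, then applied
  to the validation cohort where normalization, mortality association and
  the nutrient/drug screens run.
* files — read the five NHANES-style tables from disk (XPT or CSV); the
  single cohort is split 70/30, the clock is trained on the training part
  and all downstream analyses run on the held-out part.

Every stage writes its CSV products into the output directory, and a JSON
summary collects headline numbers (r / RMSE before and after
normalization, death proportions per aging class, top screen hits).
Reruns with an identical config reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Optional

import yaml

from . import age_model, mortality, nhanes_io, qc_features, screen, synthcohort
from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of an end-to-end run."""

    out_dir: str = "accelage_run"
    seed: int = 0

    # synthetic mode (used when activity_path is None)
    synth_n_train: int = 1500
    synth_n_validation: int = 2500

    # file mode
    activity_path: Optional[str] = None
    demographics_path: Optional[str] = None
    diet_path: Optional[str] = None
    rx_path: Optional[str] = None
    mortality_path: Optional[str] = None
    input_format: str = "xpt"

    # analysis parameters
    train_fraction: float = 0.70
    n_trees: int = age_model.DEFAULT_N_TREES
    peer_window: float = age_model.DEFAULT_PEER_WINDOW
    min_age_mortality: float = 60.0
    min_age_drugs: float = screen.DRUG_MIN_AGE
    extreme_cut: float = screen.EXTREME_CUT_YEARS
    k_clusters: int = 5

    @classmethod
    def from_yaml(cls, path: str | PathLike) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _load_cohort_from_files(config: RunConfig):
    if config.demographics_path is None:
        raise ParameterError("file mode requires demographics_path")
    weeks = nhanes_io.read_activity(config.activity_path, config.input_format)
    participants = nhanes_io.read_participants(
        config.demographics_path,
        config.diet_path,
        config.rx_path,
        config.mortality_path,
        fmt=config.input_format,
    )
    return weeks, participants


def _prepare(weeks, participants, out_dir: Path, tag: str):
    """QC + feature extraction for one cohort; writes stage CSVs."""
    retained, exclusions = qc_features.qc_filter(weeks, participants)
    features = qc_features.feature_matrix(retained)
    exclusions.to_csv(out_dir / f"exclusions_{tag}.csv", index=False)
    features.to_csv(out_dir / f"features_{tag}.csv")
    pframe = nhanes_io.participants_frame(participants)
    ages = pframe["age_years"].astype(float).loc[features.index]
    logger.info(
        "%s cohort: %d weeks in, %d retained, %d excluded",
        tag, len(weeks), len(retained), len(exclusions),
    )
    counts = {"input": len(weeks), "retained": len(retained),
              "excluded": len(exclusions)}
    return features, ages, pframe, counts


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the JSON-ready summary dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "run_config.yaml")
    summary: dict = {"seed": config.seed, "stage_counts": {}}

    synth_mode = config.activity_path is None
    if synth_mode:
        train_cohort = synthcohort.generate(
            synthcohort.SynthConfig(
                n_participants=config.synth_n_train, seed=config.seed
            )
        )
        val_cohort = synthcohort.generate(
            synthcohort.SynthConfig(
                n_participants=config.synth_n_validation,
                seed=config.seed + 1_000_003,
            )
        )
        weeks_a = train_cohort.weeks()
        parts_a = nhanes_io.participants_from_frames(
            train_cohort.demographics, train_cohort.diet,
            train_cohort.rx, train_cohort.mortality,
        )
        weeks_b = val_cohort.weeks()
        parts_b = nhanes_io.participants_from_frames(
            val_cohort.demographics, val_cohort.diet,
            val_cohort.rx, val_cohort.mortality,
        )
    else:
        weeks_a, parts_a = _load_cohort_from_files(config)
        weeks_b, parts_b = None, None

    feats_a, ages_a, pframe_a, counts_a = _prepare(
        weeks_a, parts_a, out_dir, "train"
    )
    summary["stage_counts"]["train"] = counts_a

    train_ids, test_ids = age_model.split_train_test(
        feats_a, ages_a, config.train_fraction, seed=config.seed
    )
    clock = age_model.train_rf(
        feats_a.loc[train_ids], ages_a.loc[train_ids],
        seed=config.seed, n_trees=config.n_trees,
    )
    clock.save(out_dir / "age_clock.joblib")

    pred_test = age_model.predict_age(clock, feats_a.loc[test_ids])
    r_raw, rmse_raw = age_model.evaluate(pred_test, ages_a)
    norm_test = age_model.normalize_predictions(
        pred_test, ages_a, config.peer_window
    )
    r_norm, rmse_norm = age_model.evaluate(norm_test, ages_a)
    summary["heldout"] = {
        "n": len(test_ids),
        "r_raw": r_raw, "rmse_raw": rmse_raw,
        "r_norm": r_norm, "rmse_norm": rmse_norm,
    }

    if synth_mode:
        feats_b, ages_b, pframe_b, counts_b = _prepare(
            weeks_b, parts_b, out_dir, "validation"
        )
        summary["stage_counts"]["validation"] = counts_b
        analysis_parts = parts_b
    else:
        # single-cohort mode: downstream analyses on the held-out part
        feats_b = feats_a.loc[test_ids]
        ages_b = ages_a.loc[test_ids]
        pframe_b = pframe_a
        analysis_parts = parts_a

    pred_b = age_model.predict_age(clock, feats_b)
    norm_b = age_model.normalize_predictions(pred_b, ages_b, config.peer_window)
    records = age_model.age_records(ages_b, pred_b, norm_b)
    records.to_csv(out_dir / "age_records.csv")
    delta = records["delta_age"]
    vital = pframe_b["vital_status"].loc[records.index]
    causes = pframe_b["cause_group"].loc[records.index]

    classes, (q1, q3) = mortality.classify_aging(
        delta, ages_b, config.min_age_mortality
    )
    classes.to_frame().assign(q1=q1, q3=q3).to_csv(out_dir / "aging_classes.csv")
    prop = mortality.proportion_test(classes, vital)
    summary["mortality"] = {
        "quartiles": [q1, q3],
        "proportions": prop["proportions"],
        "counts": prop["counts"],
        "chi2": prop["chi2"],
        "p": prop["p"],
    }
    mortality.decade_tests(delta, vital, ages_b).to_csv(
        out_dir / "decade_tests.csv", index=False
    )
    mortality.cause_tests(delta, causes, vital).to_csv(
        out_dir / "cause_tests.csv", index=False
    )

    intakes = nhanes_io.nutrient_frame(analysis_parts)
    if not intakes.empty:
        nut = screen.nutrient_screen(intakes, delta, ages_b)
        nut.to_csv(out_dir / "nutrient_screen.csv", index=False)
        profiles = screen.nutrient_profiles(nut)
        try:
            clusters, leaf_order = screen.cluster_nutrients(
                profiles, config.k_clusters
            )
            clusters.to_frame().to_csv(out_dir / "nutrient_clusters.csv")
        except ParameterError as exc:
            logger.warning("nutrient clustering skipped: %s", exc)
        best = nut.dropna(subset=["r"]).nsmallest(3, "r")
        summary["top_nutrients"] = best.to_dict(orient="records")

    drugs = nhanes_io.drug_frame(analysis_parts)
    if not drugs.empty:
        ds = screen.drug_screen(drugs, delta, ages_b, config.min_age_drugs)
        ds.to_csv(out_dir / "drug_screen.csv", index=False)
        screen.volcano_table(ds).to_csv(out_dir / "volcano.csv", index=False)
        if not ds.empty:
            summary["top_drug"] = ds.iloc[0].to_dict()

    summary["ok"] = True
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary
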