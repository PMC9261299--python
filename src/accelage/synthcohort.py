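"""Synthetic NHANES-like cohort with planted, recoverable aging effects.

A single latent variable ties everything together: each participant draws
a frailty offset ``f ~ Normal(0, frailty_sd)`` (years), shifting their
effective "movement age" to ``age + f``.  Minute-level intensity counts
come from a zero-inflated negative-binomial process whose activity
probability and count magnitude both decline with effective age (and are
near zero in sleep hours), so hourly max and variance carry the age
signal — strongest in the active afternoon, mirroring real actigraphy.
Death is Bernoulli with a logistic hazard in effective age; planted
nutrients correlate with ``-f`` following a per-decade effect profile;
users of the planted geroprotective drug have their frailty reduced by
the configured shift, which then propagates to movement, mortality and
diet.  Because every downstream association is a consequence of the one
latent frailty, each pipeline stage has a testable ground truth.

Each output table draws from its own RNG stream spawned from the master
seed, so adding or resizing one table never perturbs the others, and the
same seed yields byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from os import PathLike
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .mortality import DECADE_LABELS
from .nhanes_io import ActivityWeek, write_table

DAYS, MINUTES = 7, 1440
HOURS = 24

# Hour-of-day schedules (fractions / multipliers), fixed across configs:
# probability that a given minute is active at effective age 18 ...
_WAKE_PROB = np.array(
    [0.02, 0.02, 0.02, 0.02, 0.02, 0.05,
     0.35, 0.70, 0.80, 0.80, 0.80, 0.80,
     0.85, 0.85, 0.88, 0.88, 0.88, 0.85,
     0.80, 0.75, 0.65, 0.50, 0.30, 0.10]
)
# ... and the relative magnitude of an active minute's mean count.
_CIRCADIAN = np.array(
    [0.20, 0.20, 0.20, 0.20, 0.20, 0.30,
     0.60, 0.90, 1.00, 1.05, 1.10, 1.15,
     1.25, 1.35, 1.45, 1.50, 1.50, 1.40,
     1.20, 1.00, 0.80, 0.60, 0.40, 0.25]
)


@dataclass(frozen=True)
class NutrientSpec:
    """One dietary component: ``profile`` maps decade-bin label to the
    strength of the planted intake ~ -frailty association (None = null)."""

    code: str
    base: float
    sd: float
    profile: Optional[dict[str, float]] = None


@dataclass(frozen=True)
class DrugSpec:
    """One prescription drug.  ``usage_rate`` is the usage probability for
    participants aged 70+, tapering for the young; ``frailty_shift`` (years)
    is added to users' frailty (negative = geroprotective)."""

    name: str
    usage_rate: float
    frailty_shift: float = 0.0


def _default_nutrients() -> tuple[NutrientSpec, ...]:
    # the late-peaking profile rises through midlife and peaks in [50, 60),
    # echoing fiber-like components whose association with decelerated
    # aging is strongest in the 6th decade of life
    late_peak = dict(zip(DECADE_LABELS, [0.0, 0.1, 0.3, 1.0, 0.5, 0.35, 0.25]))
    moderate = dict(zip(DECADE_LABELS, [0.0, 0.1, 0.25, 0.7, 0.45, 0.3, 0.2]))
    nulls = [
        "DR1TPROT", "DR1TCARB", "DR1TSUGR", "DR1TTFAT", "DR1TCHOL",
        "DR1TCALC", "DR1TIRON", "DR1TZINC", "DR1TSODI", "DR1TPOTA",
        "DR1TVITC",
    ]
    planted = [
        NutrientSpec("DR1TFIBE", base=16.0, sd=7.0, profile=late_peak),
        NutrientSpec("DR1TMAGN", base=280.0, sd=110.0, profile=moderate),
    ]
    return tuple(planted) + tuple(
        NutrientSpec(code, base=100.0, sd=35.0) for code in nulls
    )


def _default_drugs() -> tuple[DrugSpec, ...]:
    nulls = [
        ("HYDROCHLOROTHIAZIDE", 0.15), ("LISINOPRIL", 0.12),
        ("ATORVASTATIN", 0.12), ("SIMVASTATIN", 0.10), ("METFORMIN", 0.10),
        ("AMLODIPINE", 0.08), ("OMEPRAZOLE", 0.08), ("ASPIRIN", 0.15),
        ("LEVOTHYROXINE", 0.08), ("FUROSEMIDE", 0.06), ("WARFARIN", 0.04),
        ("ATENOLOL", 0.08),
    ]
    return (DrugSpec("DOXAZOSIN", usage_rate=0.02, frailty_shift=-6.0),) + tuple(
        DrugSpec(name, rate) for name, rate in nulls
    )


@dataclass
class SynthConfig:
    """All knobs of the synthetic cohort.

    The defaults define the generator's reference conditions; every
    recovery test in the suite runs against them unless it explicitly
    perturbs a knob.
    """

    n_participants: int = 1500
    seed: int = 0
    age_min: int = 18
    age_max: int = 85  # stored top-coded: 85 means 85+
    frailty_sd: float = 3.0  # SD (years) of the latent aging-rate offset
    lifestyle_sd: float = 0.05  # log-normal SD of an age-independent
    # per-person activity-magnitude multiplier (sedentary vs sporty)

    # activity model
    base_count: float = 350.0  # mean count of an active midday minute at 18
    nb_dispersion: float = 1.0  # negative-binomial shape (smaller = burstier)
    intensity_age_slope: float = 0.012  # exp decay of count magnitude per year
    active_prob_age_slope: float = 0.006  # linear decay of activity prob/year

    # mortality model: P(death) = logistic(intercept + slope * effective_age)
    mort_intercept: float = -13.75
    mort_slope: float = 0.18
    unknown_vital_rate: float = 0.02  # linkage-ineligible fraction

    nutrients: tuple[NutrientSpec, ...] = field(default_factory=_default_nutrients)
    drugs: tuple[DrugSpec, ...] = field(default_factory=_default_drugs)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if not 0 <= self.age_min <= self.age_max:
            raise ValidationError("require 0 <= age_min <= age_max")
        for name in ("frailty_sd", "lifestyle_sd", "base_count", "nb_dispersion"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.unknown_vital_rate <= 1:
            raise ValidationError("unknown_vital_rate must be in [0, 1]")
        for spec in self.nutrients:
            if spec.sd < 0:
                raise ValidationError(f"nutrient {spec.code}: sd must be >= 0")
            if spec.profile is not None and set(spec.profile) - set(DECADE_LABELS):
                raise ValidationError(
                    f"nutrient {spec.code}: profile has unknown decade labels"
                )
        for spec in self.drugs:
            if not 0 <= spec.usage_rate <= 1:
                raise ValidationError(
                    f"drug {spec.name}: usage_rate must be in [0, 1]"
                )


@dataclass
class SynthCohort:
    """Generated cohort: five canonical tables plus the answer key."""

    config: SynthConfig
    seqn: np.ndarray
    ages: np.ndarray
    frailty: np.ndarray  # latent offset before drug effects
    effective_frailty: np.ndarray  # after geroprotector shifts
    activity_counts: np.ndarray  # (n, 7, 1440) int32
    calibrated: np.ndarray  # bool per participant
    demographics: pd.DataFrame
    diet: pd.DataFrame
    rx: pd.DataFrame
    mortality: pd.DataFrame
    drug_users: dict[str, np.ndarray]  # drug name -> user SEQNs

    @property
    def effective_age(self) -> np.ndarray:
        return self.ages + self.effective_frailty

    def weeks(self) -> dict[int, ActivityWeek]:
        return {
            int(s): ActivityWeek(
                participant_id=int(s),
                calibrated=bool(c),
                counts=grid.astype(float),
            )
            for s, c, grid in zip(self.seqn, self.calibrated, self.activity_counts)
        }

    def features(self) -> pd.DataFrame:
        """Hourly max/variance feature matrix, computed without building
        per-week objects (the generated grids are complete by construction)."""
        from .qc_features import counts_feature_matrix

        return counts_feature_matrix(self.activity_counts, self.seqn)

    def activity_table(self) -> pd.DataFrame:
        """Long NHANES-schema activity table (one row per minute)."""
        n = len(self.seqn)
        total = DAYS * MINUTES
        return pd.DataFrame(
            {
                "SEQN": np.repeat(self.seqn, total),
                "PAXCAL": np.repeat(np.where(self.calibrated, 1, 2), total),
                "PAXDAY": np.tile(np.repeat(np.arange(1, DAYS + 1), MINUTES), n),
                "PAXN": np.tile(np.arange(1, total + 1), n),
                "PAXINTEN": self.activity_counts.reshape(-1),
            }
        )

    def truth_frame(self) -> pd.DataFrame:
        """The answer key used by parameter-recovery tests."""
        return pd.DataFrame(
            {
                "SEQN": self.seqn,
                "age": self.ages,
                "frailty": self.frailty,
                "effective_frailty": self.effective_frailty,
            }
        ).set_index("SEQN")

    def write(self, out_dir: str | PathLike, fmt: str = "csv") -> dict[str, Path]:
        """Write the five tables plus a JSON manifest of true parameters."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ext = fmt
        paths = {}
        tables = {
            "activity": (self.activity_table(), "PAXRAW"),
            "demographics": (self.demographics, "DEMO"),
            "diet": (self.diet, "DR1TOT"),
            "rx": (self.rx, "RXQ_RX"),
            "mortality": (self.mortality, "MORT"),
        }
        for key, (frame, sas_name) in tables.items():
            path = out / f"{key}.{ext}"
            write_table(frame, path, fmt=fmt, name=sas_name)
            paths[key] = path
        manifest = {
            "config": _config_to_jsonable(self.config),
            "drug_users": {k: v.tolist() for k, v in self.drug_users.items()},
            "truth": self.truth_frame().reset_index().to_dict(orient="list"),
        }
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=1))
        paths["manifest"] = mpath
        return paths


def _config_to_jsonable(config: SynthConfig) -> dict:
    d = asdict(config)
    d["nutrients"] = [asdict(s) for s in config.nutrients]
    d["drugs"] = [asdict(s) for s in config.drugs]
    return d


def _age_usage_factor(ages: np.ndarray) -> np.ndarray:
    # prescription prevalence climbs with age; the configured usage_rate is
    # the rate at 70+
    return 0.25 + 0.75 * np.clip((ages - 40.0) / 30.0, 0.0, 1.0)


def generate(config: SynthConfig) -> SynthCohort:
    """Draw a full synthetic cohort under ``config`` (deterministic per seed)."""
    n = config.n_participants
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_demo, rng_act, rng_diet, rng_rx, rng_mort = (
        np.random.default_rng(s) for s in streams
    )

    seqn = np.arange(100001, 100001 + n, dtype=np.int64)
    ages = rng_demo.integers(config.age_min, config.age_max + 1, size=n).astype(float)
    frailty = rng_demo.normal(0.0, config.frailty_sd, size=n)

    # drug assignment first: geroprotector shifts feed every other table
    usage_factor = _age_usage_factor(ages)
    drug_users: dict[str, np.ndarray] = {}
    shifts = np.zeros(n)
    for spec in config.drugs:
        users = rng_rx.random(n) < spec.usage_rate * usage_factor
        drug_users[spec.name] = seqn[users]
        shifts[users] += spec.frailty_shift
    eff_frailty = frailty + shifts
    eff_age = np.clip(ages + eff_frailty, 18.0, 100.0)

    lifestyle = np.exp(rng_act.normal(0.0, config.lifestyle_sd, size=n))
    counts = _draw_activity(config, eff_age, lifestyle, rng_act)
    calibrated = np.ones(n, dtype=bool)

    demographics = pd.DataFrame({"SEQN": seqn, "RIDAGEYR": ages.astype(int)})

    # diet: planted components track -frailty with decade-specific strength
    decade_idx = np.clip(
        np.searchsorted([30, 40, 50, 60, 70, 80], ages, side="right"), 0, 6
    )
    diet_cols: dict[str, np.ndarray] = {"SEQN": seqn}
    for spec in config.nutrients:
        noise = rng_diet.normal(0.0, spec.sd, size=n)
        if spec.profile is None:
            signal = 0.0
        else:
            betas = np.array([spec.profile.get(lbl, 0.0) for lbl in DECADE_LABELS])
            # scaled by frailty_sd so a beta of 1 always contributes half a
            # nutrient-SD of frailty-linked signal
            f_unit = -eff_frailty / max(config.frailty_sd, 1e-12)
            signal = betas[decade_idx] * f_unit * (0.5 * spec.sd)
        diet_cols[spec.code] = np.maximum(spec.base + signal + noise, 0.0)
    diet = pd.DataFrame(diet_cols)

    rx_rows = []
    for spec in config.drugs:
        users = drug_users[spec.name]
        salted = rng_rx.random(len(users)) < 0.4
        for s, add_salt in zip(users, salted):
            name = spec.name + (" MESYLATE" if add_salt else "")
            rx_rows.append((int(s), name))
    rx = pd.DataFrame(rx_rows, columns=["SEQN", "RXDDRUG"]).sort_values(
        ["SEQN", "RXDDRUG"], kind="stable"
    ).reset_index(drop=True)

    # mortality: logistic hazard in effective age; a respiratory cause is
    # preferentially assigned to the frail among the deceased
    logit = config.mort_intercept + config.mort_slope * eff_age
    p_death = 1.0 / (1.0 + np.exp(-logit))
    dead = rng_mort.random(n) < p_death
    unknown = rng_mort.random(n) < config.unknown_vital_rate
    causes = np.array([""] * n, dtype=object)
    other_causes = ["I00-I09", "C00-C97", "G30-G31", "Nephrosis related", "Other"]
    for i in np.flatnonzero(dead & ~unknown):
        p_resp = float(np.clip(0.12 + 0.02 * eff_frailty[i], 0.02, 0.6))
        if rng_mort.random() < p_resp:
            causes[i] = "J40-J47"
        else:
            causes[i] = other_causes[int(rng_mort.integers(len(other_causes)))]
    mortstat = np.where(unknown, np.nan, dead.astype(float))
    mortality = pd.DataFrame(
        {"SEQN": seqn, "MORTSTAT": mortstat, "UCOD_LEADING": causes}
    )

    return SynthCohort(
        config=config,
        seqn=seqn,
        ages=ages,
        frailty=frailty,
        effective_frailty=eff_frailty,
        activity_counts=counts,
        calibrated=calibrated,
        demographics=demographics,
        diet=diet,
        rx=rx,
        mortality=mortality,
        drug_users=drug_users,
    )


def _draw_activity(
    config: SynthConfig,
    eff_age: np.ndarray,
    lifestyle: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-inflated negative-binomial minute counts, (n, 7, 1440) int32."""
    n = len(eff_age)
    age_excess = eff_age - 18.0
    prob_scale = np.clip(1.0 - config.active_prob_age_slope * age_excess, 0.15, 1.0)
    mag_scale = lifestyle * np.exp(-config.intensity_age_slope * age_excess)

    hour_of_minute = np.arange(MINUTES) // 60  # (1440,)
    p_active = prob_scale[:, None] * _WAKE_PROB[hour_of_minute]  # (n, 1440)
    mean_count = (
        config.base_count * mag_scale[:, None] * _CIRCADIAN[hour_of_minute]
    )  # (n, 1440)

    shape = config.nb_dispersion
    counts = np.zeros((n, DAYS, MINUTES), dtype=np.int32)
    for day in range(DAYS):  # per-day blocks keep peak memory modest
        active = rng.random((n, MINUTES)) < p_active
        lam = rng.gamma(shape, mean_count / shape, size=(n, MINUTES))
        c = rng.poisson(lam).astype(np.int32)
        c[~active] = 0
        counts[:, day, :] = c
    return counts


def make_fixture(tiny: bool = True, seed: int = 20030) -> SynthCohort:
    """Miniature cohort (n = 30) with one planted violator per QC rule.

    Participant 1 gets a day with exactly 143/1440 (9.93%) nonzero minutes,
    participant 2 is aged 17, and participant 3's device is uncalibrated —
    so the QC filter excludes exactly those three.  Regenerating with the
    same seed yields byte-identical tables.
    """
    n = 30 if tiny else 200
    config = SynthConfig(n_participants=n, seed=seed)
    cohort = generate(config)

    # rule (c): a day just below the 10%-nonzero threshold
    day = np.zeros(MINUTES, dtype=np.int32)
    day[np.arange(0, 143 * 10, 10) % MINUTES] = 50  # 143 scattered nonzeros
    cohort.activity_counts[0, 2, :] = day
    # rule (d): under-age participant
    cohort.ages[1] = 17.0
    cohort.demographics.loc[1, "RIDAGEYR"] = 17
    # rule (a): uncalibrated device
    cohort.calibrated[2] = False
    return cohort
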