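"""Shared fixtures: small synthetic cohorts and a quickly-trained clock."""

import numpy as np
import pandas as pd
import pytest

from accelage import age_model, qc_features, synthcohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """The n=30 miniature bundle with one planted QC violator per rule."""
    return synthcohort.make_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A clean n=350 cohort for unit-level end-to-end checks."""
    return synthcohort.generate(synthcohort.SynthConfig(n_participants=350, seed=7))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return qc_features.feature_matrix(small_cohort.weeks())


@pytest.fixture(scope="session")
def small_ages(small_cohort):
    return pd.Series(
        small_cohort.ages, index=small_cohort.seqn, name="age_years"
    )


@pytest.fixture(scope="session")
def small_clock(small_features, small_ages):
    """A modest forest: enough trees for stable unit-test behaviour."""
    train_ids, _ = age_model.split_train_test(small_features, small_ages, seed=7)
    return age_model.train_rf(
        small_features.loc[train_ids], small_ages.loc[train_ids],
        seed=7, n_trees=150,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
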