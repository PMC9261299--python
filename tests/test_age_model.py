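"""The random-forest clock, peer-median normalization and delta-age."""

import numpy as np
import pandas as pd
import pytest

from accelage import age_model
from accelage.errors import DegenerateInputError, ParameterError, SchemaError


def _toy_features(rng, n=300, p=20):
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)],
        index=pd.RangeIndex(n),
    )
    return X


class TestSplit:
    def test_sizes_and_partition(self, small_features, small_ages):
        tr, te = age_model.split_train_test(small_features, small_ages, 0.70, seed=1)
        assert len(tr) + len(te) == len(small_features)
        assert len(tr) == round(0.70 * len(small_features))
        assert set(tr).isdisjoint(te)

    def test_deterministic(self, small_features, small_ages):
        a = age_model.split_train_test(small_features, small_ages, seed=5)
        b = age_model.split_train_test(small_features, small_ages, seed=5)
        assert list(a[0]) == list(b[0]) and list(a[1]) == list(b[1])

    def test_stratification_balances_age(self, rng):
        ages = pd.Series(rng.uniform(18, 85, 1000))
        X = pd.DataFrame({"f0": rng.normal(size=1000)})
        tr, te = age_model.split_train_test(X, ages, seed=3)
        assert abs(ages.loc[tr].mean() - ages.loc[te].mean()) < 2.0

    def test_bad_fraction_rejected(self, small_features, small_ages):
        with pytest.raises(ParameterError):
            age_model.split_train_test(small_features, small_ages, 1.2, seed=0)


class TestTrainPredict:
    def test_constant_target_predicts_constant(self, rng):
        X = _toy_features(rng)
        y = pd.Series(50.0, index=X.index)
        clock = age_model.train_rf(X, y, seed=0, n_trees=20)
        preds = age_model.predict_age(clock, X)
        assert (preds == 50.0).all()

    def test_same_seed_same_model(self, rng):
        X = _toy_features(rng)
        y = pd.Series(X["f0"] * 3 + rng.normal(size=len(X)), index=X.index)
        c1 = age_model.train_rf(X, y, seed=9, n_trees=30)
        c2 = age_model.train_rf(X, y, seed=9, n_trees=30)
        assert c1.forest.oob_score_ == c2.forest.oob_score_
        np.testing.assert_array_equal(
            age_model.predict_age(c1, X), age_model.predict_age(c2, X)
        )

    def test_constant_feature_gets_unit_scale(self, rng, caplog):
        X = _toy_features(rng)
        X["f0"] = 7.0
        y = pd.Series(rng.normal(50, 5, len(X)), index=X.index)
        with caplog.at_level("WARNING"):
            clock = age_model.train_rf(X, y, seed=0, n_trees=10)
        assert clock.scale[0] == 1.0
        assert "constant" in caplog.text

    def test_row_order_irrelevant(self, small_clock, small_features):
        shuffled = small_features.sample(frac=1.0, random_state=1)
        p1 = age_model.predict_age(small_clock, small_features)
        p2 = age_model.predict_age(small_clock, shuffled)
        np.testing.assert_array_equal(p1.loc[shuffled.index], p2)

    def test_feature_mismatch_rejected(self, small_clock, small_features):
        bad = small_features.rename(columns={"max_d1_h0": "oops"})
        with pytest.raises(SchemaError):
            age_model.predict_age(small_clock, bad)

    def test_pure_noise_features_give_null_r(self, rng):
        """With no age signal, held-out r stays inside the 95% null band."""
        n = 600
        X = _toy_features(rng, n=n, p=30)
        ages = pd.Series(rng.uniform(18, 85, n), index=X.index)
        tr, te = age_model.split_train_test(X, ages, seed=0)
        clock = age_model.train_rf(X.loc[tr], ages.loc[tr], seed=0, n_trees=100)
        preds = age_model.predict_age(clock, X.loc[te])
        r, _ = age_model.evaluate(preds, ages)
        assert abs(r) < 1.96 / np.sqrt(len(te))


class TestImportance:
    def test_planted_feature_ranks_first_and_noise_near_zero(self, rng):
        n = 400
        X = _toy_features(rng, n=n, p=15)
        y = pd.Series(40 + 8 * X["f3"] + rng.normal(0, 1, n), index=X.index)
        clock = age_model.train_rf(X, y, seed=1, n_trees=100)
        imp = age_model.importance(clock, X, y, n_repeats=5, seed=1)
        assert imp.idxmax() == "f3"
        noise = imp.drop("f3")
        assert noise.abs().max() < imp["f3"] / 5

    def test_duplicated_signal_column_dilutes_importance(self, rng):
        n = 600
        X = _toy_features(rng, n=n, p=10)
        y = pd.Series(40 + 3 * X["f3"] + rng.normal(0, 3, n), index=X.index)
        solo = age_model.importance(
            age_model.train_rf(X, y, seed=1, n_trees=200), X, y, 10, seed=1
        )["f3"]
        Xdup = X.copy()
        Xdup["f9"] = X["f3"]  # redundant copy of the informative column
        dup = age_model.importance(
            age_model.train_rf(Xdup, y, seed=1, n_trees=200), Xdup, y, 10, seed=1
        )
        assert dup["f3"] < solo and dup["f9"] < solo

    def test_bad_repeats_rejected(self, small_clock, small_features, small_ages):
        with pytest.raises(ParameterError):
            age_model.importance(
                small_clock, small_features, small_ages, n_repeats=0
            )


class TestNormalization:
    def test_identity_when_raw_equals_peer_median(self):
        raw = pd.Series([60.0, 50.0, 70.0], index=[1, 2, 3])
        chron = pd.Series([60.0, 60.0, 60.0], index=[1, 2, 3])
        norm = age_model.normalize_predictions(raw, chron, peer_window=0)
        assert norm[1] == pytest.approx(60.0)  # raw == same-age median

    def test_double_median_doubles_age(self):
        raw = pd.Series([40.0, 80.0], index=[1, 2])
        chron = pd.Series([40.0, 40.0], index=[1, 2])
        norm = age_model.normalize_predictions(raw, chron, peer_window=0)
        # with peers including self, the two-person median is 60, so the
        # exact formula value differs from a naive "2x the median" reading
        assert norm[2] == pytest.approx(80.0 / 60.0 * 40.0)
        raw3 = pd.Series([40.0, 40.0, 80.0], index=[1, 2, 3])
        chron3 = pd.Series([40.0] * 3, index=[1, 2, 3])
        norm3 = age_model.normalize_predictions(raw3, chron3, peer_window=0)
        assert norm3[3] == pytest.approx(80.0)  # 2x the (40) median at age 40

    def test_per_age_group_median_delta_is_zero(self, rng):
        """With peers = same chronological age, each group's median delta
        is forced to zero (odd counts) or bracketed by the central pair."""
        ages = rng.integers(18, 86, 501).astype(float)
        raw = ages + rng.normal(0, 10, 501)
        raw = pd.Series(np.abs(raw) + 1.0)
        chron = pd.Series(ages)
        norm = age_model.normalize_predictions(raw, chron, peer_window=0)
        delta = age_model.delta_age(norm, chron)
        for a, grp in delta.groupby(chron):
            if len(grp) % 2 == 1:
                assert grp.median() == pytest.approx(0.0, abs=1e-9)
            else:
                vals = grp.sort_values().to_numpy()
                mid = len(vals) // 2
                assert vals[mid - 1] <= 1e-9 and vals[mid] >= -1e-9

    def test_proportional_predictions_normalize_exactly(self, rng):
        """raw = c * chron collapses to norm = chron, all deltas zero."""
        chron = pd.Series(rng.integers(18, 86, 200).astype(float))
        raw = 1.37 * chron
        norm = age_model.normalize_predictions(raw, chron, peer_window=0)
        np.testing.assert_allclose(norm, chron, rtol=1e-12)

    def test_nonpositive_peer_median_rejected(self):
        raw = pd.Series([0.0, 0.0, 5.0], index=[1, 2, 3])
        chron = pd.Series([50.0, 50.0, 50.0], index=[1, 2, 3])
        with pytest.raises(DegenerateInputError):
            age_model.normalize_predictions(raw, chron, peer_window=0)


class TestDeltaAndEvaluate:
    def test_delta_sign_convention(self):
        norm = pd.Series([70.0, 50.0, 60.0])
        chron = pd.Series([60.0, 60.0, 60.0])
        delta = age_model.delta_age(norm, chron)
        assert delta.tolist() == [10.0, -10.0, 0.0]

    def test_perfect_and_offset_predictions(self):
        chron = pd.Series([20.0, 40.0, 60.0, 80.0])
        r, rmse = age_model.evaluate(chron.copy(), chron)
        assert r == pytest.approx(1.0) and rmse == pytest.approx(0.0)
        r, rmse = age_model.evaluate(chron + 5, chron)
        assert r == pytest.approx(1.0) and rmse == pytest.approx(5.0)

    def test_hand_computed_rmse(self):
        pred = pd.Series([2.0, 4.0, 6.0])
        chron = pd.Series([1.0, 2.0, 3.0])
        r, rmse = age_model.evaluate(pred, chron)
        assert r == pytest.approx(1.0)
        assert rmse == pytest.approx(np.sqrt((1 + 4 + 9) / 3))

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            age_model.evaluate(pd.Series([5.0, 5.0, 5.0]), pd.Series([1.0, 2.0, 3.0]))


def test_clock_save_load_roundtrip(tmp_path, small_clock, small_features):
    path = tmp_path / "clock.joblib"
    small_clock.save(path)
    loaded = age_model.AgeClock.load(path)
    np.testing.assert_array_equal(
        age_model.predict_age(small_clock, small_features),
        age_model.predict_age(loaded, small_features),
    )
    assert loaded.feature_names == small_clock.feature_names
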