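"""Nutrient and drug screens, clustering, and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from accelage import screen
from accelage.errors import ParameterError, ValidationError
from accelage.mortality import DECADE_LABELS


def _bh_bruteforce(p):
    """Independent step-up oracle: adj_(i) = min over j>=i of p_(j)*m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return np.minimum(adj, 1.0)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            screen.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert screen.bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_all_ones_stay_one(self):
        assert (screen.bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]):
            with pytest.raises(ValidationError):
                screen.bh_adjust(bad)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
            min_size=1, max_size=20,
        )
    )
    def test_matches_bruteforce_oracle(self, ps):
        np.testing.assert_allclose(
            screen.bh_adjust(ps), _bh_bruteforce(ps), rtol=1e-12
        )


class TestNutrientScreen:
    def test_perfect_anticorrelation(self, rng):
        n = 40
        ages = pd.Series(np.full(n, 55.0))
        delta = pd.Series(rng.normal(0, 5, n))
        intakes = pd.DataFrame({"NUT": -delta})
        out = screen.nutrient_screen(intakes, delta, ages)
        row = out[(out.nutrient == "NUT") & (out.decade == "50-59")].iloc[0]
        assert row["r"] == pytest.approx(-1.0)
        assert row["n"] == n

    def test_null_intake_within_null_band(self, rng):
        n = 500
        ages = pd.Series(np.full(n, 45.0))
        delta = pd.Series(rng.normal(0, 5, n))
        intakes = pd.DataFrame({"NUT": rng.normal(100, 10, n)})
        out = screen.nutrient_screen(intakes, delta, ages)
        row = out[(out.nutrient == "NUT") & (out.decade == "40-49")].iloc[0]
        assert abs(row["r"]) < 1.96 / np.sqrt(n)

    def test_affine_rescaling_leaves_r_unchanged(self, rng):
        n = 80
        ages = pd.Series(np.full(n, 65.0))
        delta = pd.Series(rng.normal(0, 5, n))
        intake = pd.Series(rng.normal(10, 2, n)) + 0.3 * delta
        out1 = screen.nutrient_screen(pd.DataFrame({"N": intake}), delta, ages)
        out2 = screen.nutrient_screen(
            pd.DataFrame({"N": intake * 28.35 + 4.0}), delta, ages
        )
        r1 = out1[out1.decade == "60-69"]["r"].iloc[0]
        r2 = out2[out2.decade == "60-69"]["r"].iloc[0]
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_small_or_constant_cells_left_missing(self, rng):
        ages = pd.Series([25.0, 25.0, 65.0, 65.0, 65.0, 65.0])
        delta = pd.Series(rng.normal(size=6))
        intakes = pd.DataFrame(
            {"CONST": [np.nan, np.nan, 5.0, 5.0, 5.0, 5.0]}
        )
        out = screen.nutrient_screen(intakes, delta, ages)
        young = out[(out.decade == "18-29")].iloc[0]
        old = out[(out.decade == "60-69")].iloc[0]
        assert np.isnan(young["r"])  # n < 3
        assert np.isnan(old["r"])  # zero variance
        assert np.isnan(old["adj_p"])

    def test_bh_within_each_decade_bin(self, rng):
        n = 200
        ages = pd.Series(np.r_[np.full(n, 35.0), np.full(n, 75.0)])
        delta = pd.Series(rng.normal(0, 5, 2 * n))
        intakes = pd.DataFrame(
            {f"N{i}": rng.normal(50, 5, 2 * n) for i in range(6)}
        )
        out = screen.nutrient_screen(intakes, delta, ages)
        for label in ("30-39", "70-79"):
            cell = out[(out.decade == label)].dropna(subset=["p"])
            np.testing.assert_allclose(
                cell["adj_p"], _bh_bruteforce(cell["p"].to_numpy()), rtol=1e-12
            )
        assert (out.dropna(subset=["p"])["adj_p"] >= out.dropna(subset=["p"])["p"] - 1e-15).all()


class TestClusterNutrients:
    def _profiles(self, rows):
        return pd.DataFrame(rows, columns=DECADE_LABELS)

    def test_identical_rows_share_cluster(self):
        prof = self._profiles(
            [[0.1] * 7, [0.1] * 7, [-0.4] * 7]
        )
        prof.index = ["a", "b", "c"]
        clusters, _ = screen.cluster_nutrients(prof, k=2)
        assert clusters["a"] == clusters["b"] != clusters["c"]

    def test_k_equals_rows_gives_singletons(self):
        prof = self._profiles([[i / 10.0] * 7 for i in range(4)])
        prof.index = list("abcd")
        clusters, _ = screen.cluster_nutrients(prof, k=4)
        assert clusters.nunique() == 4

    def test_two_planted_profiles_perfectly_recovered(self, rng):
        flat = np.zeros(7)
        late = np.array([0.0, 0.0, -0.1, -0.2, -0.35, -0.3, -0.25])
        rows, names = [], []
        for i in range(5):
            rows.append(flat + rng.normal(0, 0.02, 7))
            names.append(f"flat{i}")
        for i in range(5):
            rows.append(late + rng.normal(0, 0.02, 7))
            names.append(f"late{i}")
        prof = self._profiles(rows)
        prof.index = names
        clusters, _ = screen.cluster_nutrients(prof, k=2)
        assert clusters[[f"flat{i}" for i in range(5)]].nunique() == 1
        assert clusters[[f"late{i}" for i in range(5)]].nunique() == 1
        assert clusters["flat0"] != clusters["late0"]

    def test_too_few_rows_rejected(self):
        prof = self._profiles([[0.0] * 7, [1.0] * 7])
        with pytest.raises(ParameterError):
            screen.cluster_nutrients(prof, k=5)

    def test_rows_with_missing_cells_dropped(self):
        prof = self._profiles([[0.0] * 7, [1.0] * 7, [0.5] * 7])
        prof.iloc[0, 3] = np.nan
        prof.index = list("abc")
        clusters, _ = screen.cluster_nutrients(prof, k=2)
        assert "a" not in clusters.index


class TestExtremeGroupTest:
    def test_identical_constant_intake_gives_p_one(self):
        delta = pd.Series([-15.0, -12.0, 13.0, 16.0])
        intake = pd.Series([5.0, 5.0, 5.0, 5.0])
        res = screen.extreme_group_test(intake, delta)
        assert res["testable"] and res["p"] == pytest.approx(1.0)

    def test_strong_difference_detected(self, rng):
        n = 25
        delta = pd.Series(np.r_[np.full(n, -14.0), np.full(n, 14.0)])
        intake = pd.Series(
            np.r_[rng.normal(30, 1, n), rng.normal(27, 1, n)]
        )
        res = screen.extreme_group_test(intake, delta)
        assert res["p"] < 1e-4
        assert res["mean_decelerated"] > res["mean_accelerated"]

    def test_no_extremes_untestable(self, rng):
        delta = pd.Series(rng.uniform(-5, 5, 50))
        intake = pd.Series(rng.normal(10, 1, 50))
        res = screen.extreme_group_test(intake, delta)
        assert not res["testable"] and np.isnan(res["p"])


class TestDrugScreen:
    def _drugs(self, mapping):
        rows = [
            {"participant_id": pid, "drug": d}
            for d, pids in mapping.items()
            for pid in pids
        ]
        return pd.DataFrame(rows, columns=["participant_id", "drug"])

    def test_users_identical_to_population(self, rng):
        n = 60
        ages = pd.Series(np.full(n, 75.0))
        delta = pd.Series(rng.normal(0, 5, n))
        drugs = self._drugs({"A": list(range(n))})  # everyone uses it
        out = screen.drug_screen(drugs, delta, ages)
        row = out.iloc[0]
        assert row["ks_stat"] == pytest.approx(0.0)
        assert row["ks_p"] == pytest.approx(1.0)
        assert row["median_shift"] == pytest.approx(0.0)

    def test_fully_separated_users(self, rng):
        """Users' deltas all lie below every non-user's: KS D = 1."""
        n = 500
        ages = pd.Series(np.full(n, 80.0))
        delta = pd.Series(np.r_[rng.normal(-30, 1, 10), rng.normal(5, 3, n - 10)])
        drugs = self._drugs({"GERO": list(range(10))})
        out = screen.drug_screen(drugs, delta, ages, comparison="nonusers")
        row = out.iloc[0]
        assert row["ks_stat"] == pytest.approx(1.0)
        assert row["ks_p"] < 1e-9
        assert row["rank_score"] > 9  # strongly decelerating -> large positive

    def test_age_restriction_and_rank_convention(self, rng):
        n = 400
        ages = pd.Series(np.r_[np.full(n // 2, 50.0), np.full(n // 2, 75.0)])
        delta = pd.Series(rng.normal(0, 5, n))
        delta.iloc[n // 2 : n // 2 + 12] -= 11.0  # elderly decelerated users
        delta.iloc[n // 2 + 12 : n // 2 + 24] += 11.0  # elderly accelerated users
        drugs = self._drugs(
            {
                "DEC": list(range(n // 2, n // 2 + 12)),
                "ACC": list(range(n // 2 + 12, n // 2 + 24)),
                "YOUNG": list(range(0, 12)),  # no users aged 70+
            }
        )
        out = screen.drug_screen(drugs, delta, ages, min_age=70)
        assert "YOUNG" not in set(out["drug"])
        assert out.iloc[0]["drug"] == "DEC"  # most decelerating sorts first
        assert out.iloc[-1]["drug"] == "ACC"
        dec = out[out.drug == "DEC"].iloc[0]
        assert dec["rank_score"] == pytest.approx(
            np.log10(dec["ks_p"]) * np.sign(dec["median_shift"])
        )
        assert dec["rank_score"] > 0 and dec["median_shift"] < 0

    def test_polypharmacy_counts_once_per_drug(self, rng):
        ages = pd.Series(np.full(30, 75.0))
        delta = pd.Series(rng.normal(0, 5, 30))
        drugs = pd.DataFrame(
            {"participant_id": [0, 0, 1], "drug": ["A", "A", "A"]}
        )
        out = screen.drug_screen(drugs, delta, ages)
        assert out.iloc[0]["n_users"] == 2

    def test_empty_elderly_subset_rejected(self, rng):
        ages = pd.Series(np.full(10, 40.0))
        delta = pd.Series(rng.normal(size=10))
        with pytest.raises(ValidationError):
            screen.drug_screen(self._drugs({"A": [0]}), delta, ages)

    def test_null_drug_table_rarely_reaches_significance(self, rng):
        """200 effect-free drugs: the smallest BH-adjusted p clears 0.05 in
        at least 90% of replicates."""
        hits = 0
        reps = 20
        for _ in range(reps):
            n = 1200
            ages = pd.Series(np.full(n, 75.0))
            delta = pd.Series(rng.normal(0, 5, n))
            mapping = {
                f"D{j}": rng.choice(n, size=rng.integers(5, 60), replace=False)
                for j in range(200)
            }
            out = screen.drug_screen(self._drugs(mapping), delta, ages)
            if out["adj_p"].min() <= 0.05:
                hits += 1
        assert reps - hits >= 0.9 * reps


def test_volcano_table_columns(rng):
    ages = pd.Series(np.full(40, 75.0))
    delta = pd.Series(rng.normal(0, 5, 40))
    drugs = pd.DataFrame({"participant_id": range(10), "drug": ["A"] * 10})
    out = screen.drug_screen(drugs, delta, ages)
    vol = screen.volcano_table(out)
    assert list(vol.columns) == ["drug", "n_users", "median_shift", "neg_log10_p"]
    assert vol["neg_log10_p"].iloc[0] == pytest.approx(-np.log10(out["ks_p"].iloc[0]))
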