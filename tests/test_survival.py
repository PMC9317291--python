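"""Min-p dichotomization, penalized Cox scenarios, ranking, KM curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tilscape as ts
from oracles import harrell_c_brute, km_brute


class TestMinmaxScale:
    def test_simple(self):
        assert np.allclose(ts.minmax_scale([0.0, 5.0, 10.0]), [0, 0.5, 1])

    def test_already_unit_interval_identity(self):
        x = np.array([0.0, 0.3, 1.0])
        assert np.allclose(ts.minmax_scale(x), x)

    def test_na_dropped_before_scaling(self):
        out = ts.minmax_scale([3.0, np.nan, 7.0])
        assert np.allclose(out, [0.0, 1.0])

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            ts.minmax_scale([2.0, 2.0, 2.0])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30).filter(
        lambda v: len(set(v)) > 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_spans_unit_interval(self, vals):
        out = ts.minmax_scale(vals)
        assert out.min() == 0.0 and out.max() == 1.0


class TestMinpDichotomize:
    def test_p_curve_has_thirty_entries(self, survival_frame_factory):
        df = survival_frame_factory(120, seed=0, beta=1.0)
        scaled = ts.minmax_scale(df["m"].values)
        thr, labels, curve = ts.minp_dichotomize(
            scaled, df["OS.time"].values, df["OS"].values, df["age"].values
        )
        assert len(curve) == 30
        assert np.isfinite(thr)
        assert set(np.unique(labels)) <= {0.0, 1.0}

    def test_threshold_within_percentile_band(self, survival_frame_factory):
        df = survival_frame_factory(150, seed=1, beta=2.0, threshold_effect=True)
        scaled = ts.minmax_scale(df["m"].values)
        thr, _, _ = ts.minp_dichotomize(
            scaled, df["OS.time"].values, df["OS"].values, df["age"].values
        )
        lo, hi = np.quantile(scaled, [0.10, 0.90])
        assert lo <= thr <= hi

    def test_tie_breaks_toward_smaller_threshold(self):
        # every threshold gives identical groups -> identical p; first wins
        x = np.array([0.0] * 10 + [1.0] * 10)
        rng = np.random.default_rng(0)
        times = rng.exponential(50, 20)
        events = np.ones(20)
        age = rng.normal(60, 5, 20)
        thr, _, curve = ts.minp_dichotomize(x, times, events, age)
        fitted = curve[~curve["skipped"]]
        assert thr == fitted["threshold"].iloc[0]

    def test_null_measure_minp_anticonservative(self):
        """The minimum over ~30 dependent tests sits well below uniform."""
        rng = np.random.default_rng(42)
        minps = []
        for _ in range(10):
            n = 150
            x = rng.uniform(0, 1, n)
            times = rng.exponential(100, n)
            events = (rng.random(n) < 0.7).astype(float)
            age = rng.normal(60, 8, n)
            _, _, curve = ts.minp_dichotomize(x, times, events, age)
            minps.append(np.nanmin(curve["p"].values))
        # mean of U(0,1) minimum over ~30 draws is ~0.03; uniform mean is 0.5
        assert np.mean(minps) < 0.25

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="event"):
            ts.minp_dichotomize(
                np.linspace(0, 1, 20), np.ones(20), np.zeros(20), np.full(20, 60.0)
            )


class TestFitCox:
    def test_recovers_generating_coefficient(self, survival_frame_factory):
        betas = []
        for seed in range(5):
            df = survival_frame_factory(500, seed=100 + seed, beta=0.7)
            res = ts.fit_cox(ts.Scenario("OS", "original", "continuous", "binary"),
                             "sim", "m", df)
            betas.append(np.log(res.hazard_ratio))
        assert abs(np.mean(betas) - 0.7) < 0.25  # ridge shrinks slightly

    def test_harrell_c_matches_brute_force_enumeration(self):
        """4 patients, no ties: C equals the concordant fraction of
        comparable pairs counted by hand."""
        from lifelines.utils import concordance_index

        times = np.array([5.0, 10.0, 15.0, 20.0])
        events = np.array([1, 1, 0, 1])
        risk = np.array([0.9, 0.1, 0.5, 0.2])
        ref = harrell_c_brute(times, events, risk)
        ours = concordance_index(times, -risk, events)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_random_score_c_near_half(self):
        from lifelines.utils import concordance_index

        cs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t = rng.exponential(100, 200)
            e = rng.random(200) < 0.7
            cs.append(concordance_index(t, -rng.random(200), e))
        se = np.std(cs, ddof=1) / np.sqrt(len(cs))
        assert abs(np.mean(cs) - 0.5) <= 3 * se + 1e-9

    def test_too_few_patients_na_result(self, survival_frame_factory):
        df = survival_frame_factory(8, seed=0, beta=1.0)
        res = ts.fit_cox(ts.Scenario("OS", "original", "continuous", "binary"),
                         "sim", "m", df)
        assert np.isnan(res.hazard_ratio)
        assert "too few" in res.note

    def test_degenerate_measure_na_result(self, survival_frame_factory):
        df = survival_frame_factory(50, seed=0, beta=0.0)
        df["m"] = 1.0
        res = ts.fit_cox(ts.Scenario("OS", "original", "continuous", "binary"),
                         "sim", "m", df)
        assert np.isnan(res.hazard_ratio)
        assert "degenerate" in res.note

    def test_discretized_records_threshold(self, survival_frame_factory):
        df = survival_frame_factory(200, seed=3, beta=1.5, threshold_effect=True)
        res = ts.fit_cox(ts.Scenario("OS", "original", "discretized", "binary"),
                         "sim", "m", df)
        assert 0.0 <= res.threshold <= 1.0
        assert res.hazard_ratio > 0


class TestScenarios:
    def test_sixteen_distinct(self):
        scns = ts.all_scenarios()
        assert len(scns) == 16
        assert len(set(scns)) == 16

    def test_invalid_field_rejected(self):
        with pytest.raises(ValueError):
            ts.Scenario("OS", "original", "continuous", "grayscale")

    def test_binary_only_input_runs_eight_scenarios(self, survival_frame_factory):
        df = survival_frame_factory(80, seed=5, beta=1.0)
        out = ts.run_all_scenarios(df, measures=["m"])
        assert set(out["map_scale"]) == {"binary"}
        assert len(out) == 8

    def test_identical_input_identical_table(self, survival_frame_factory):
        df = survival_frame_factory(80, seed=6, beta=1.0)
        a = ts.run_all_scenarios(df, measures=["m"])
        b = ts.run_all_scenarios(df.copy(), measures=["m"])
        pd.testing.assert_frame_equal(a, b)

    def test_probability_only_measure_restricted(self, survival_frame_factory):
        df = survival_frame_factory(80, seed=7, beta=1.0)
        df = df.rename(columns={"m": "banfeld_raftery"})
        out = ts.run_all_scenarios(df, measures=["banfeld_raftery"])
        assert len(out) == 0  # binary-scale input only


class TestRankMeasures:
    @staticmethod
    def _results(rows):
        base = {"cancer_type": "x", "endpoint": "OS", "model": "original",
                "measure_scale": "continuous", "map_scale": "binary"}
        return pd.DataFrame([{**base, **r} for r in rows])

    def test_simple_ordering(self):
        res = self._results(
            [{"measure": "a", "c_index": 0.7},
             {"measure": "b", "c_index": 0.6},
             {"measure": "c", "c_index": 0.5}]
        )
        out = ts.rank_measures(res)
        assert list(out["measure"]) == ["a", "b", "c"]
        assert list(out["mean_rank"]) == [1.0, 2.0, 3.0]

    def test_ties_get_average_rank(self):
        res = self._results(
            [{"measure": "a", "c_index": 0.7},
             {"measure": "b", "c_index": 0.7}]
        )
        out = ts.rank_measures(res)
        assert set(out["mean_rank"]) == {1.5}

    def test_two_blocks_averaged(self):
        r1 = self._results(
            [{"measure": "a", "c_index": 0.7}, {"measure": "b", "c_index": 0.6}]
        )
        r2 = self._results(
            [{"measure": "a", "c_index": 0.5}, {"measure": "b", "c_index": 0.9}]
        )
        r2["endpoint"] = "PFI"
        out = ts.rank_measures(pd.concat([r1, r2], ignore_index=True))
        # a: ranks 1 and 2 -> 1.5; b: ranks 2 and 1 -> 1.5
        assert set(out["mean_rank"]) == {1.5}

    def test_all_na_measure_excluded(self):
        res = self._results(
            [{"measure": "a", "c_index": 0.7}, {"measure": "b", "c_index": np.nan}]
        )
        out = ts.rank_measures(res)
        assert list(out["measure"]) == ["a"]


class TestKmCurves:
    def test_uncensored_group_drops_one_over_n(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0])
        events = np.ones(8)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        out = ts.km_curves(times, events, labels)
        low = out["low"]
        surv = low.loc[low["time"] > 0, "survival"].to_numpy()
        assert np.allclose(surv, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_group_flat_at_one(self):
        times = np.array([5.0, 6.0, 7.0, 1.0, 2.0, 3.0])
        events = np.array([0, 0, 0, 1, 1, 1])
        labels = np.array([0, 0, 0, 1, 1, 1])
        out = ts.km_curves(times, events, labels)
        assert (out["low"]["survival"] == 1.0).all()

    def test_matches_hand_product_limit(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 30).round(2)
        events = (rng.random(30) < 0.7).astype(int)
        labels = np.array([0] * 15 + [1] * 15)
        out = ts.km_curves(times, events, labels)
        ref_t, ref_s = km_brute(times[:15], events[:15])
        ours = out["low"].set_index("time")["survival"]
        for t, s in zip(ref_t, ref_s):
            assert ours.loc[t] == pytest.approx(s, abs=1e-12)

    def test_one_empty_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            ts.km_curves(np.ones(3), np.ones(3), np.zeros(3))


def test_discretized_beats_continuous_under_true_threshold(survival_frame_factory):
    wins = 0
    for seed in range(6):
        df = survival_frame_factory(250, seed=300 + seed, beta=np.log(2.5),
                                    threshold_effect=True)
        pc = ts.fit_cox(ts.Scenario("OS", "original", "continuous", "binary"),
                        "sim", "m", df).p_value
        pdisc = ts.fit_cox(ts.Scenario("OS", "original", "discretized", "binary"),
                           "sim", "m", df).p_value
        wins += pdisc <= pc
    assert wins >= 5
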