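import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drivernet.errors import ConfigurationError, DegenerateInputError
from drivernet.expression import ExpressionMatrix
from drivernet.survival import (apply_horizon, kaplan_meier, logrank_test,
                                median_split, survival_screen)


def surv_frame(times, events, groups=None):
    df = pd.DataFrame({"sample": [f"S{i}" for i in range(len(times))],
                       "time_days": times, "event": events})
    if groups is not None:
        df["group"] = groups
    return df


class TestMedianSplit:
    def test_even_split(self):
        labels = median_split([1, 2, 3, 4])  # median 2.5
        assert list(labels) == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        labels = median_split([1, 2, 2, 2, 9])  # median 2
        assert list(labels) == ["low", "low", "low", "low", "high"]

    def test_partition_complete_and_nonempty(self, rng):
        labels = median_split(rng.standard_normal(101))
        assert (labels == "high").sum() + (labels == "low").sum() == 101
        assert (labels == "high").any() and (labels == "low").any()

    def test_constant_values_degenerate(self):
        with pytest.raises(DegenerateInputError):
            median_split([2.0, 2.0, 2.0, 2.0])


class TestApplyHorizon:
    def test_late_event_becomes_censored(self):
        out = apply_horizon(surv_frame([4000.0], [1]), 3650)
        assert out.loc[0, "time_days"] == 3650 and out.loc[0, "event"] == 0

    def test_boundary_inclusive(self):
        out = apply_horizon(surv_frame([3650.0], [1]), 3650)
        assert out.loc[0, "time_days"] == 3650 and out.loc[0, "event"] == 1

    def test_identity_below_horizon(self):
        df = surv_frame([10.0, 200.0], [1, 0])
        pd.testing.assert_frame_equal(apply_horizon(df, 3650), df)

    def test_never_increases_event_count(self, rng):
        df = surv_frame(rng.exponential(2000, 50),
                        rng.integers(0, 2, 50))
        out = apply_horizon(df, 1500)
        assert out["event"].sum() <= df["event"].sum()


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = kaplan_meier(surv_frame([5.0, 8.0, 9.0], [0, 0, 0]))
        assert curve.times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_single_event_one_step(self):
        curve = kaplan_meier(surv_frame([2.0, 3.0, 4.0, 5.0, 6.0],
                                        [1, 0, 0, 0, 0]))
        assert curve.survival_at(2.0) == pytest.approx(0.8)

    def test_hand_computed_product_limit_table(self):
        # t:  1+  2   2   4+  5   5   7+  8     (+ = censored)
        # t=2: n=7, d=2 -> S = 5/7
        # t=5: n=4, d=2 -> S = 5/7 * 2/4 = 5/14
        # t=8: n=1, d=1 -> S = 0
        curve = kaplan_meier(surv_frame([1, 2, 2, 4, 5, 5, 7, 8],
                                        [0, 1, 1, 0, 1, 1, 0, 1]))
        np.testing.assert_array_equal(curve.times, [2, 5, 8])
        np.testing.assert_array_equal(curve.at_risk, [7, 4, 1])
        np.testing.assert_array_equal(curve.events, [2, 2, 1])
        np.testing.assert_allclose(curve.survival, [5 / 7, 5 / 14, 0.0])

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        times = rng.exponential(100, 60).round(1) + 0.1
        events = rng.integers(0, 2, 60)
        curve = kaplan_meier(surv_frame(times, events))
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t in curve.times:
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_record_order_invariance_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        times = rng.exponential(50, 30).round(0) + 1
        events = rng.integers(0, 2, 30)
        curve = kaplan_meier(surv_frame(times, events))
        perm = rng.permutation(30)
        shuffled = kaplan_meier(surv_frame(times[perm], events[perm]))
        np.testing.assert_allclose(curve.survival, shuffled.survival)
        s = np.concatenate([[1.0], curve.survival])
        assert (np.diff(s) <= 1e-12).all()
        assert ((0.0 <= curve.survival) & (curve.survival <= 1.0)).all()


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        times = [3.0, 5.0, 7.0, 11.0]
        events = [1, 0, 1, 1]
        df = surv_frame(times * 2, events * 2,
                        ["a"] * 4 + ["b"] * 4)
        res = logrank_test(df)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_separation_highly_significant(self):
        # group a: all events at t=1; group b: all censored at t=10
        df = surv_frame([1.0] * 20 + [10.0] * 20, [1] * 20 + [0] * 20,
                        ["a"] * 20 + ["b"] * 20)
        res = logrank_test(df)
        # hand O/E: single event time, n=40, d=20, E_a = 20*20/40 = 10,
        # V = 20*0.5*0.5*20/39; chi2 = 100/V = 39
        assert res.observed["a"] == 20
        assert res.expected["a"] == pytest.approx(10.0)
        assert res.statistic == pytest.approx(100 / (20 * 0.25 * 20 / 39))
        assert res.p_value < 0.001

    def test_zero_events_flagged(self):
        df = surv_frame([5.0, 6.0, 7.0, 8.0], [0, 0, 0, 0],
                        ["a", "a", "b", "b"])
        res = logrank_test(df)
        assert res.degenerate and res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_lifelines_statistic(self, rng):
        lifelines = pytest.importorskip("lifelines")
        times = rng.exponential(80, 30).round(1) + 0.5
        events = rng.integers(0, 2, 30)
        groups = rng.choice(["a", "b"], 30)
        if len(set(groups)) < 2:
            groups[0], groups[1] = "a", "b"
        df = surv_frame(times, events, groups)
        mine = logrank_test(df)
        ref = lifelines.statistics.logrank_test(
            times[groups == "a"], times[groups == "b"],
            events[groups == "a"], events[groups == "b"])
        assert mine.statistic == pytest.approx(ref.test_statistic, abs=1e-10)
        assert mine.p_value == pytest.approx(ref.p_value, abs=1e-10)

    def test_label_swap_invariance(self, rng):
        times = rng.exponential(80, 40) + 0.5
        events = rng.integers(0, 2, 40)
        groups = np.array(["a"] * 20 + ["b"] * 20)
        a = logrank_test(surv_frame(times, events, groups))
        swapped = np.where(groups == "a", "b", "a")
        b = logrank_test(surv_frame(times, events, swapped))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value)

    def test_single_group_rejected(self):
        df = surv_frame([1.0, 2.0], [1, 1], ["a", "a"])
        with pytest.raises(ConfigurationError):
            logrank_test(df)


class TestSurvivalScreen:
    def make_inputs(self, rng, n=60):
        genes = ["HIT", "NULL1", "NULL2"]
        expr_vals = rng.standard_normal((3, n))
        samples = [f"S{i}" for i in range(n)]
        expr = ExpressionMatrix(pd.DataFrame(expr_vals, index=genes,
                                             columns=samples))
        high = expr_vals[0] > np.median(expr_vals[0])
        rate = np.where(high, 4.0, 1.0) / 1000.0
        times = rng.exponential(1.0 / rate)
        surv = pd.DataFrame({"sample": samples, "time_days": times,
                             "event": 1})
        return expr, surv

    def test_effect_gene_flagged_nulls_mostly_not(self, rng):
        expr, surv = self.make_inputs(rng, n=200)
        result, significant = survival_screen(["HIT", "NULL1", "NULL2"],
                                              expr, surv)
        assert "HIT" in significant
        assert set(result["gene"]) == {"HIT", "NULL1", "NULL2"}
        assert result["n_high"].add(result["n_low"]).eq(200).all()

    def test_empty_gene_set(self, rng):
        expr, surv = self.make_inputs(rng)
        result, significant = survival_screen([], expr, surv)
        assert result.empty and significant == []

    def test_absent_gene_skipped(self, rng):
        expr, surv = self.make_inputs(rng)
        result, _ = survival_screen(["HIT", "GHOST"], expr, surv)
        assert list(result["gene"]) == ["HIT"]

    def test_bh_correction_never_adds_hits(self, rng):
        expr, surv = self.make_inputs(rng, n=100)
        raw, sig_raw = survival_screen(["HIT", "NULL1", "NULL2"], expr, surv)
        adj, sig_adj = survival_screen(["HIT", "NULL1", "NULL2"], expr, surv,
                                       correct="fdr_bh")
        assert set(sig_adj) <= set(sig_raw)
        assert (adj["p_adjusted"] >= adj["p"] - 1e-12).all()
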