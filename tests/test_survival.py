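import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from sepsisgrs import (
    WindowSpec,
    cox_fit,
    grs_trend_test,
    km_estimate,
    landmark_window_analysis,
    logrank_test,
)
from sepsisgrs.survival import DEFAULT_WINDOWS

from conftest import (
    cox_partial_loglik,
    km_brute_force,
    logrank_brute_force,
    random_survival_instance,
)


class TestKaplanMeier:
    def test_no_censoring_reduces_to_ecdf(self):
        times = [1.0, 2.0, 2.0, 3.0, 5.0]
        km = km_estimate(times, [True] * 5)
        for _, row in km.iterrows():
            surv_emp = np.mean(np.array(times) > row["time"])
            assert row["survival"] == pytest.approx(surv_emp)

    def test_all_censored_survival_stays_one(self):
        km = km_estimate([1, 2, 3], [False, False, False])
        assert km.empty  # no event times; S == 1 everywhere

    def test_hand_computed_product_limit(self):
        # times (1,2,3), events (1,0,1): S(1)=2/3, censoring at 2, S(3)=0
        km = km_estimate([1, 2, 3], [True, False, True])
        assert list(km["time"]) == [1.0, 3.0]
        assert km["survival"].tolist() == pytest.approx([2 / 3, 0.0])
        assert km["n_at_risk"].tolist() == [3, 1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(200):
            inst = random_survival_instance(rng)
            km = km_estimate(inst["time"], inst["event"])
            oracle = km_brute_force(inst["time"], inst["event"])
            pd.testing.assert_frame_equal(km, oracle, check_dtype=False)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        inst = random_survival_instance(rng, n_max=40)
        km = km_estimate(inst["time"], inst["event"])
        kmf = KaplanMeierFitter().fit(inst["time"], inst["event"])
        for _, row in km.iterrows():
            assert kmf.predict(row["time"]) == pytest.approx(row["survival"], abs=1e-10)


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        times = [1, 2, 3, 4]
        events = [True, True, False, True]
        t2 = times + times
        e2 = events + events
        g = [0] * 4 + [1] * 4
        chi2, df, p = logrank_test(t2, e2, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_textbook_two_group_instance(self):
        # small instance verified against explicit O-E bookkeeping
        times = [6, 7, 10, 15, 19, 25, 13, 21, 27, 30]
        events = [True, True, False, True, True, False, True, True, True, False]
        groups = [0] * 6 + [1] * 4
        chi2, df, p = logrank_test(times, events, groups)
        oracle = logrank_brute_force(times, events, groups)
        assert chi2 == pytest.approx(oracle, rel=1e-10)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            inst = random_survival_instance(rng)
            chi2, _, _ = logrank_test(inst["time"], inst["event"], inst["group"])
            assert chi2 == pytest.approx(
                logrank_brute_force(inst["time"], inst["event"], inst["group"]),
                rel=1e-9, abs=1e-12,
            )

    def test_matches_lifelines_multivariate(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        inst = random_survival_instance(rng, n_max=40)
        chi2, df, p = logrank_test(inst["time"], inst["event"], inst["group"])
        ll = multivariate_logrank_test(inst["time"], inst["group"], inst["event"])
        assert chi2 == pytest.approx(ll.test_statistic, rel=1e-8)
        assert p == pytest.approx(ll.p_value, rel=1e-8)

    def test_six_group_run_has_df_five(self, rng):
        n = 300
        times = rng.exponential(5, n)
        events = rng.random(n) < 0.7
        groups = np.repeat(np.arange(6), n // 6)
        chi2, df, p = logrank_test(times, events, groups)
        assert df == 5
        assert 0 <= p <= 1

    def test_invariant_under_time_rescaling(self, rng):
        inst = random_survival_instance(rng)
        a = logrank_test(inst["time"], inst["event"], inst["group"])[0]
        b = logrank_test(inst["time"] * 7.3, inst["event"], inst["group"])[0]
        assert a == pytest.approx(b, rel=1e-12)


class TestCox:
    def test_three_subject_instance_matches_grid_search(self):
        """Partial-likelihood maximum located by dense 1-d search."""
        times = [1.0, 2.0, 3.0]
        events = [True, True, False]
        x = [1.0, 0.0, 1.0]
        df = pd.DataFrame({"time": times, "event": events, "x": x})
        fit = cox_fit(df, ["x"])
        beta_hat = np.log(fit.loc[0, "hr"])
        res = minimize_scalar(
            lambda b: -cox_partial_loglik(b, times, events, x),
            bounds=(-6, 6),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert beta_hat == pytest.approx(res.x, abs=1e-4)

    def test_null_covariate_recovers_hr_one(self, rng):
        n = 20_000
        x = rng.integers(0, 2, n)
        t = rng.exponential(10, n)
        c = rng.uniform(0, 15, n)
        df = pd.DataFrame(
            {"time": np.minimum(t, c), "event": t <= c, "x": x.astype(float)}
        )
        fit = cox_fit(df, ["x"])
        assert fit.loc[0, "ci_low"] < 1.0 < fit.loc[0, "ci_high"]
        assert fit.loc[0, "hr"] == pytest.approx(1.0, abs=0.1)

    def test_exponential_data_recovers_planted_hr(self, rng):
        # binary exposure multiplying the hazard by 3
        n = 50_000
        x = rng.integers(0, 2, n)
        rate = 0.1 * 3.0**x
        t = rng.exponential(1 / rate)
        df = pd.DataFrame({"time": np.minimum(t, 20.0), "event": t <= 20.0, "x": x.astype(float)})
        fit = cox_fit(df, ["x"])
        assert fit.loc[0, "hr"] == pytest.approx(3.0, rel=0.05)

    def test_zero_events_flagged_inestimable(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [False, False], "x": [0.0, 1.0]})
        fit = cox_fit(df, ["x"])
        assert (fit["flag"] == "inestimable").all()

    def test_constant_covariate_flagged(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [True, True, False], "x": [1.0, 1.0, 1.0]})
        fit = cox_fit(df, ["x"])
        assert (fit["flag"] == "inestimable").all()


def _landmark_records():
    # handcrafted: event days converted to years from origin
    day = 1 / 365.25
    return pd.DataFrame(
        {
            "time": [45 * day, 10 * day, 800 * day, 900 * day, 400 * day, 3.0],
            "event": [True, True, True, False, True, False],
            "group": [1, 1, 0, 0, 0, 1],
        }
    )


class TestLandmark:
    def test_window_membership_by_definition(self):
        rec = _landmark_records()
        res = landmark_window_analysis(rec, group_col="group")
        short, mid, long_ = res
        # subject with event at day 45: not a short-term event, at risk and
        # an event in the mid window
        assert short.n_events[1] == 1  # only the day-10 event
        assert short.n_at_risk[1] == 3
        assert mid.n_at_risk[1] == 2  # day-10 event left the risk set
        assert mid.n_events[1] == 1  # the day-45 event
        assert mid.n_events[0] == 1  # the day-400 event
        assert long_.n_events[0] == 1  # day-800

    def test_event_partition_across_windows(self, rng):
        inst = random_survival_instance(rng, n_max=50)
        inst["time"] = inst["time"] / 2.0  # spread over ~0-4 years
        res = landmark_window_analysis(inst, group_col="group")
        total = sum(sum(r.n_events.values()) for r in res)
        assert total == int(inst["event"].sum())

    def test_risk_set_chaining_without_censoring(self, rng):
        # all subjects event-free to the end or event, no censoring inside
        n = 400
        t = rng.exponential(1.5, n)
        rec = pd.DataFrame(
            {"time": np.minimum(t, 50.0), "event": t <= 50.0, "group": rng.integers(0, 2, n)}
        )
        res = landmark_window_analysis(rec, group_col="group")
        for g in (0, 1):
            assert res[1].n_at_risk[g] == res[0].n_at_risk[g] - res[0].n_events[g]
            assert res[2].n_at_risk[g] == res[1].n_at_risk[g] - res[1].n_events[g]

    def test_zero_events_window_inestimable(self):
        rec = pd.DataFrame(
            {"time": [5.0, 6.0, 7.0, 8.0], "event": [False] * 4, "group": [0, 0, 1, 1]}
        )
        res = landmark_window_analysis(rec, group_col="group")
        assert all(r.flag == "inestimable" for r in res)


class TestTrend:
    def test_null_groups_give_uniform_ish_p(self, rng):
        # identical event processes: p should not concentrate near 0
        ps = []
        for _ in range(40):
            n = 300
            df = pd.DataFrame(
                {
                    "time": rng.exponential(5, n),
                    "event": rng.random(n) < 0.8,
                    "group": rng.choice(["low", "intermediate", "high"], n),
                }
            )
            res = grs_trend_test(df["time"], df["event"], df["group"])
            ps.append(res.loc[0, "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_dose_response_detected(self, rng):
        n = 3000
        g = rng.choice([0, 1, 2], n)
        rate = 0.05 * 2.0**g
        t = rng.exponential(1 / rate)
        labels = np.array(["low", "intermediate", "high"])[g]
        res = grs_trend_test(np.minimum(t, 30.0), t <= 30.0, labels)
        assert (res["p"] < 0.001).all()
        assert res.loc[0, "statistic"] > 0

    def test_reversal_flips_statistic_same_p(self, rng):
        inst = random_survival_instance(rng, n_max=50)
        labels = np.array(["low", "high"])[inst["group"]]
        fwd = grs_trend_test(inst["time"], inst["event"], labels, levels=("low", "high"))
        rev = grs_trend_test(
            inst["time"], inst["event"],
            np.where(labels == "low", "high", "low"), levels=("low", "high"),
        )
        assert fwd.loc[0, "statistic"] == pytest.approx(-rev.loc[0, "statistic"], rel=1e-9)
        assert fwd.loc[0, "p"] == pytest.approx(rev.loc[0, "p"], rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            grs_trend_test([1, 2], [True, True], ["low", "low"])
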