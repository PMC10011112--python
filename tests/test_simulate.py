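import numpy as np
import pandas as pd
import pytest

from sepsisgrs import (
    SimulationConfig,
    compute_grs_matrix,
    logrank_test,
    records_from_truth,
    simulate_cohort,
    simulate_covariates,
    simulate_event_times,
    simulate_genotypes,
    simulate_panel,
    simulate_sepsis,
)
from scipy import stats


class TestPanels:
    def test_default_sizes(self):
        assert len(simulate_panel("MI")) == 78
        assert len(simulate_panel("IS")) == 30
        assert len(simulate_panel("VTE")) == 22

    def test_all_gwas_significant_and_unambiguous(self):
        panel = simulate_panel("VTE", seed=2)
        assert all(s.gwas_p < 5e-8 for s in panel)
        assert not any(s.is_palindromic for s in panel)

    def test_seeded_determinism(self):
        a = simulate_panel("MI", seed=5)
        b = simulate_panel("MI", seed=5)
        assert a == b


class TestGenotypes:
    def test_hwe_genotype_frequencies(self):
        panel = simulate_panel("IS", n_snps=1, seed=0)
        f = panel.snps[0].risk_freq
        gm = simulate_genotypes(100_000, panel, seed=4)
        g = gm.dosage[:, 0]
        n = len(g)
        expected = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        observed = np.array([(g == k).mean() for k in (0, 1, 2)])
        se = np.sqrt(expected * (1 - expected) / n)
        assert (np.abs(observed - expected) < 3 * se + 1e-12).all()

    def test_mean_dosage_is_two_f(self):
        panel = simulate_panel("VTE", seed=1)
        gm = simulate_genotypes(100_000, panel, seed=7)
        freqs = np.array([s.risk_freq for s in panel])
        means = gm.dosage.astype(float).mean(axis=0)
        se = np.sqrt(2 * freqs * (1 - freqs) / len(gm.subject_ids))
        assert (np.abs(means - 2 * freqs) < 3 * se).all()

    def test_missing_rate_applied(self):
        panel = simulate_panel("VTE", seed=1)
        gm = simulate_genotypes(20_000, panel, seed=7, missing_rate=0.1)
        frac = (gm.dosage == -1).mean()
        assert frac == pytest.approx(0.1, abs=0.01)


class TestCovariates:
    def test_empty_cohort(self):
        assert len(simulate_covariates(0)) == 0

    def test_ranges_and_determinism(self):
        a = simulate_covariates(5000, seed=3)
        b = simulate_covariates(5000, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert a["age"].between(40, 69).all()
        assert set(a["male"].unique()) <= {0, 1}
        assert (a["ascvd_risk"] > 0).all()
        assert a["race"].value_counts(normalize=True)["White"] > 0.9


class TestSepsis:
    def test_zero_rate_means_no_cases(self):
        cov = simulate_covariates(1000, seed=1)
        cfg = SimulationConfig(n_subjects=1000, sepsis_rate=0.0)
        out = simulate_sepsis(cov, cfg, seed=1)
        assert not out["sepsis"].any()

    def test_marginal_incidence_calibrated(self):
        n = 50_000
        cov = simulate_covariates(n, seed=11)
        cfg = SimulationConfig(n_subjects=n)
        out = simulate_sepsis(cov, cfg, seed=11)
        frac = out["sepsis"].mean()
        se = np.sqrt(0.022 * 0.978 / n)
        assert abs(frac - 0.022) < 3 * se

    def test_age_gradient_in_cases(self):
        n = 50_000
        cov = simulate_covariates(n, seed=12)
        cfg = SimulationConfig(n_subjects=n)
        out = simulate_sepsis(cov, cfg, seed=12)
        assert cov.loc[out["sepsis"], "age"].mean() > cov["age"].mean() + 0.5

    def test_onsets_within_followup(self):
        cov = simulate_covariates(5000, seed=13)
        cfg = SimulationConfig(n_subjects=5000)
        out = simulate_sepsis(cov, cfg, seed=13)
        onsets = out.loc[out["sepsis"], "sepsis_onset"]
        assert ((onsets > 0) & (onsets <= cfg.followup_years)).all()


class TestEventTimes:
    def test_zero_hazard_no_events(self, rng):
        t = simulate_event_times(np.zeros(100), np.full(100, np.nan), (0.0, 0.0, 0.0), rng)
        assert np.isinf(t).all()

    def test_constant_hazard_exponential_mean(self, rng):
        n = 50_000
        lam = 0.25
        t = simulate_event_times(np.full(n, lam), np.full(n, np.nan), (1.0, 1.0, 1.0), rng)
        se = (1 / lam) / np.sqrt(n)  # exponential sd = mean
        assert abs(t.mean() - 1 / lam) < 3 * se

    def test_multiplier_boosts_post_onset_hazard(self, rng):
        # with onset at 0 and w1=w2=w3=m the time is exponential at rate m*r
        n = 50_000
        r, m = 0.1, 5.0
        t = simulate_event_times(np.full(n, r), np.zeros(n), (m, m, m), rng)
        se = (1 / (m * r)) / np.sqrt(n)
        assert abs(t.mean() - 1 / (m * r)) < 3 * se

    def test_agrees_with_fine_grid_bernoulli(self, rng):
        """Marginal P(event by T) matches a dt=0.001 discrete-hazard walk."""
        n = 4000
        T = 3.0
        rate = 0.3
        onset = np.full(n, 1.0)  # sepsis at year 1 for everyone
        mult = (4.0, 2.0, 0.5)
        t = simulate_event_times(np.full(n, rate), onset, mult, rng)
        p_sampler = (t <= T).mean()

        dt = 0.001
        grid = np.arange(0, T, dt)
        w1_end = 1.0 + 30 / 365.25
        w2_end = 1.0 + 730 / 365.25
        m = np.where(
            grid < 1.0, 1.0, np.where(grid < w1_end, mult[0], np.where(grid < w2_end, mult[1], mult[2]))
        )
        p_step = rate * m * dt
        surv = np.exp(np.log1p(-p_step).sum())  # closed-form of the Bernoulli walk
        draws = rng.random((n, len(grid))) < p_step[None, :]
        p_brute = draws.any(axis=1).mean()
        p_expected = 1 - surv
        se = np.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(p_sampler - p_brute) < 3 * np.sqrt(2) * se
        assert abs(p_sampler - p_expected) < 3 * se


class TestFullCohort:
    def test_bit_exact_reproducibility(self):
        cfg = SimulationConfig(n_subjects=800, seed=21)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.events, b.events)
        pd.testing.assert_frame_equal(a.registry, b.registry)
        assert a.panels == b.panels

    def test_event_dates_within_followup_span(self):
        cfg = SimulationConfig(n_subjects=2000, seed=22, prevalent_sepsis_frac=0.0)
        sim = simulate_cohort(cfg)
        start = sim.registry["recruit_date"].min()
        end = sim.registry["followup_end"].max()
        assert (sim.events["date"] >= start).all()
        assert (sim.events["date"] <= end).all()

    def test_death_truncates_events(self):
        cfg = SimulationConfig(n_subjects=5000, seed=23, death_rate=0.05)
        sim = simulate_cohort(cfg)
        merged = sim.events.merge(
            sim.registry[["subject_id", "death_date"]], on="subject_id"
        )
        died = merged["death_date"].notna()
        assert (merged.loc[died, "date"] <= merged.loc[died, "death_date"]).all()

    def test_gamma_zero_skips_genotypes(self):
        cfg = SimulationConfig(n_subjects=200, seed=24, grs_exponent=0.0)
        sim = simulate_cohort(cfg)
        assert sim.grs is None and sim.genotypes == {}

    def test_gamma_zero_grs_groups_are_null(self, rng):
        """With gamma=0 the GRS has no effect on events: log-rank p across
        GRS groups is uniform over replicates."""
        panel = simulate_panel("VTE", seed=0)
        ps = []
        for rep in range(120):
            r = np.random.default_rng(1000 + rep)
            n = 1500
            gm = simulate_genotypes(n, panel, r)
            grs = compute_grs_matrix(gm, panel)
            base = np.full(n, 0.15)  # gamma=0: hazard free of GRS
            t = simulate_event_times(base, np.full(n, np.nan), (1, 1, 1), r)
            obs = np.minimum(t, 12.6)
            ev = t <= 12.6
            groups = grs["group"].to_numpy()
            if len(np.unique(groups)) < 2:
                continue
            _, _, p = logrank_test(obs, ev, groups)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.005

    def test_unit_multipliers_make_sepsis_null(self):
        """With all window multipliers 1 sepsis does not shift event times."""
        ps = []
        for rep in range(80):
            cfg = SimulationConfig(
                n_subjects=1200,
                seed=3000 + rep,
                grs_exponent=0.0,
                sepsis_covariate_effects={},
                covariate_effects={},
                sepsis_hr_windows={t: (1.0, 1.0, 1.0) for t in ("MI", "IS", "VTE")},
                baseline_hazards={"MI": 0.02, "IS": 0.001, "VTE": 0.001},
                sepsis_rate=0.15,
            )
            sim = simulate_cohort(cfg)
            rec = records_from_truth(sim.truth, "MI", cfg.followup_years)
            if rec["event"].sum() < 5 or rec["sepsis"].nunique() < 2:
                continue
            _, _, p = logrank_test(rec["time"], rec["event"], rec["sepsis"])
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.005

    def test_records_origin_convention(self):
        cfg = SimulationConfig(n_subjects=4000, seed=26)
        sim = simulate_cohort(cfg)
        rec = records_from_truth(sim.truth, "VTE", cfg.followup_years)
        septic = rec[rec["sepsis"] == 1].merge(
            sim.truth[["subject_id", "sepsis_onset"]], on="subject_id"
        )
        # time measured from onset never exceeds remaining follow-up
        assert (
            septic["time"] <= cfg.followup_years - septic["sepsis_onset"] + 1e-9
        ).all()
        non = rec[rec["sepsis"] == 0]
        assert (non["time"] <= cfg.followup_years + 1e-9).all()


class TestConfig:
    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_subjects=10, death_rate=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_subjects=10, sepsis_hr_windows={"MI": (-1, 1, 1)})

    def test_from_dict_round_trip_and_unknown_keys(self):
        cfg = SimulationConfig.from_dict({"n_subjects": 50, "seed": 9})
        assert cfg.n_subjects == 50
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig.from_dict({"bogus": 1})
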