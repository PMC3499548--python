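"""Burn-in, Geweke diagnostic, run pooling, interval summaries and the
Bayes-factor epoch-dating machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popcollapse.inference import HierarchicalPriors, TraceSet
from popcollapse.posterior import (CANONICAL_EPOCHS, EpochHypothesis,
                                   bayes_factor_interval, discard_burnin,
                                   drop_stuck_chains,
                                   epoch_bf_profile, epoch_hypothesis_test,
                                   generations_to_years, geweke_table,
                                   geweke_z, interval_summary, pool_runs,
                                   support_label, t_prior_years)


def make_trace(values_by_chain: dict[int, np.ndarray],
               name: str = "x", seed: int = 0) -> TraceSet:
    frames = []
    for c, vals in values_by_chain.items():
        frames.append(pd.DataFrame({
            "chain": c, "iteration": np.arange(1, len(vals) + 1), name: vals}))
    return TraceSet(pd.concat(frames, ignore_index=True), [name], seed)


class TestBurnin:
    def test_ten_percent_of_thousand(self):
        tr = make_trace({0: np.arange(1000.0)})
        out = discard_burnin(tr, 0.10)
        assert len(out.df) == 900
        assert out.df["x"].iloc[0] == 100.0

    def test_zero_fraction_is_identity(self):
        tr = make_trace({0: np.arange(50.0)})
        assert discard_burnin(tr, 0.0).df.equals(tr.df)

    def test_ceiling_convention(self):
        tr = make_trace({0: np.arange(100.0)})
        assert len(discard_burnin(tr, 0.99).df) == 1

    def test_per_chain_removal(self):
        tr = make_trace({0: np.arange(100.0), 1: np.arange(200.0)})
        out = discard_burnin(tr, 0.10)
        assert len(out.chain(0)) == 90
        assert len(out.chain(1)) == 180

    def test_empty_trace_rejected(self):
        tr = make_trace({0: np.arange(10.0)})
        tr.df = tr.df.iloc[:0]
        with pytest.raises(ValueError):
            discard_burnin(tr, 0.1)


class TestGeweke:
    def test_null_behaviour_iid_chain(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=10_000)
            if abs(geweke_z(x)) < 3:
                hits += 1
        assert hits >= 19

    def test_strong_drift_detected(self):
        x = np.linspace(0, 5, 5000) + np.random.default_rng(1).normal(
            scale=0.5, size=5000)
        assert abs(geweke_z(x)) > 3

    def test_constant_chain_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            geweke_z(np.ones(1000))

    def test_table_shape_and_nan_for_degenerate(self):
        tr = make_trace({0: np.ones(500), 1: np.random.default_rng(0).normal(
            size=500)})
        tab = geweke_table(tr)
        assert np.isnan(tab.loc[tab["chain"] == 0, "x"]).all()
        assert np.isfinite(tab.loc[tab["chain"] == 1, "x"]).all()


class TestPooling:
    def test_four_runs_concatenate(self):
        runs = [make_trace({0: np.arange(900.0)}, seed=s) for s in range(4)]
        pooled = pool_runs(runs)
        assert len(pooled.df) == 3600
        assert len(pooled.chains) == 4
        assert len(pooled.meta["pooled_from"]) == 4

    def test_single_run_identity_values(self):
        tr = make_trace({0: np.arange(10.0)})
        pooled = pool_runs([tr])
        assert pooled.df["x"].tolist() == tr.df["x"].tolist()

    def test_mismatched_parameters_rejected(self):
        a = make_trace({0: np.arange(10.0)}, name="x")
        b = make_trace({0: np.arange(10.0)}, name="y")
        with pytest.raises(ValueError, match="parameterization"):
            pool_runs([a, b])

    def test_pooled_quantiles_match_per_run(self):
        rng = np.random.default_rng(3)
        runs = [make_trace({0: rng.normal(size=4000)}) for _ in range(3)]
        pooled = pool_runs(runs)
        q_pool = np.quantile(pooled.df["x"], [0.25, 0.75])
        for r in runs:
            q_run = np.quantile(r.df["x"], [0.25, 0.75])
            assert np.allclose(q_pool, q_run, atol=0.08)


class TestStuckChainControl:
    @staticmethod
    def _trace_with_loglik(lls: dict[int, float]) -> TraceSet:
        frames = []
        rng = np.random.default_rng(0)
        for c, ll in lls.items():
            frames.append(pd.DataFrame({
                "chain": c, "iteration": np.arange(1, 201),
                "x": rng.normal(size=200), "loglik": ll + rng.normal(size=200)}))
        return TraceSet(pd.concat(frames, ignore_index=True), ["x"], 0)

    def test_trailing_chain_dropped(self):
        tr = self._trace_with_loglik({0: -100.0, 1: -103.0, 2: -160.0})
        kept, stuck = drop_stuck_chains(tr, burnin=0.1, tol=20.0)
        assert stuck == [2]
        assert kept.chains == [0, 1]

    def test_agreeing_chains_all_kept(self):
        tr = self._trace_with_loglik({0: -100.0, 1: -108.0})
        kept, stuck = drop_stuck_chains(tr, burnin=0.1, tol=20.0)
        assert stuck == []
        assert kept.chains == [0, 1]

    def test_best_chain_always_survives(self):
        tr = self._trace_with_loglik({0: -500.0})
        kept, stuck = drop_stuck_chains(tr, burnin=0.1)
        assert kept.chains == [0] and stuck == []

    def test_missing_loglik_column_rejected(self):
        tr = make_trace({0: np.arange(100.0)})
        with pytest.raises(ValueError, match="likelihood column"):
            drop_stuck_chains(tr)


class TestIntervals:
    def test_uniform_central_interval(self):
        x = np.random.default_rng(0).uniform(size=40_000)
        iv = interval_summary(x, 0.5)["central"]
        assert iv[0] == pytest.approx(0.25, abs=0.02)
        assert iv[1] == pytest.approx(0.75, abs=0.02)

    def test_hpd_no_wider_than_central(self):
        x = np.random.default_rng(1).lognormal(size=20_000)
        out = interval_summary(x, 0.9)
        w_hpd = out["hpd"][1] - out["hpd"][0]
        w_cen = out["central"][1] - out["central"][0]
        assert w_hpd <= w_cen + 1e-12

    def test_point_mass_zero_width(self):
        out = interval_summary(np.full(100, 3.3), 0.5)
        assert out["hpd"] == (3.3, 3.3)

    def test_hpd_matches_arviz(self):
        az = pytest.importorskip("arviz")
        x = np.random.default_rng(2).gamma(2.0, size=30_000)
        ours = interval_summary(x, 0.9)["hpd"]
        ref = az.hdi(x, hdi_prob=0.9)
        assert ours[0] == pytest.approx(ref[0], abs=0.02)
        assert ours[1] == pytest.approx(ref[1], abs=0.05)


class TestYearsConversion:
    def test_generation_time_scaling(self):
        assert generations_to_years([100], 8)[0] == 800
        assert generations_to_years([100], 25)[0] == 2500

    def test_median_scales_linearly(self):
        x = np.random.default_rng(0).lognormal(5, 1, size=5000)
        m8 = np.median(generations_to_years(x, 8))
        m25 = np.median(generations_to_years(x, 25))
        assert m25 / m8 == pytest.approx(25 / 8, rel=1e-12)

    def test_invalid_generation_time(self):
        with pytest.raises(ValueError):
            generations_to_years([1.0], 0)


class TestBayesFactors:
    def test_posterior_equal_prior_gives_unit_bf(self):
        prior = stats.lognorm(s=1.0, scale=2000.0)
        x = prior.rvs(size=100_000, random_state=0)
        for hyp in CANONICAL_EPOCHS:
            bf = bayes_factor_interval(x, prior, hyp).bf
            assert bf == pytest.approx(1.0, abs=0.12)

    def test_all_mass_inside_is_bounded(self):
        x = np.full(500, 1000.0)
        prior = stats.uniform(loc=0, scale=4000)  # half mass in (0, 2000]
        res = bayes_factor_interval(x, prior, (0.0, 2000.0))
        assert res.bounded_below
        assert res.bf >= 500 * (0.5 / 0.5) * 0.99  # ~M with even prior odds

    def test_quadrature_oracle_shifted_lognormal(self):
        """Interval BF from samples matches the analytic mass ratio within 5%
        at 1e5 samples."""
        prior = stats.lognorm(s=2.0 * np.log(10), scale=8.0 * 1e5)
        post_dist = stats.lognorm(s=0.8, scale=1500.0)
        x = post_dist.rvs(size=100_000, random_state=1)
        res = bayes_factor_interval(x, prior, (200.0, 5000.0))
        po = post_dist.cdf(5000) - post_dist.cdf(200)
        pr = prior.cdf(5000) - prior.cdf(200)
        expected = (po / (1 - po)) / (pr / (1 - pr))
        assert res.bf == pytest.approx(expected, rel=0.05)

    def test_prior_without_mass_in_interval_rejected(self):
        x = np.full(10, 50.0)
        prior = stats.uniform(loc=1000, scale=10)  # no mass below 1000
        with pytest.raises(ValueError, match="not testable"):
            bayes_factor_interval(x, prior, (0.0, 200.0))

    def test_support_thresholds_switch_exactly(self):
        assert support_label(2.9999) == "none"
        assert support_label(3.0) == "substantial"
        assert support_label(9.9999) == "substantial"
        assert support_label(10.0) == "strong"


class TestEpochProfile:
    def test_default_profile_has_hundred_windows(self):
        prior = stats.lognorm(s=2.0, scale=1e4)
        x = prior.rvs(size=2000, random_state=0)
        prof = epoch_bf_profile(x, prior)
        assert len(prof) == 100
        assert prof[0].hypothesis.lo == 0.0
        assert prof[-1].hypothesis.hi == 50_000.0

    def test_concentrated_posterior_peaks_in_its_window(self):
        prior = stats.lognorm(s=2.0, scale=1e4)
        x = np.random.default_rng(0).normal(750.0, 30.0, size=5000)
        prof = epoch_bf_profile(x, prior)
        best = max(prof, key=lambda r: -np.inf if np.isnan(r.bf) else r.bf)
        assert (best.hypothesis.lo, best.hypothesis.hi) == (500.0, 1000.0)

    def test_prior_equal_posterior_flat_profile(self):
        prior = stats.lognorm(s=1.0, scale=5000.0)
        x = prior.rvs(size=200_000, random_state=3)
        prof = epoch_bf_profile(x, prior)
        finite = [r.bf for r in prof if np.isfinite(r.bf) and not r.bounded_below]
        assert np.median(np.abs(np.log(finite))) < 0.35


class TestEpochHypotheses:
    def test_farmer_epoch_wins_when_mass_concentrates_there(self):
        prior = stats.lognorm(s=2.0 * np.log(10), scale=1e4)
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.uniform(250, 4500, size=9500),
                            rng.uniform(6000, 90_000, size=500)])
        ranked = epoch_hypothesis_test(x, prior)
        assert ranked[0].hypothesis.name == "H2"
        assert ranked[0].bf > 3

    def test_posterior_equal_prior_no_support_anywhere(self):
        prior = stats.lognorm(s=1.2, scale=8000.0)
        x = prior.rvs(size=100_000, random_state=5)
        ranked = epoch_hypothesis_test(x, prior)
        for r in ranked:
            assert r.bf == pytest.approx(1.0, abs=0.25)
            assert r.support == "none"

    def test_recent_mass_ranks_forest_exploitation_first(self):
        prior = stats.lognorm(s=2.0, scale=5000.0)
        x = np.random.default_rng(6).uniform(10, 150, size=3000)
        ranked = epoch_hypothesis_test(x, prior)
        assert ranked[0].hypothesis.name == "H1"

    def test_h2_split_subperiods(self):
        prior = stats.lognorm(s=2.0, scale=5000.0)
        x = np.random.default_rng(7).uniform(300, 1800, size=3000)
        ranked = epoch_hypothesis_test(x, prior, split_h2=True)
        assert ranked[0].hypothesis.name == "H2.1"

    def test_epoch_partition_covers_horizon(self):
        lo = min(e.lo for e in CANONICAL_EPOCHS)
        hi = max(e.hi for e in CANONICAL_EPOCHS)
        assert (lo, hi) == (0.0, 100_000.0)
        edges = sorted([(e.lo, e.hi) for e in CANONICAL_EPOCHS])
        for (a, b), (c, d) in zip(edges, edges[1:]):
            assert b == c  # contiguous, non-overlapping

    def test_invalid_hypothesis_rejected(self):
        with pytest.raises(ValueError):
            EpochHypothesis("bad", 10.0, 5.0)


class TestTPrior:
    def test_analytic_prior_matches_sampling(self):
        pr = HierarchicalPriors()
        dist = t_prior_years(pr, 25.0)
        rng = np.random.default_rng(8)
        samples = 25.0 * 10 ** rng.normal(pr.mean_log10_T, pr.sd_log10_T,
                                          size=200_000)
        for q in (0.1, 0.5, 0.9):
            assert dist.ppf(q) == pytest.approx(np.quantile(samples, q),
                                                rel=0.05)


class TestPlots:
    def test_density_and_profile_plots_render(self):
        import matplotlib
        matplotlib.use("Agg")
        from scipy import stats as st

        from popcollapse.plots import plot_bf_profile, plot_posterior_density

        tr = make_trace({0: np.random.default_rng(0).normal(size=500),
                         1: np.random.default_rng(1).normal(size=500)})
        ax = plot_posterior_density(tr, "x", prior=st.norm())
        assert ax.get_xlabel() == "x"
        prior = st.lognorm(s=1.0, scale=5000.0)
        prof = epoch_bf_profile(prior.rvs(size=2000, random_state=2), prior)
        ax = plot_bf_profile(prof)
        assert ax.get_ylabel() == "ln BF"
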