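"""Bayesian psychometric fitting, z-transform pooling, group splits."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from avcausal.psychometrics import (
    BayesianPsychometric, fit_psychometric, fit_all_cells, z_transform,
    split_fit_switch, split_fit_duration, split_fit_causal,
    MU_RANGE, LOG_SIGMA_RANGE,
)
from conftest import make_psychometric_trials

FAST = dict(n_samples=1000, n_burn=1000)


def make_table(mu, sigma, n, rng, subject="s0", condition="temporal",
               modality="AV", jitter=True):
    x, y = make_psychometric_trials(mu, sigma, n, rng)
    jit = rng.choice(np.arange(-250, 251, 50), size=n) if jitter else 0
    prev = rng.choice(["A", "V", "AV"], size=n)
    return pd.DataFrame({
        "subject": subject, "condition": condition, "modality": modality,
        "rate_diff": x, "duration_jitter_ms": jit, "response_faster": y,
        "prev_modality": prev})


class TestFit:
    def test_recovers_generating_parameters(self, rng):
        x, y = make_psychometric_trials(0.5, 2.0, 2000, rng)
        est = BayesianPsychometric(random_state=1).fit(x, y)
        assert est.mu_ == pytest.approx(0.5, abs=0.3)
        assert est.sigma_ == pytest.approx(2.0, rel=0.15)

    def test_draws_respect_prior_support(self, rng):
        x, y = make_psychometric_trials(0.0, 2.0, 200, rng)
        post = BayesianPsychometric(random_state=2, **FAST).fit(x, y).posterior_
        assert post.n_samples == 1000
        assert np.all((post.mu_samples > MU_RANGE[0])
                      & (post.mu_samples < MU_RANGE[1]))
        logs = np.log(post.sigma_samples)
        assert np.all((logs > LOG_SIGMA_RANGE[0])
                      & (logs < LOG_SIGMA_RANGE[1]))
        assert post.ci95["mu"][0] <= post.mu_hat <= post.ci95["mu"][1]

    def test_step_data_pushes_sigma_to_prior_floor(self, rng):
        x = np.tile([-3.0, -0.3, 0.3, 3.0], 100)
        y = (x > 0).astype(int)
        post = BayesianPsychometric(random_state=3, **FAST).fit(x, y).posterior_
        # noiseless step: sigma posterior concentrates near exp(-2.3) ~ 0.1
        assert post.sigma_hat < 0.2
        assert post.ci95["sigma"][0] < 0.12

    def test_degenerate_responses_warn(self, rng):
        x = rng.uniform(-6, 6, 50)
        with pytest.warns(UserWarning, match="degenerate"):
            BayesianPsychometric(random_state=4, n_samples=200,
                                 n_burn=200).fit(x, np.ones(50))

    def test_seed_reproducibility(self, rng):
        x, y = make_psychometric_trials(0.0, 2.0, 300, rng)
        p1 = BayesianPsychometric(random_state=7, **FAST).fit(x, y).posterior_
        p2 = BayesianPsychometric(random_state=7, **FAST).fit(x, y).posterior_
        assert np.array_equal(p1.mu_samples, p2.mu_samples)
        assert np.array_equal(p1.sigma_samples, p2.sigma_samples)

    def test_matches_independent_ensemble_sampler(self, rng):
        # cross-check the Metropolis posterior against emcee on one dataset
        emcee = pytest.importorskip("emcee")
        from avcausal.psychometrics import _log_posterior

        x, y = make_psychometric_trials(1.0, 2.0, 500, rng)
        mine = BayesianPsychometric(random_state=8).fit(x, y).posterior_

        nw = 16
        p0 = np.column_stack([rng.normal(1, 0.2, nw),
                              rng.normal(np.log(2), 0.1, nw)])
        sampler = emcee.EnsembleSampler(nw, 2, _log_posterior, args=(x, y))
        state = sampler.run_mcmc(p0, 600, progress=False)
        chain = sampler.get_chain(discard=200, flat=True)
        assert mine.mu_hat == pytest.approx(chain[:, 0].mean(), abs=0.1)
        assert mine.sigma_hat == pytest.approx(
            np.exp(chain[:, 1]).mean(), abs=0.15)

    def test_coverage_of_credible_intervals(self, rng):
        # 95% CIs should cover the generating parameters in most of 100
        # small replicate fits
        hits_mu = hits_sigma = 0
        for i in range(100):
            x, y = make_psychometric_trials(0.0, 2.0, 200, rng)
            post = BayesianPsychometric(
                random_state=100 + i, n_samples=600, n_burn=800).fit(
                    x, y).posterior_
            lo, hi = post.ci95["mu"]
            hits_mu += lo <= 0.0 <= hi
            lo, hi = post.ci95["sigma"]
            hits_sigma += lo <= 2.0 <= hi
        assert hits_mu >= 90
        assert hits_sigma >= 90


class TestZTransform:
    def test_point_identities(self, rng):
        table = make_table(0.0, 2.0, 400, rng)
        fits = fit_all_cells(table, seed=0, **FAST)
        post = fits[("s0", "temporal", "AV")]
        z = z_transform(table, fits)
        # r = mu_hat -> z = 0; r = mu_hat + sigma_hat -> z = 1
        probe = table.iloc[:2].copy()
        probe["rate_diff"] = [post.mu_hat, post.mu_hat + post.sigma_hat]
        zp = z_transform(probe, fits)
        assert zp["z_level"].to_numpy() == pytest.approx([0.0, 1.0])
        assert len(z) == len(table)

    def test_missing_cell_raises(self, rng):
        table = make_table(0.0, 2.0, 100, rng)
        with pytest.raises(KeyError):
            z_transform(table, {})

    def test_pooled_refit_is_standardized(self, rng):
        # refitting all z-scored trials should give mu ~ 0, sigma ~ 1
        tables = [make_table(mu, sg, 2000, rng, subject=s)
                  for s, mu, sg in [("a", -1.0, 1.5), ("b", 1.0, 3.0)]]
        table = pd.concat(tables, ignore_index=True)
        fits = fit_all_cells(table, seed=1, **FAST)
        z = z_transform(table, fits)
        refit = fit_psychometric(z, level_col="z_level", seed=2, **FAST)
        assert abs(refit.mu_hat) < 0.1
        assert abs(refit.sigma_hat - 1.0) < 0.1


class TestSplits:
    def test_switch_split_partitions_trials(self, rng):
        table = make_table(0.0, 2.0, 600, rng)
        table["z_level"] = table["rate_diff"] / 2.0
        stay, switch = split_fit_switch(table, seed=0, **FAST)
        n_stay = (table["prev_modality"] == table["modality"]).sum()
        n_switch = ((table["prev_modality"].notna())
                    & (table["prev_modality"] != table["modality"])).sum()
        assert n_stay + n_switch == table["prev_modality"].notna().sum()
        assert stay.n_samples == switch.n_samples == 1000

    def test_null_switch_effect_has_overlapping_cis(self, rng):
        # same generator for both splits -> sigma CIs overlap in most
        # replicates
        overlaps = 0
        for i in range(20):
            table = make_table(0.0, 2.0, 800, np.random.default_rng(i))
            table["z_level"] = table["rate_diff"] / 2.0
            stay, switch = split_fit_switch(table, seed=i, n_samples=500,
                                            n_burn=800)
            lo1, hi1 = stay.ci95["sigma"]
            lo2, hi2 = switch.ci95["sigma"]
            overlaps += (lo1 <= hi2) and (lo2 <= hi1)
        assert overlaps >= 18

    def test_switch_cost_detected_at_scale(self, rng):
        # sigma_switch = 1.5 sigma_stay, 12000 trials -> separated CIs
        n = 12_000
        prev = rng.choice(["AV", "A"], size=n)
        sigma = np.where(prev == "AV", 1.0, 1.5)
        x = rng.choice([-3, -2, -1, -0.5, 0.5, 1, 2, 3.0], size=n)
        y = (rng.uniform(size=n) < norm.cdf(x / sigma)).astype(int)
        table = pd.DataFrame({
            "subject": "s0", "condition": "temporal", "modality": "AV",
            "rate_diff": x, "duration_jitter_ms": 0, "response_faster": y,
            "prev_modality": prev, "z_level": x})
        stay, switch = split_fit_switch(table, seed=5, **FAST)
        assert stay.ci95["sigma"][1] < switch.ci95["sigma"][0]

    def test_counting_observer_has_negative_duration_slope(self):
        from avcausal.synthetic import simulate_exp1_dataset, ObserverSpec

        trials = simulate_exp1_dataset(
            {"s0": ObserverSpec(sigma_A=1.5, sigma_V=1.5,
                                counting_weight=1.0)},
            conditions=("no-conflict",), n_per_cell=60, seed=11,
            modalities=("AV",))
        fits = fit_all_cells(trials, seed=3, **FAST)
        z = z_transform(trials, fits)
        res = split_fit_duration(z, seed=4, n_samples=400, n_burn=600)
        slope = res["regression"].params[1]
        assert slope < 0
        assert res["regression"].pvalues[1] < 0.05

    def test_rate_observer_slope_ci_covers_zero(self):
        from avcausal.synthetic import simulate_exp1_dataset, ObserverSpec

        trials = simulate_exp1_dataset(
            {"s0": ObserverSpec(sigma_A=1.5, sigma_V=1.5,
                                counting_weight=0.0)},
            conditions=("no-conflict",), n_per_cell=60, seed=12,
            modalities=("AV",))
        fits = fit_all_cells(trials, seed=5, **FAST)
        z = z_transform(trials, fits)
        res = split_fit_duration(z, seed=6, n_samples=400, n_burn=600)
        lo, hi = res["regression"].conf_int()[1]
        assert lo <= 0.0 <= hi

    def test_duration_split_excludes_small_jitter(self, rng):
        table = make_table(0.0, 2.0, 1200, rng)
        table["z_level"] = table["rate_diff"] / 2.0
        res = split_fit_duration(table, seed=7, n_samples=300, n_burn=400)
        n_short = (table["duration_jitter_ms"] <= -100).sum()
        n_long = (table["duration_jitter_ms"] >= 100).sum()
        assert n_short + n_long < len(table)  # middle jitters omitted
        assert len(res["pse_by_jitter"]) == 11

    def test_causal_split_counts_and_empty_group(self, rng):
        table = make_table(0.0, 2.0, 400, rng)
        table["z_level"] = table["rate_diff"] / 2.0
        offs = rng.uniform(0, 200, size=len(table))
        common, separate = split_fit_causal(table, offs, boundary_ms=103,
                                            seed=8, n_samples=300,
                                            n_burn=400)
        assert (offs <= 103).sum() + (offs > 103).sum() == len(table)
        with pytest.raises(ValueError):
            split_fit_causal(table, offs, boundary_ms=-1, seed=9)

    def test_integration_gated_by_boundary_separates_sigmas(self, rng):
        # observer integrates only when the offset is under the boundary
        n = 12_000
        offs = rng.uniform(0, 206, size=n)
        sigma = np.where(offs <= 103, 1.0, 1.8)
        x = rng.choice([-3, -2, -1, -0.5, 0.5, 1, 2, 3.0], size=n)
        y = (rng.uniform(size=n) < norm.cdf(x / sigma)).astype(int)
        table = pd.DataFrame({
            "subject": "s0", "condition": "temporal", "modality": "AV",
            "rate_diff": x, "duration_jitter_ms": 0, "response_faster": y,
            "prev_modality": None, "z_level": x})
        common, separate = split_fit_causal(table, offs, boundary_ms=103,
                                            seed=10, **FAST)
        assert common.ci95["sigma"][1] < separate.ci95["sigma"][0]
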