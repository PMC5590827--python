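"""Causal-judgement logistic mixed model: fit, bootstrap, boundary."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from avcausal.glmm import (
    GLMMFit, LogisticGLMM, fit_causal_glmm, bootstrap_pvalues,
    integration_boundary, feature_correlations, UndefinedBoundaryError,
)
from conftest import make_glmm_table


def printed_fit(b0=1.76, b_off=-17.0):
    return GLMMFit(beta={"intercept": b0, "max_offset_s": b_off},
                   random_intercept_sd=0.5, loglik=0.0,
                   vcov=np.eye(3), term_names=["intercept", "max_offset_s"])


class TestBoundary:
    def test_reference_coefficients_give_103ms(self):
        assert integration_boundary(printed_fit()) == \
            pytest.approx(103.5, abs=0.1)

    def test_zero_intercept_gives_zero_boundary(self):
        assert integration_boundary(printed_fit(b0=0.0)) == 0.0

    def test_probability_at_boundary_is_half(self):
        fit = printed_fit()
        b_s = integration_boundary(fit) / 1000.0
        eta = fit.beta_intercept + fit.beta_offset * b_s
        assert expit(eta) == pytest.approx(0.5, abs=1e-12)

    def test_zero_offset_effect_undefined(self):
        with pytest.raises(UndefinedBoundaryError):
            integration_boundary(printed_fit(b_off=0.0))

    def test_invariant_to_offset_rescaling(self):
        # offsets in ms with the slope rescaled accordingly
        ms_fit = GLMMFit(beta={"intercept": 1.76, "max_offset_s": -0.017},
                         random_intercept_sd=0.5, loglik=0.0,
                         vcov=np.eye(3),
                         term_names=["intercept", "max_offset_s"])
        assert integration_boundary(ms_fit) == pytest.approx(
            1000.0 * integration_boundary(printed_fit()), rel=1e-12)


class TestFit:
    def test_zero_random_effect_reduces_to_plain_logistic(
            self, exp2_feature_pool):
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        table = make_glmm_table(exp2_feature_pool,
                                (1.76, 0.0, -17.0, 0.0), tau=0.0,
                                n_subjects=6, n_per_subject=250, rng=rng)
        fit = fit_causal_glmm(table, include_sync=False,
                              include_interaction=False)
        X = sm.add_constant(table["max_offset_s"].to_numpy())
        ref = sm.Logit(table["response_common"].to_numpy(), X).fit(disp=0)
        assert fit.beta_intercept == pytest.approx(ref.params[0], abs=1e-2)
        assert fit.beta_offset == pytest.approx(ref.params[1], abs=5e-2)
        assert fit.random_intercept_sd < 0.1

    def test_all_zero_covariates_give_logit_of_rate(self):
        rng = np.random.default_rng(22)
        n = 4000
        table = pd.DataFrame({
            "subject": np.repeat(np.arange(4), n // 4),
            "prop_sync": 0.0, "max_offset_s": 0.0,
            "response_common": (rng.uniform(size=n) < 0.7).astype(int)})
        fit = fit_causal_glmm(table, include_sync=False,
                              include_interaction=False)
        target = logit(table["response_common"].mean())
        assert fit.beta_intercept == pytest.approx(target, abs=0.1)

    def test_recovers_generating_coefficients(self, exp2_feature_pool):
        rng = np.random.default_rng(23)
        table = make_glmm_table(exp2_feature_pool,
                                (1.76, 0.0, -17.0, 0.0), tau=0.5,
                                n_subjects=10, n_per_subject=600, rng=rng)
        fit = fit_causal_glmm(table, include_sync=False,
                              include_interaction=False)
        assert fit.beta_intercept == pytest.approx(1.76, abs=0.5)
        assert fit.beta_offset == pytest.approx(-17.0, abs=3.0)
        assert fit.random_intercept_sd == pytest.approx(0.5, abs=0.35)

    def test_matches_lme4_oracle(self, exp2_feature_pool, tmp_path):
        # independent reference fit via R lme4 (Laplace), same data
        rng = np.random.default_rng(24)
        table = make_glmm_table(exp2_feature_pool,
                                (1.76, 0.4, -17.0, 0.0), tau=0.5,
                                n_subjects=8, n_per_subject=250, rng=rng)
        fit = fit_causal_glmm(table, include_interaction=False)
        csv = tmp_path / "glmm.csv"
        table.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(response_common ~ prop_sync + max_offset_s +
                       (1 | subject), data = d, family = binomial)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), sep = "\\n")
        """)
        rpath = tmp_path / "fit.R"
        rpath.write_text(script)
        out = subprocess.run(["Rscript", "--vanilla", str(rpath)],
                             capture_output=True, text=True, check=True)
        b0, b_sync, b_off, tau = map(float, out.stdout.split())
        assert fit.beta_intercept == pytest.approx(b0, abs=0.05)
        assert fit.beta_sync == pytest.approx(b_sync, abs=0.05)
        assert fit.beta_offset == pytest.approx(b_off, abs=0.15)
        assert fit.random_intercept_sd == pytest.approx(tau, abs=0.05)

    def test_single_group_rejected(self):
        table = pd.DataFrame({"subject": 0, "prop_sync": [0.1] * 10,
                              "max_offset_s": np.linspace(0, 0.2, 10),
                              "response_common": [0, 1] * 5})
        with pytest.raises(ValueError):
            fit_causal_glmm(table)

    def test_loglik_at_fit_beats_generating_parameters(
            self, exp2_feature_pool):
        rng = np.random.default_rng(25)
        table = make_glmm_table(exp2_feature_pool,
                                (1.76, 0.0, -17.0, 0.0), tau=0.5,
                                n_subjects=8, n_per_subject=300, rng=rng)
        fit = fit_causal_glmm(table, include_sync=False,
                              include_interaction=False)
        est = LogisticGLMM()
        X = table["max_offset_s"].to_numpy().reshape(-1, 1)
        y = table["response_common"].to_numpy(float)
        g = table["subject"].to_numpy()
        z, w = np.polynomial.hermite.hermgauss(15)
        codes, _ = pd.factorize(g)
        ll_true = -est._neg_loglik(np.array([1.76, -17.0, np.log(0.5)]),
                                   np.column_stack([np.ones(len(y)), X]),
                                   y, codes, codes.max() + 1, z, w)
        assert fit.loglik >= ll_true - 1e-6


class TestBootstrap:
    def test_floor_ci_nesting_and_determinism(self, exp2_feature_pool):
        rng = np.random.default_rng(26)
        table = make_glmm_table(exp2_feature_pool,
                                (1.76, 0.0, -17.0, 0.0), tau=0.3,
                                n_subjects=5, n_per_subject=80, rng=rng)
        fit = fit_causal_glmm(table, include_sync=False,
                              include_interaction=False)
        boot = bootstrap_pvalues(fit, table, n_boot=59, seed=1)
        # strong offset effect: no bootstrap draw crosses zero
        assert boot.bootstrap_p["max_offset_s"] == pytest.approx(1 / 60)
        lo, hi = boot.ci90["max_offset_s"]
        assert lo < fit.beta_offset < hi
        boot2 = bootstrap_pvalues(fit, table, n_boot=59, seed=1)
        assert boot.ci90 == boot2.ci90

    def test_null_coefficient_p_calibration(self, exp2_feature_pool):
        # data generated with b_sync = 0: the sync p-value should reject
        # at the 10% level about 10% of the time
        rejections = 0
        n_rep = 20
        for i in range(n_rep):
            rng = np.random.default_rng(3000 + i)
            table = make_glmm_table(exp2_feature_pool,
                                    (1.76, 0.0, -17.0, 0.0), tau=0.3,
                                    n_subjects=4, n_per_subject=60, rng=rng)
            fit = fit_causal_glmm(table, include_interaction=False)
            boot = bootstrap_pvalues(fit, table, n_boot=49, seed=i)
            rejections += boot.bootstrap_p["prop_sync"] < 0.1
        # binomial(20, 0.1): 0..6 rejections is the plausible range
        assert rejections <= 6


class TestCorrelations:
    def test_self_correlation_is_one(self, exp2_feature_pool):
        t = exp2_feature_pool.copy()
        t["max_offset_s"] = t["prop_sync"]
        r = feature_correlations(t)
        assert r.iloc[0]["r"] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        t = pd.DataFrame({
            "prop_sync": [0.1, 0.2, 0.0, 0.3, 0.15],
            "max_offset_s": [0.12, 0.08, 0.2, 0.05, 0.1],
            "rate_hz": [8, 10, 8, 14, 12.0]})
        x = t["prop_sync"].to_numpy()
        y = t["max_offset_s"].to_numpy()
        r_hand = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean())**2).sum()
                            * ((y - y.mean())**2).sum()))
        res = feature_correlations(t)
        assert res.iloc[0]["r"] == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_flagged(self):
        t = pd.DataFrame({"prop_sync": [0.1] * 5,
                          "max_offset_s": np.linspace(0, 0.2, 5),
                          "rate_hz": [8, 10, 12, 14, 8.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            res = feature_correlations(t)
        assert np.isnan(res.iloc[0]["r"])

    def test_too_few_rows(self):
        t = pd.DataFrame({"prop_sync": [0.1], "max_offset_s": [0.1],
                          "rate_hz": [8.0]})
        with pytest.raises(ValueError):
            feature_correlations(t)
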