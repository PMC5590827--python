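"""Bayesian cumulative-Gaussian psychometric fitting and group-level splits.

The observer's probability of judging a comparison stimulus "faster" than
the standard is modelled as ``P(faster) = Phi((x - mu) / sigma)`` where
``x`` is the rate difference (comparison - standard, events/s), ``mu`` is
the point of subjective equality (PSE) and ``sigma`` the sensitivity
threshold.  Posteriors are sampled under flat priors ``mu ~ U(-7, 7)`` and
``log(sigma) ~ U(-2.3, 1.6)`` with an adaptive random-walk Metropolis
sampler; 2000 draws are retained after burn-in.

Group-level analyses first z-transform each trial's stimulus level with the
per-cell point estimates (so every cell's psychometric function becomes
mu = 0, sigma = 1 in signal-to-noise units), pool the trials, and refit
within splits: by attention switching (previous trial same vs different
modality), by stimulus duration, and by the causal-judgement model's
common/separate classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

MU_RANGE = (-7.0, 7.0)
LOG_SIGMA_RANGE = (-2.3, 1.6)


@dataclass
class PsychometricPosterior:
    """Posterior over (mu, sigma) for one cumulative-Gaussian fit."""

    mu_samples: np.ndarray
    sigma_samples: np.ndarray
    mu_hat: float = field(init=False)
    sigma_hat: float = field(init=False)
    ci95: dict = field(init=False)
    accept_rate: float = np.nan

    def __post_init__(self):
        self.mu_samples = np.asarray(self.mu_samples, float)
        self.sigma_samples = np.asarray(self.sigma_samples, float)
        self.mu_hat = float(self.mu_samples.mean())
        self.sigma_hat = float(self.sigma_samples.mean())
        self.ci95 = {
            "mu": tuple(np.percentile(self.mu_samples, [2.5, 97.5])),
            "sigma": tuple(np.percentile(self.sigma_samples, [2.5, 97.5])),
        }

    @property
    def n_samples(self) -> int:
        return self.mu_samples.size

    def to_json_dict(self) -> dict:
        return {
            "mu_hat": self.mu_hat,
            "sigma_hat": self.sigma_hat,
            "ci95_mu": list(self.ci95["mu"]),
            "ci95_sigma": list(self.ci95["sigma"]),
            "accept_rate": self.accept_rate,
            "n_samples": int(self.n_samples),
        }


def _log_posterior(theta, x, y):
    """Flat-prior log posterior over theta = (mu, log sigma)."""
    mu, log_sigma = theta
    if not (MU_RANGE[0] < mu < MU_RANGE[1]):
        return -np.inf
    if not (LOG_SIGMA_RANGE[0] < log_sigma < LOG_SIGMA_RANGE[1]):
        return -np.inf
    p = norm.cdf((x - mu) / np.exp(log_sigma))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


class BayesianPsychometric(BaseEstimator):
    """Cumulative-Gaussian psychometric function with flat-prior MCMC.

    Scikit-learn style estimator: ``fit(X, y)`` takes stimulus levels
    (rate differences, shape ``(n,)`` or ``(n, 1)``) and binary "faster"
    responses; fitted attributes carry the posterior.

    Parameters
    ----------
    n_samples : int
        Retained posterior draws (after burn-in and thinning).
    n_burn : int
        Burn-in iterations, during which the proposal scale adapts toward
        a 25-45% acceptance rate.
    thin : int
        Keep every ``thin``-th post-burn-in draw.
    random_state : int or numpy.random.Generator or None
        Seed for the sampler.

    Attributes
    ----------
    posterior_ : PsychometricPosterior
    mu_, sigma_ : float
        Posterior means (PSE and sensitivity threshold).
    """

    def __init__(self, n_samples=2000, n_burn=2000, thin=2, random_state=None):
        self.n_samples = n_samples
        self.n_burn = n_burn
        self.thin = thin
        self.random_state = random_state

    def fit(self, X, y):
        x = np.asarray(X, float).reshape(-1)
        y = np.asarray(y, float).reshape(-1)
        if x.size != y.size:
            raise ValueError("X and y must have equal length")
        if x.size == 0:
            raise ValueError("no trials to fit")
        if np.unique(y).size < 2:
            warnings.warn("degenerate data: all responses identical; "
                          "posterior will hug the prior bounds")
        rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))

        # start at a crude moment-based guess, clipped inside the prior box
        p_hi = y[x > np.median(x)].mean() if np.any(x > np.median(x)) else 0.5
        theta = np.array([
            np.clip(np.median(x), MU_RANGE[0] + 0.1, MU_RANGE[1] - 0.1),
            np.clip(np.log(max(x.std(), 0.5)), LOG_SIGMA_RANGE[0] + 0.05,
                    LOG_SIGMA_RANGE[1] - 0.05),
        ])
        del p_hi
        logp = _log_posterior(theta, x, y)
        scale = np.array([0.5, 0.2])
        accepted = 0
        window_acc = 0
        kept = np.empty((self.n_samples, 2))
        n_iter = self.n_burn + self.n_samples * self.thin
        steps = rng.standard_normal((n_iter, 2))
        unif = np.log(rng.uniform(size=n_iter))
        k = 0
        for i in range(n_iter):
            prop = theta + steps[i] * scale
            logp_prop = _log_posterior(prop, x, y)
            if logp_prop - logp > unif[i]:
                theta, logp = prop, logp_prop
                accepted += 1
                window_acc += 1
            if i < self.n_burn and (i + 1) % 100 == 0:
                # adapt toward ~35% acceptance during burn-in only
                rate = window_acc / 100.0
                scale *= np.exp(0.5 * (rate - 0.35))
                window_acc = 0
            if i >= self.n_burn and (i - self.n_burn) % self.thin == 0:
                kept[k] = theta
                k += 1
        post = PsychometricPosterior(
            mu_samples=kept[:, 0],
            sigma_samples=np.exp(kept[:, 1]),
            accept_rate=accepted / n_iter,
        )
        self.posterior_ = post
        self.mu_ = post.mu_hat
        self.sigma_ = post.sigma_hat
        self.n_trials_ = int(x.size)
        return self

    def predict_proba(self, X):
        """P("faster") at each stimulus level, using posterior means."""
        x = np.asarray(X, float).reshape(-1)
        p = norm.cdf((x - self.mu_) / self.sigma_)
        return np.column_stack([1 - p, p])


def fit_psychometric(trials: pd.DataFrame, level_col="rate_diff",
                     response_col="response_faster", seed=None,
                     **kwargs) -> PsychometricPosterior:
    """Fit one psychometric function to a table of trials."""
    est = BayesianPsychometric(random_state=seed, **kwargs)
    est.fit(trials[level_col].to_numpy(), trials[response_col].to_numpy())
    return est.posterior_


CELL_COLS = ["subject", "condition", "modality"]


def fit_all_cells(trials: pd.DataFrame, seed=None, **kwargs) -> dict:
    """Independent psychometric fit per subject x condition x modality cell."""
    ss = np.random.SeedSequence(seed)
    fits = {}
    groups = trials.groupby(CELL_COLS, sort=True)
    seeds = ss.spawn(groups.ngroups)
    for (key, cell), child in zip(groups, seeds):
        fits[key] = fit_psychometric(cell, seed=np.random.default_rng(child),
                                     **kwargs)
    return fits


def z_transform(trials: pd.DataFrame, fits: dict,
                level_col="rate_diff") -> pd.DataFrame:
    """Express each trial's stimulus level in signal-to-noise units.

    The level ``r`` becomes ``(r - mu_hat) / sigma_hat`` using the point
    estimates of that trial's subject x condition x modality cell, so all
    cells share a common (mu = 0, sigma = 1) scale and can be pooled.
    """
    out = trials.copy()
    z = np.empty(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        key = (row.subject, row.condition, row.modality)
        if key not in fits:
            raise KeyError(f"no psychometric fit for cell {key}")
        post = fits[key]
        z[i] = (getattr(row, level_col) - post.mu_hat) / post.sigma_hat
    out["z_level"] = z
    return out


def _fit_z(trials, seed, **kwargs):
    return fit_psychometric(trials, level_col="z_level", seed=seed, **kwargs)


def split_fit_switch(ztrials: pd.DataFrame, seed=None, **kwargs):
    """Fit pooled z-scored trials split by modality repetition.

    "stay" trials follow a trial of the same modality condition; "switch"
    trials follow a different one.  Returns ``(stay_fit, switch_fit)``.
    """
    stay = ztrials[ztrials["prev_modality"] == ztrials["modality"]]
    switch = ztrials[(ztrials["prev_modality"].notna())
                     & (ztrials["prev_modality"] != ztrials["modality"])]
    if len(stay) == 0 or len(switch) == 0:
        raise ValueError("one of the stay/switch splits is empty")
    ss = np.random.SeedSequence(seed).spawn(2)
    return (_fit_z(stay, np.random.default_rng(ss[0]), **kwargs),
            _fit_z(switch, np.random.default_rng(ss[1]), **kwargs))


def split_fit_duration(ztrials: pd.DataFrame, seed=None, **kwargs):
    """Duration analyses on pooled z-scored trials.

    Returns a dict with ``short``/``long`` fits (jitter -250..-100 and
    +100..+250 ms; trials with |jitter| < 100 ms are omitted from the
    two-group split) and a ``regression`` of per-jitter PSE on the 11
    jitter levels (ordinary least squares), which separates rate-based
    from count-based observers: a counting observer shows a negative slope.
    """
    import statsmodels.api as sm

    jit = ztrials["duration_jitter_ms"]
    short = ztrials[(jit <= -100)]
    long_ = ztrials[(jit >= 100)]
    if len(short) == 0 or len(long_) == 0:
        raise ValueError("one of the short/long splits is empty")
    levels = np.sort(jit.unique())
    ss = np.random.SeedSequence(seed).spawn(2 + levels.size)
    short_fit = _fit_z(short, np.random.default_rng(ss[0]), **kwargs)
    long_fit = _fit_z(long_, np.random.default_rng(ss[1]), **kwargs)

    pses = []
    for lev, child in zip(levels, ss[2:]):
        sub = ztrials[jit == lev]
        pses.append(_fit_z(sub, np.random.default_rng(child), **kwargs).mu_hat)
    if levels.size < 11:
        warnings.warn(f"only {levels.size} of 11 jitter levels present; "
                      "PSE regression uses the available levels")
    X = sm.add_constant(levels.astype(float))
    ols = sm.OLS(np.asarray(pses), X).fit()
    return {
        "short": short_fit,
        "long": long_fit,
        "pse_by_jitter": pd.DataFrame({"jitter_ms": levels, "pse": pses}),
        "regression": ols,
    }


def split_fit_causal(ztrials: pd.DataFrame, max_offset_ms, boundary_ms,
                     seed=None, **kwargs):
    """Fit z-scored trials split by likely causal percept.

    Trials whose sequence pair has maximum click-flash offset at or below
    ``boundary_ms`` are classified "common source more likely"; the rest
    "separate sources more likely".  Returns ``(common_fit, separate_fit)``.
    """
    off = np.asarray(max_offset_ms, float)
    if off.size != len(ztrials):
        raise ValueError("one max offset per trial required")
    common = ztrials[off <= boundary_ms]
    separate = ztrials[off > boundary_ms]
    if len(common) == 0 or len(separate) == 0:
        raise ValueError("causal split produced an empty group")
    ss = np.random.SeedSequence(seed).spawn(2)
    return (_fit_z(common, np.random.default_rng(ss[0]), **kwargs),
            _fit_z(separate, np.random.default_rng(ss[1]), **kwargs))
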