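"""Logistic mixed-effects model of causality judgements.

The probability of a "common source" judgement on a temporal-conflict
trial is modelled as

    logit P(common) = b0 + b_sync * prop_sync + b_off * max_offset_s
                      + b_int * prop_sync * max_offset_s + u_subject,

with a Gaussian random intercept per subject, ``u ~ N(0, tau^2)``.
Covariates are deliberately uncentered and unscaled (offset in seconds,
proportion unitless) so that ``-b0 / b_off`` is directly the offset at
which P(common) = 0.5 — the integration boundary.

Estimation is marginal maximum likelihood: the per-subject random-effect
integral is one-dimensional and is evaluated with adaptive Gauss-Hermite
quadrature (nodes centred at each subject's conditional mode and scaled by
the local curvature; the Laplace approximation is the one-node special
case).  Inference uses a parametric bootstrap: response tables are
simulated from the fitted model and refitted, giving percentile confidence
intervals and two-sided p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, log_expit
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess1


class ConvergenceError(RuntimeError):
    """The mixed-model fit did not converge (e.g. complete separation)."""


class UndefinedBoundaryError(ValueError):
    """The integration boundary is undefined (zero offset effect)."""


@dataclass
class GLMMFit:
    """Fixed effects, random-intercept SD and inference summaries."""

    beta: dict                       # name -> estimate (log-odds units)
    random_intercept_sd: float
    loglik: float
    vcov: np.ndarray                 # Wald covariance of (beta..., log tau)
    term_names: list
    converged: bool = True
    ci90: dict = field(default_factory=dict)        # from bootstrap
    bootstrap_p: dict = field(default_factory=dict)
    n_boot_failed: int = 0

    @property
    def beta_intercept(self):
        return self.beta["intercept"]

    @property
    def beta_offset(self):
        return self.beta.get("max_offset_s", 0.0)

    @property
    def beta_sync(self):
        return self.beta.get("prop_sync", 0.0)

    @property
    def beta_interaction(self):
        return self.beta.get("interaction", 0.0)

    def wald_ci90(self):
        """Hessian-based 90% confidence intervals per fixed effect."""
        se = np.sqrt(np.diag(self.vcov))
        z = stats.norm.ppf(0.95)
        est = np.array([self.beta[t] for t in self.term_names])
        return {t: (est[i] - z * se[i], est[i] + z * se[i])
                for i, t in enumerate(self.term_names)}

    def to_json_dict(self):
        return {
            "beta": self.beta,
            "random_intercept_sd": self.random_intercept_sd,
            "loglik": self.loglik,
            "converged": self.converged,
            "ci90": {k: list(v) for k, v in self.ci90.items()},
            "bootstrap_p": self.bootstrap_p,
            "n_boot_failed": self.n_boot_failed,
        }


def _bernoulli_loglik_rows(eta, y):
    # y*log p + (1-y)*log(1-p), numerically stable
    return y * log_expit(eta) + (1 - y) * log_expit(-eta)


class LogisticGLMM(BaseEstimator):
    """Random-intercept logistic regression fitted by marginal ML.

    ``fit(X, y, groups)`` takes a design matrix *without* an intercept
    column (one is always prepended), binary responses, and a group label
    per row.  The per-group random-intercept integral is evaluated by
    adaptive Gauss-Hermite quadrature.

    Parameters
    ----------
    n_quad : int
        Quadrature nodes per group (1 = Laplace approximation).
    max_abs_beta : float
        Estimates beyond this magnitude are treated as evidence of
        complete separation and raise :class:`ConvergenceError`.

    Attributes
    ----------
    coef_ : ndarray of fixed effects (intercept first)
    tau_ : float, random-intercept SD
    loglik_ : float, marginal log likelihood at the optimum
    vcov_ : Wald covariance of (coef..., log tau)
    """

    def __init__(self, n_quad=15, max_iter=200, max_abs_beta=50.0,
                 tol=1e-8):
        self.n_quad = n_quad
        self.max_iter = max_iter
        self.max_abs_beta = max_abs_beta
        self.tol = tol

    def _neg_loglik(self, theta, X, y, group_idx, n_groups, z, w):
        beta, log_tau = theta[:-1], theta[-1]
        tau = np.exp(log_tau)
        eta0 = X @ beta
        # conditional mode per group by damped Newton (concave problem)
        u = np.zeros(n_groups)
        for _ in range(50):
            eta = eta0 + u[group_idx]
            p = expit(eta)
            grad = np.bincount(group_idx, weights=y - p,
                               minlength=n_groups) - u / tau**2
            hess = np.bincount(group_idx, weights=p * (1 - p),
                               minlength=n_groups) + 1.0 / tau**2
            step = grad / hess
            u = u + step
            if np.max(np.abs(step)) < 1e-10:
                break
        sd = 1.0 / np.sqrt(hess)
        # adaptive GH: u_t = u_hat + sqrt(2)*sd*z_t
        log_terms = np.empty((z.size, n_groups))
        for t in range(z.size):
            ut = u + np.sqrt(2.0) * sd * z[t]
            eta = eta0 + ut[group_idx]
            ll = np.bincount(group_idx,
                             weights=_bernoulli_loglik_rows(eta, y),
                             minlength=n_groups)
            log_prior = -0.5 * (ut / tau) ** 2 - np.log(tau) \
                - 0.5 * np.log(2 * np.pi)
            log_terms[t] = np.log(w[t]) + z[t] ** 2 + ll + log_prior
        from scipy.special import logsumexp
        log_int = logsumexp(log_terms, axis=0) + 0.5 * np.log(2.0) \
            + np.log(sd)
        return -float(np.sum(log_int))

    def fit(self, X, y, groups):
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size != 1:
            X = X.T
        y = np.asarray(y, float).reshape(-1)
        codes, _ = pd.factorize(np.asarray(groups))
        n_groups = codes.max() + 1
        if n_groups < 2:
            raise ValueError("need at least 2 groups (subjects)")
        if np.unique(y).size < 2:
            raise ValueError("both response values must be present")
        Xd = np.column_stack([np.ones(len(y)), X])
        z, w = np.polynomial.hermite.hermgauss(self.n_quad)

        # start from a plain logistic fit
        import statsmodels.api as sm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                start_beta = sm.Logit(y, Xd).fit(disp=0, maxiter=100).params
            except Exception:
                start_beta = np.zeros(Xd.shape[1])
        if not np.all(np.isfinite(start_beta)):
            start_beta = np.zeros(Xd.shape[1])
        theta0 = np.r_[start_beta, np.log(0.5)]

        obj = lambda th: self._neg_loglik(th, Xd, y, codes, n_groups, z, w)
        res = optimize.minimize(
            obj, theta0, method="L-BFGS-B",
            bounds=[(None, None)] * Xd.shape[1] + [(np.log(1e-4), np.log(50))],
            options={"maxiter": self.max_iter, "ftol": self.tol},
        )
        beta, log_tau = res.x[:-1], res.x[-1]
        if np.max(np.abs(beta)) > self.max_abs_beta or not np.all(
                np.isfinite(res.x)):
            raise ConvergenceError(
                "fixed effects diverged; likely complete separation")
        if not res.success and res.status != 1:  # 1 = maxiter
            warnings.warn(f"optimizer reports: {res.message}")
        try:
            H = approx_hess1(res.x, obj)
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = np.full((res.x.size, res.x.size), np.nan)
        self.coef_ = beta
        self.tau_ = float(np.exp(log_tau))
        self.loglik_ = -float(res.fun)
        self.vcov_ = vcov
        self.converged_ = bool(res.success or res.status == 1)
        self.n_groups_ = int(n_groups)
        return self

    def predict_proba(self, X):
        """P(common) for a typical subject (random intercept at 0)."""
        X = np.atleast_2d(np.asarray(X, float))
        eta = self.coef_[0] + X @ self.coef_[1:]
        p = expit(eta)
        return np.column_stack([1 - p, p])


def _design(table, include_sync=True, include_interaction=True):
    cols = []
    names = ["intercept"]
    if include_sync:
        cols.append(table["prop_sync"].to_numpy(float))
        names.append("prop_sync")
    cols.append(table["max_offset_s"].to_numpy(float))
    names.append("max_offset_s")
    if include_sync and include_interaction:
        cols.append(table["prop_sync"].to_numpy(float)
                    * table["max_offset_s"].to_numpy(float))
        names.append("interaction")
    return np.column_stack(cols), names


def fit_causal_glmm(table: pd.DataFrame, include_sync=True,
                    include_interaction=True, n_quad=15) -> GLMMFit:
    """Fit the causal-judgement GLMM to a trial table.

    ``table`` needs columns ``subject``, ``prop_sync``, ``max_offset_s``
    and ``response_common`` (binary).  Only temporal-conflict trials
    should be included; no-conflict trials carry no cue variation.
    """
    X, names = _design(table, include_sync, include_interaction)
    est = LogisticGLMM(n_quad=n_quad)
    est.fit(X, table["response_common"].to_numpy(float),
            table["subject"].to_numpy())
    beta = {n: float(b) for n, b in zip(names, np.r_[est.coef_])}
    return GLMMFit(beta=beta, random_intercept_sd=est.tau_,
                   loglik=est.loglik_, vcov=est.vcov_, term_names=names,
                   converged=est.converged_)


def simulate_glmm_responses(fit: GLMMFit, table: pd.DataFrame, rng):
    """Draw a response vector from the fitted model (parametric)."""
    X, _ = _design(table,
                   include_sync="prop_sync" in fit.beta,
                   include_interaction="interaction" in fit.beta)
    beta = np.array([fit.beta[t] for t in fit.term_names])
    codes, uniques = pd.factorize(table["subject"].to_numpy())
    u = rng.normal(0.0, fit.random_intercept_sd, size=uniques.size)
    eta = beta[0] + X @ beta[1:] + u[codes]
    return (rng.uniform(size=len(table)) < expit(eta)).astype(int)


def bootstrap_pvalues(fit: GLMMFit, table: pd.DataFrame, n_boot=1000,
                      seed=None, n_quad=15) -> GLMMFit:
    """Parametric-bootstrap CIs and p-values for the fixed effects.

    Response tables are simulated from the fitted model and refitted;
    each coefficient gets a percentile 90% CI and a two-sided p-value
    (the tail probability of 0 under the bootstrap distribution, floored
    at ``1 / (n_boot + 1)``).  Failed refits are excluded and counted.
    """
    rng = np.random.default_rng(seed)
    draws = {t: [] for t in fit.term_names}
    failed = 0
    sim = table.copy()
    for _ in range(n_boot):
        sim["response_common"] = simulate_glmm_responses(fit, table, rng)
        try:
            refit = fit_causal_glmm(
                sim, include_sync="prop_sync" in fit.beta,
                include_interaction="interaction" in fit.beta,
                n_quad=n_quad)
        except (ConvergenceError, ValueError):
            failed += 1
            continue
        for t in fit.term_names:
            draws[t].append(refit.beta[t])
    if failed:
        warnings.warn(f"{failed} of {n_boot} bootstrap refits failed")
    out = GLMMFit(beta=fit.beta, random_intercept_sd=fit.random_intercept_sd,
                  loglik=fit.loglik, vcov=fit.vcov,
                  term_names=fit.term_names, converged=fit.converged,
                  n_boot_failed=failed)
    floor = 1.0 / (n_boot + 1)
    for t in fit.term_names:
        b = np.asarray(draws[t])
        out.ci90[t] = tuple(np.percentile(b, [5, 95]))
        p = 2.0 * min((b <= 0).mean(), (b >= 0).mean())
        out.bootstrap_p[t] = float(max(min(p, 1.0), floor))
    return out


def integration_boundary(fit: GLMMFit) -> float:
    """Offset at which the model predicts P(common) = 0.5, in ms.

    Defined on the offset axis as ``-b0 / b_off``; the fit should come
    from the reduced model (intercept + offset), or have zero sync and
    interaction terms.
    """
    if fit.beta_offset == 0:
        raise UndefinedBoundaryError("offset coefficient is zero")
    if abs(fit.beta_sync) > 1e-12 or abs(fit.beta_interaction) > 1e-12:
        warnings.warn("boundary computed on the offset axis while sync / "
                      "interaction terms are non-zero")
    return float(-fit.beta_intercept / fit.beta_offset * 1000.0)


def feature_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations among the cue columns.

    Rows: (prop_sync, max_offset_s), (max_offset_s, rate_hz),
    (prop_sync, rate_hz); columns r and p.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    pairs = [("prop_sync", "max_offset_s"),
             ("max_offset_s", "rate_hz"),
             ("prop_sync", "rate_hz")]
    rows = []
    for a, b in pairs:
        xa = table[a].to_numpy(float)
        xb = table[b].to_numpy(float)
        if xa.std() == 0 or xb.std() == 0:
            warnings.warn(f"zero variance in {a} or {b}; r undefined")
            rows.append((a, b, np.nan, np.nan))
            continue
        r, p = stats.pearsonr(xa, xb)
        rows.append((a, b, float(r), float(p)))
    return pd.DataFrame(rows, columns=["x", "y", "r", "p"])
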