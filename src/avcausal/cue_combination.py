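"""Best-cue and optimal-integration predictions for multisensory thresholds.

With unisensory sensitivity thresholds ``sigma_A`` and ``sigma_V``, two
benchmark strategies bound multisensory performance:

- best-cue: use only the more reliable modality,
  ``sigma_best^2 = min(sigma_A^2, sigma_V^2)``;
- optimal integration: reliability-weighted combination,
  ``1/sigma_opt^2 = 1/sigma_A^2 + 1/sigma_V^2``.

Posterior uncertainty is propagated by drawing independent samples from
the two unisensory posteriors and applying the combination rule draw-wise.
An observed audiovisual threshold posterior is then classified against the
two predictions by 95% credible-interval overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .psychometrics import PsychometricPosterior


@dataclass
class PosteriorSummary:
    """Point estimate and central 95% interval of a derived quantity."""

    samples: np.ndarray
    point: float
    ci95: tuple

    @classmethod
    def from_samples(cls, samples):
        samples = np.asarray(samples, float)
        return cls(samples, float(samples.mean()),
                   tuple(np.percentile(samples, [2.5, 97.5])))


@dataclass
class IntegrationPrediction:
    """Predicted multisensory thresholds under both strategies."""

    sigma_best_post: PosteriorSummary
    mu_best: float
    best_modality: str
    sigma_opt_post: PosteriorSummary
    source_fits: tuple


def predict_best_cue(postA: PsychometricPosterior, postV: PsychometricPosterior):
    """Best-cue threshold posterior and PSE.

    The modality with the smaller posterior-mean sigma is selected; its
    sigma posterior and point-estimate PSE are the prediction.  Ties break
    toward the auditory modality.

    Returns
    -------
    (PosteriorSummary, float, str)
        sigma_best posterior, mu_best, and the selected modality label.
    """
    if postA.sigma_hat <= postV.sigma_hat:
        chosen, label = postA, "auditory"
    else:
        chosen, label = postV, "visual"
    return (PosteriorSummary.from_samples(chosen.sigma_samples),
            chosen.mu_hat, label)


def predict_optimal(postA: PsychometricPosterior, postV: PsychometricPosterior,
                    n_draws=2000, rng=None) -> PosteriorSummary:
    """Optimal-integration threshold posterior.

    Independent draws ``s`` are resampled from each unisensory posterior
    and combined draw-wise, ``1/sigma_opt(s)^2 = 1/sigma_A(s)^2 +
    1/sigma_V(s)^2``.
    """
    if rng is None:
        rng = np.random.default_rng()
    sa = rng.choice(postA.sigma_samples, size=n_draws, replace=True)
    sv = rng.choice(postV.sigma_samples, size=n_draws, replace=True)
    s_opt = 1.0 / np.sqrt(1.0 / sa**2 + 1.0 / sv**2)
    return PosteriorSummary.from_samples(s_opt)


def predict_integration(postA, postV, n_draws=2000, rng=None) -> IntegrationPrediction:
    """Both strategy predictions bundled for classification."""
    best_post, mu_best, label = predict_best_cue(postA, postV)
    opt_post = predict_optimal(postA, postV, n_draws=n_draws, rng=rng)
    return IntegrationPrediction(best_post, mu_best, label, opt_post,
                                 (postA, postV))


def _overlap(ci1, ci2) -> bool:
    return ci1[0] <= ci2[1] and ci2[0] <= ci1[1]


def classify_integration(postAV: PsychometricPosterior,
                         prediction: IntegrationPrediction) -> str:
    """Label observed multisensory behaviour against the two predictions.

    Based on 95% credible-interval overlap of the observed sigma with the
    predicted sigma_opt and sigma_best:

    - ``optimal``: observed CI overlaps the optimal prediction;
    - ``enhancement``: observed CI entirely below the best-cue CI (better
      than any single cue, beyond optimal);
    - ``worse-than-best``: observed CI entirely above the best-cue CI;
    - ``best-cue``: overlaps the best-cue CI but not the optimal one;
    - ``suboptimal``: between the two predictions, overlapping neither.
    """
    ci_av = postAV.ci95["sigma"]
    ci_opt = prediction.sigma_opt_post.ci95
    ci_best = prediction.sigma_best_post.ci95
    if _overlap(ci_av, ci_opt):
        return "optimal"
    if ci_av[1] < ci_best[0]:
        return "enhancement"
    if ci_av[0] > ci_best[1]:
        return "worse-than-best"
    if _overlap(ci_av, ci_best):
        return "best-cue"
    return "suboptimal"


def compare_unisensory(sigmaA_list, sigmaV_list):
    """Paired t-test of auditory vs visual threshold estimates.

    Returns ``(t, df, p)``.
    """
    a = np.asarray(sigmaA_list, float)
    v = np.asarray(sigmaV_list, float)
    if a.size != v.size:
        raise ValueError("paired lists must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.all(a - v == 0):
        return 0.0, int(a.size - 1), 1.0
    res = stats.ttest_rel(a, v)
    return float(res.statistic), int(a.size - 1), float(res.pvalue)
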