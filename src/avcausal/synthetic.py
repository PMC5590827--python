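"""Synthetic observers and complete synthetic datasets.

Two generative observer models mirror the two experimental tasks:

- A rate-discrimination observer draws a noisy internal rate estimate per
  modality, ``r_hat_m ~ N(stim + mu_m, sigma_m^2)``, combines the two
  estimates according to its strategy (optimal reliability weighting or
  best-cue selection) on audiovisual trials, and answers "faster" when the
  combined estimate exceeds the 8 events/s standard.  A ``counting_weight``
  mixes a count-based decision variable (events / 2 s) into the rate
  estimate, which reproduces the negative PSE-versus-duration slope that a
  counting strategy produces under duration jitter.
- A causality-judgement observer responds "common source" with probability
  ``logistic(b0 + b_sync*prop + b_off*offset_s + b_int*prop*offset_s +
  u_subject)`` on temporal-conflict trials, with a Gaussian per-subject
  random intercept, and with a fixed high probability on no-conflict
  trials.

Default design parameters follow the study conditions: a 2 s standard at
8 events/s; comparison durations jittered +-250 ms on a 50 ms grid; the
causality sessions contain 360 trials each — per rate in {8, 10, 12, 14}
events/s, 75 temporal-conflict and 15 no-conflict trials, conflict pairs
rejected and redrawn until the maximum click-flash offset is <= 200 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .sequences import (
    generate_exp2_trial, jitter_duration, _n_events,
)
from .features import feature_table

#: Default comparison-stimulus grid (rate differences, events/s).
DEFAULT_STIMULUS_GRID = np.array(
    [-6, -4, -3, -2, -1, -0.5, 0.5, 1, 2, 3, 4, 6], dtype=float)

DEFAULT_CONDITIONS = ("no-conflict", "temporal", "spatial", "spatiotemporal")

STANDARD_RATE_HZ = 8.0
STANDARD_DURATION_MS = 2000.0


@dataclass
class ObserverSpec:
    """Rate-discrimination observer for one condition.

    sigma_A, sigma_V : unisensory rate-noise SDs (events/s)
    mu_A, mu_V : unisensory biases (events/s)
    strategy : {"optimal", "best-cue", "fixed-sigma"}
    counting_weight : fraction of the decision variable based on event
        count rather than rate (0 = pure rate observer)
    sigma_fixed : SD used by the "fixed-sigma" strategy
    """

    sigma_A: float = 2.0
    sigma_V: float = 2.5
    mu_A: float = 0.0
    mu_V: float = 0.0
    strategy: str = "optimal"
    counting_weight: float = 0.0
    sigma_fixed: float = 2.0

    def __post_init__(self):
        if self.sigma_A <= 0 or self.sigma_V <= 0 or self.sigma_fixed <= 0:
            raise ValueError("sigmas must be positive")
        if not 0.0 <= self.counting_weight <= 1.0:
            raise ValueError("counting_weight must lie in [0, 1]")
        if self.strategy not in ("optimal", "best-cue", "fixed-sigma"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass
class CausalObserverSpec:
    """Generative twin of the causal-judgement GLMM.

    beta : (intercept, b_sync, b_offset [per s], b_interaction)
    random_intercept_sd : SD of the per-subject intercept (log-odds)
    sync_response_rate : P("common") on no-conflict trials
    """

    beta: tuple = (1.76, 0.0, -17.0, 0.0)
    random_intercept_sd: float = 0.5
    sync_response_rate: float = 0.971

    def __post_init__(self):
        if not 0.0 <= self.sync_response_rate <= 1.0:
            raise ValueError("sync_response_rate must be a probability")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")


def _decision_stimulus(rate_diff, duration_ms, counting_weight):
    """Stimulus value feeding the internal estimate, in events/s.

    A pure rate observer sees the nominal rate; a counting observer sees
    the realised event count divided by the 2 s standard duration, so
    longer jittered stimuli look "faster" to it.
    """
    rate = STANDARD_RATE_HZ + rate_diff
    count_rate = _n_events(rate, duration_ms) / (STANDARD_DURATION_MS / 1000.0)
    return (1 - counting_weight) * rate + counting_weight * count_rate


def simulate_exp1_dataset(observers, conditions=DEFAULT_CONDITIONS,
                          stimulus_grid=DEFAULT_STIMULUS_GRID,
                          n_per_cell=25, seed=None,
                          modalities=("A", "V", "AV")) -> pd.DataFrame:
    """Simulate a rate-discrimination trial table.

    Parameters
    ----------
    observers : dict or list
        Either ``{subject_id: ObserverSpec}`` applied to every condition,
        or ``{subject_id: {condition: ObserverSpec}}``.
    n_per_cell : int
        Trials per subject x condition x modality x stimulus level.

    Returns
    -------
    DataFrame with columns subject, condition, modality, rate_diff,
    duration_jitter_ms, response_faster, prev_modality.  Trial order is
    shuffled within subject x condition so the previous-trial modality
    bookkeeping is meaningful.
    """
    rng = np.random.default_rng(seed)
    if not isinstance(observers, dict):
        observers = {i: spec for i, spec in enumerate(observers)}
    rows = []
    for subj, spec_or_map in sorted(observers.items(), key=lambda kv: str(kv[0])):
        for cond in conditions:
            spec = (spec_or_map[cond] if isinstance(spec_or_map, dict)
                    else spec_or_map)
            cell = []
            for modality in modalities:
                for rd in stimulus_grid:
                    for _ in range(n_per_cell):
                        dur = jitter_duration(rng=rng)
                        stim = _decision_stimulus(rd, dur,
                                                  spec.counting_weight)
                        est_a = stim + spec.mu_A \
                            + rng.normal(0, spec.sigma_A)
                        est_v = stim + spec.mu_V \
                            + rng.normal(0, spec.sigma_V)
                        if modality == "A":
                            est = est_a
                        elif modality == "V":
                            est = est_v
                        elif spec.strategy == "best-cue":
                            est = est_a if spec.sigma_A <= spec.sigma_V \
                                else est_v
                        elif spec.strategy == "fixed-sigma":
                            est = stim + rng.normal(0, spec.sigma_fixed)
                        else:  # optimal: reliability-weighted average
                            wa = 1.0 / spec.sigma_A**2
                            wv = 1.0 / spec.sigma_V**2
                            est = (wa * est_a + wv * est_v) / (wa + wv)
                        cell.append((modality, rd,
                                     dur - STANDARD_DURATION_MS,
                                     int(est > STANDARD_RATE_HZ)))
            order = rng.permutation(len(cell))
            prev = None
            for idx in order:
                modality, rd, jit, resp = cell[idx]
                rows.append((subj, cond, modality, rd, jit, resp, prev))
                prev = modality
    return pd.DataFrame(rows, columns=[
        "subject", "condition", "modality", "rate_diff",
        "duration_jitter_ms", "response_faster", "prev_modality"])


EXP2_RATES = (8.0, 10.0, 12.0, 14.0)
N_CONFLICT_PER_RATE = 75
N_NOCONFLICT_PER_RATE = 15


def simulate_exp2_dataset(spec: CausalObserverSpec = None, n_subjects=10,
                          sessions=2, seed=None, rates=EXP2_RATES,
                          n_conflict=N_CONFLICT_PER_RATE,
                          n_noconflict=N_NOCONFLICT_PER_RATE,
                          duration_ms=2000.0):
    """Simulate the causality-judgement experiment.

    Each session holds, per rate, ``n_conflict`` temporal-conflict pairs
    (rejection-sampled to a maximum click-flash offset of 200 ms) and
    ``n_noconflict`` shared-train pairs.  Conflict responses follow the
    logistic observer with per-subject random intercepts; no-conflict
    responses are "common" with ``sync_response_rate``.

    Returns
    -------
    (pairs, table) where ``pairs`` is the list of SequencePair objects and
    ``table`` a DataFrame with one row per trial: subject, session,
    rate_hz, temporal_conflict, prop_sync, max_offset_ms, max_offset_s,
    max_xcorr_win, response_common.
    """
    if spec is None:
        spec = CausalObserverSpec()
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, spec.random_intercept_sd, size=n_subjects)
    b0, b_sync, b_off, b_int = spec.beta

    all_pairs = []
    rows = []
    for subj in range(n_subjects):
        for sess in range(sessions):
            for rate in rates:
                for conflict, n in ((True, n_conflict),
                                    (False, n_noconflict)):
                    for _ in range(n):
                        pair = generate_exp2_trial(
                            rate, duration_ms, temporal_conflict=conflict,
                            rng=rng)
                        all_pairs.append(pair)
                        rows.append((subj, sess, rate, conflict, pair))
    feats = feature_table(p for *_, p in rows)
    table = pd.DataFrame(
        [(s, se, r, c) for s, se, r, c, _ in rows],
        columns=["subject", "session", "rate_hz", "temporal_conflict"])
    table["prop_sync"] = feats["prop_sync"].to_numpy()
    table["max_offset_ms"] = feats["max_offset_ms"].to_numpy()
    table["max_offset_s"] = table["max_offset_ms"] / 1000.0
    table["max_xcorr_win"] = feats["max_xcorr_win"].to_numpy()

    conflict_mask = table["temporal_conflict"].to_numpy()
    eta = (b0 + b_sync * table["prop_sync"].to_numpy()
           + b_off * table["max_offset_s"].to_numpy()
           + b_int * (table["prop_sync"] * table["max_offset_s"]).to_numpy()
           + u[table["subject"].to_numpy()])
    p = np.where(conflict_mask, expit(eta), spec.sync_response_rate)
    table["response_common"] = (rng.uniform(size=len(table)) < p).astype(int)
    return all_pairs, table
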