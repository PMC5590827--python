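# Methods

`avcausal` models audiovisual causal inference with stochastic event
trains: how observers judge whether a stream of auditory clicks and a
stream of visual flashes share a common source, and how that judgement
relates to multisensory rate discrimination. Everything below is
implemented and exercised on synthetic data; no behavioural recordings
ship with the package.

## Stimulus models

**Frame-triplet trains** (`generate_triplet_sequence`). Events live on a
60 Hz display grid (frame = 1000/60 ms). A stimulus of duration *D* ms is
divided into *D*/50 three-frame bins; `round(rate × D / 1000)` bins are
chosen uniformly without replacement to carry one event each. Within a
bin the event frame is uniform over the three positions, except that a
bin immediately following an event-bearing bin copies that bin's
position. This guarantees at least two blank frames (≥ 33 ms) between
events while leaving the train otherwise maximally irregular. Event
counts use round-to-nearest, which is exact for integer rates at the 2 s
standard duration; for jittered durations the same rule applies.

**60/120 ms interval trains** (`generate_raposo_sequence`). Inter-event
intervals are drawn from {60, 120} ms. The integer interval mix is the
one whose mean is closest to 1000/rate (equivalently, whose total span is
closest to `(n − 1) × 1000/rate`); the order is uniformly shuffled.
Rates outside [1000/120, 1000/60] events/s clip to the closest
achievable mix. The first onset is placed uniformly in the leading slack
by default (`first_onset="zero"` is available; the generator makes no
claim about which convention the original simulations used, so it is
explicit and configurable). Temporal-conflict pairs shift the visual
train by +20 ms; because all intervals are multiples of 60 ms, no click
can then coincide with a flash.

**Pairs and the rejection filter.** Without temporal conflict both
modalities share a single draw, so their trains are identical. With
conflict the trains are independent draws. Causality-judgement trials
additionally reject and redraw any conflict pair whose maximum
click-flash offset exceeds 200 ms (rejection capped at 10,000 attempts),
keeping the judgement genuinely ambiguous. The rate-discrimination
pipeline never applies this filter.

## Temporal causal-inference cues

Three per-trial cues are computed from each pair:

- **Proportion synchronous** — the fraction of events coded at identical
  times in both modalities (identical frame index for triplet trains,
  identical millisecond onset for interval trains). With unequal event
  counts the larger count is the denominator.
- **Maximum click-flash offset** — the default (`"directional"`) reading
  takes, for each click, the distance to its nearest flash, and reports
  the maximum over clicks. Two alternative readings are implemented and
  selectable: `"symmetric"` (nearest-neighbour from both modalities) and
  `"adjacent"` (largest gap between consecutive opposite-modality events
  in the merged train). The directional reading is the default because
  it is the one that reproduces the reference simulation statistics for
  triplet pairs — the ~17.6% sub-boundary probability at 8 events/s and
  the cue correlation structure (r ≈ −0.20, −0.53, +0.32); the
  symmetric and adjacent readings give ~4% and ~6% respectively and are
  retained for sensitivity analyses.
- **Windowed pattern similarity** — the peak of the normalized
  cross-correlogram within ±200 ms.

The cross-correlogram itself correlates the two binary frame trains at
every lag from −1 to +1 s at frame resolution: at lag *m* the
overlapping portions of the mean-subtracted, unit-normalized trains are
Pearson-correlated, so every value lies in [−1, 1]. Positive lag means
the auditory train is delayed relative to the visual train (this sign
convention is stated once here and used everywhere). A zero-variance
overlap yields 0, a neutral value.

## Psychometric model

Responses in the rate-discrimination task follow a cumulative Gaussian,
`P(faster) = Φ((x − μ)/σ)`, with `x` the comparison-minus-standard rate
difference in events/s, `μ` the PSE and `σ` the sensitivity threshold.
There is no lapse parameter. Priors are flat: `μ ~ U(−7, 7)`,
`log σ ~ U(−2.3, 1.6)`. Sampling uses a random-walk Metropolis sampler
with a diagonal Gaussian proposal whose scale adapts toward ~35%
acceptance during a 2000-iteration burn-in (adaptation then freezes, so
the retained chain is a valid Markov chain); 2000 draws are kept after
thinning by 2. Point estimates are posterior means and intervals are
central 95% percentile intervals. The sampler is seeded and its
acceptance rate is recorded; a test cross-checks its posterior against
an independent affine-invariant ensemble sampler.

Degenerate data (one response category only) triggers a warning and the
posterior collapses onto the prior bounds, as it should: perfectly
step-like data drive `σ` to the lower bound e^−2.3 ≈ 0.1.

**z-transform pooling.** Group-level analyses transform each trial's
stimulus level by its own cell's point estimates, `z = (r − μ̂)/σ̂`, so
all cells share a (0, 1) scale; pooled z-scored trials refit to μ ≈ 0,
σ ≈ 1 by construction, which a test verifies. Splits (attention switch,
duration, causal classification) refit independently within groups using
the same prior ranges, which are comfortably wide on the SNR scale.
The duration analysis omits |jitter| < 100 ms from the short/long split
and regresses per-jitter PSE on the 11 jitter levels by OLS; a counting
observer (decision variable proportional to event count rather than
rate) shows a negative slope, a pure rate observer a slope near zero.

## Cue combination and model selection

With unisensory thresholds σ_A and σ_V, the best-cue prediction is
σ_best² = min(σ_A², σ_V²) with the PSE of the more reliable modality
(posterior-mean σ decides; ties break toward audition), and the optimal
prediction is 1/σ_opt² = 1/σ_A² + 1/σ_V², propagated draw-wise through
independent resamples of the two posteriors. Observed multisensory
behaviour is classified by 95% credible-interval overlap: "optimal" if
the observed σ interval overlaps the σ_opt interval, "enhancement" /
"worse-than-best" if it falls entirely below / above the best-cue
interval, "best-cue" if it overlaps only that one, "suboptimal"
otherwise. Interval overlap is a design choice (the classification rule
is not uniquely determined by the quantities involved); it is the
package's operationalisation of "indistinguishable from the
prediction", and the helper accepts any posterior pair so alternative
rules are easy to add.

Both candidate models have no free parameters (σ fixed at the predicted
posterior-mean threshold, μ at the best modality's PSE or at 0 for the
optimal model), so per-subject model evidence is the plain Bernoulli
likelihood. Group-level comparison treats model identity as a random
effect: a Dirichlet over model frequencies is fitted by the standard
variational fixed-point iteration (uniform prior α₀ = 1, convergence at
1e−6) and reported as exceedance probabilities — exact Beta tail
probabilities for two models, Dirichlet Monte-Carlo for more.

## Cross-correlogram difference analysis

Per-trial CCGs are computed once; the mean CCG of "different source"
trials is subtracted from the mean of "common source" trials and the
difference is smoothed with a Gaussian kernel of SD 80 ms (truncated at
±4 SD and renormalized at the edges of the lag grid, so a constant
signal is preserved; by linearity, subtracting then smoothing equals
smoothing then subtracting). The null band comes from 1000 label
shuffles: pointwise 2.5/97.5 percentiles of the permuted smoothed
differences. Significance is deliberately pointwise and uncorrected —
matching the analysis this reproduces — so the summary also reports run
lengths of consecutive significant lags, since isolated flagged lags at
a 5% pointwise level are expected by chance.

## Causal-judgement GLMM

`logit P(common) = β₀ + β_sync·prop + β_off·offset_s + β_int·prop·offset_s
+ u_subject`, `u ~ N(0, τ²)`, fitted by marginal maximum likelihood.
Covariates are uncentered and unscaled (offset in seconds) so that
−β₀/β_off is directly the offset at which P(common) = 0.5 — the
integration boundary (e.g. 1.76/17.00 s ≈ 103.5 ms). The per-subject
integral is one-dimensional, so it is evaluated by adaptive
Gauss-Hermite quadrature: nodes are centred at each subject's
conditional mode (found by Newton iterations) and scaled by the local
curvature; 15 nodes by default (1 node recovers the Laplace
approximation). No installed Python library fits this model by ML, so
the marginal likelihood is written here and cross-checked in a test
against an independent `lme4::glmer` fit on identical data.

Inference is by parametric bootstrap: response tables are simulated from
the fitted model (new random intercepts and responses), refitted, and
summarised as percentile 90% CIs and two-sided p-values floored at
1/(n_boot + 1); failed refits are excluded and counted. Recovery and
coverage studies in the test suite use Wald (Hessian) 90% intervals
instead, because hundreds of replicates each with a full bootstrap would
be disproportionate; the bootstrap gets its own type-I calibration test
at reduced scale. Complete separation is detected as diverging fixed
effects (|β| > 50) and raised as a non-convergence error. The boundary
is computed from the reduced (intercept + offset) model by default,
since the sync and interaction terms are defined to zero on the offset
axis; the full model remains available.

## Synthetic observers

The rate-discrimination observer draws internal estimates
`r̂_m ~ N(stim + μ_m, σ_m²)` per modality and answers "faster" iff its
combined estimate exceeds the 8 events/s standard. Strategies: optimal
(reliability-weighted average), best-cue (lower-σ modality only), or a
fixed-σ single estimate. `counting_weight` w mixes a count-based
decision variable, `(1−w)·rate + w·count/2 s`, so w > 0 yields the
duration-dependent PSE shift that diagnoses counting. Stimuli follow a
fixed constant-stimuli grid of rate differences (±{0.5, 1, 2, 3, 4, 6}
events/s) rather than an adaptive placement procedure — adaptive
placement changes efficiency, not the estimand, and a fixed grid
exercises every fitting path deterministically. Comparison durations are
jittered ±250 ms on a 50 ms grid, uniformly over the 11 values.

The causality-judgement observer is the generative twin of the GLMM with
defaults β = (1.76, 0, −17.0 s⁻¹, 0), τ = 0.5 and a 97.1% "common" rate
on no-conflict trials; its sessions reproduce the reference design: per
rate in {8, 10, 12, 14} events/s, 75 conflict and 15 no-conflict trials
(360 per session), conflict pairs rejection-filtered at 200 ms. With
these defaults the simulated conflict trials come out ~51% "common".

What the generators deliberately do not emulate: sensory adaptation,
attention lapses, session-order learning, perceptual (as opposed to
coded) synchrony, audiovisual recalibration, and any spatial acoustics —
spatial conflict is a condition label only. Passing tests therefore
demonstrate correctness of the estimators and pipeline under the stated
generative assumptions, not the behaviour of human observers.

## Numerical and design notes

- All randomness flows through `numpy.random.Generator`; the pipeline
  derives a named substream per stage from one master seed (SHA-256 of
  `"seed:stage"`), so stages are individually reproducible and whole
  runs are bit-identical. Output bundles record the config hash and seed
  in `config.json` and `report.json`.
- Problem sizes in tests and the acceptance script (20,000 pairs for the
  boundary probability, 1500 pairs per rate for cue correlations,
  n = 2000 × 100 replicates for psychometric recovery, 30–40 replicates
  for permutation and GLMM calibration) were chosen as the package's
  standard desk-scale settings; the Monte-Carlo standard errors they
  imply are well inside the assertion tolerances used.
- Degenerate inputs are errors, not silent defaults: empty trains for
  offset/synchrony, single-class responses for the CCG difference and
  GLMM, empty split groups, zero offset effect for the boundary.
- `pandas.factorize` (first-appearance order) defines subject coding in
  the GLMM; estimates are invariant to it, only the internal ordering of
  random-effect modes depends on it.

## Known limitations

- The psychometric sampler targets posterior summaries, not draw-level
  agreement with any other sampler; convergence is monitored only via
  acceptance rate and the cross-check test.
- Exceedance probabilities beyond two models are Monte-Carlo estimates.
- The GLMM supports a single random intercept (no random slopes,
  no crossed effects) — all this package needs.
- `proportion_synchronous` counts coded coincidences; it is not a model
  of perceived synchrony.
- The interval-train generator guarantees event counts within ±1 of
  `round(rate × duration / 1000)` only inside the representable rate
  band [1000/120, 1000/60] events/s.
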