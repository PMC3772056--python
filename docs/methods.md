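# Methods

This note documents the models, the synthetic generator, the numerical
choices, and the design decisions behind `valueframe`, in the spirit of the
methods appendices of mature statistical packages. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Behavioural model

Choices between two risky prospects (reward magnitude r, probability p)
are modelled with a three-parameter prospect-theory/softmax agent:

- utility u(r) = r^α, α > 0 (α < 1: concave magnitude weighting);
- probability weighting w(p), by default the one-parameter
  Tversky–Kahneman (1992) form w(p) = p^γ / (p^γ + (1−p)^γ)^{1/γ}, with a
  config switch to the simple power form w(p) = p^γ. Both are canonical
  one-parameter weighting functions; the switch exists because either is a
  defensible reading of the literature and the choice is otherwise
  under-determined. With α = γ = 1 the subjective value w(p)·u(r) reduces
  exactly to the objective expected value p·r;
- softmax choice rule P_i = e^{βV_i} / Σ_j e^{βV_j} with inverse
  temperature β ≥ 0 (β = 0: random choice). Computed through a
  log-softmax, so large βV never overflow.

**Fitting.** The negative log-likelihood is minimised with L-BFGS-B under
box bounds α, γ ∈ [0.05, 3], β ∈ [0, 50]. The likelihood is multimodal in
(γ, β), so the optimiser restarts from 10 seeded random points (plus the
neutral (1, 1, 1)); the best minimum wins and the per-restart NLLs are kept
as diagnostics. Probabilities are floored at 1e−10 inside the log so the
NLL is always finite. The one-parameter objective-EV baseline (softmax on
p·r) is fit the same way; BIC = k·ln n + 2·NLL compares the two. Restart
count, bounds, and the deterministic seeding are all arguments.

**Logistic choice analysis.** Per subject and trial type, the probability
of choosing option 1 is regressed (maximum-likelihood logistic, via
statsmodels behind the module surface) on standardized p₁−p₂, r₁−r₂ and
objective EV₁−EV₂, plus a constant absorbing any side/order bias. Perfect
separation is caught: the fit falls back to a lightly ridge-regularized
solve, coefficients are capped at ±10 and the subject is flagged. Group
inference is a one-sample T per coefficient per trial type and a paired T
between trial types.

## Synthetic generator

The generator defines the study conditions under which every downstream
guarantee is demonstrated:

- **Sessions**: 324 trials per trial type (comparison / sequential) per
  subject; 18 subjects in the effect-recovery studies. Probabilities are
  drawn without replacement from a finite grid (0.10–0.90 in steps of
  0.05) and magnitudes uniformly from 10–100, so the two options never tie
  on either attribute. Trials where one option dominates on both
  attributes ("nobrainer") are generated at a configurable target
  proportion (default 0.5, by rejection sampling); the complement are
  "harder" trials where the attributes conflict. Option sides are
  counterbalanced.
- **Choices** come from the prospect agent (default α = 0.8, γ = 0.7,
  β = 3 — mid-range human-like values), with an optional additive logit
  bias towards the second-presented option on sequential trials.
  Response times are shifted-lognormal, decreasing with |ΔV| (harder
  discriminations are slower).
- **Epochs**: one virtual channel at 200 Hz; half-open windows
  ([−1000, 2000) ms stimulus-locked, [−2000, 1000) ms response-locked,
  i.e. exactly 600 samples — half-open so sample arithmetic is exact). Per
  trial the carrier (default 20 Hz, inside the 13–30 Hz beta band) has
  instantaneous power A₀²·(1 + g_v·z_v·env(t−τ_v) + g_c·c·env(t−τ_c)):
  z_v is the standardized value regressor, c the ±1 choice, env a
  raised-cosine envelope (default width 400 ms — sustained but localised,
  the shape being otherwise unconstrained). Negative g models
  desynchronisation. The amplitude is the square root of the power
  bracket, floored at 0.05 to stay real. Noise is 1/f^χ (default χ = 1)
  plus white noise (amplitude ratio 0.3), scaled so total noise RMS equals
  carrier RMS divided by the configured SNR (default 1).
- **Subject heterogeneity**: per-subject g and τ are drawn normal around
  the group values (defaults: SD 0.08 on g, 100 ms on τ). Between-subject
  variance is what the group one-sample T needs; without it the group
  statistics would be degenerate.
- **Blinks**: Poisson-timed raised-cosine pulses (300 ms, 8× background
  SD) added to the EOG and leaked into data channels through a fixed
  spatial topography; peaks are thinned to at least one pulse-duration
  apart (blinks cannot overlap). Ground-truth peak times are returned for
  validating detection.

What the generator does **not** emulate: sensor geometry and forward
models, beamformer leakage and correlated noise between sources, real
artifact taxonomies beyond blinks, non-stationary background spectra, or
behavioural phenomena like learning and lapses. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under the stated signal model, not robustness to every property of real
recordings.

## Preprocessing

Blink detection band-passes the EOG at 1–15 Hz (4th-order Butterworth,
forward–backward so latencies are preserved), z-scores, and takes local
maxima above 3 SD with a 200 ms refractory period. By default the z-scored
trace is first matched-filtered with a raised-cosine blink template
(300 ms), which sharpens peak localisation to about one sample; the plain
local-maximum rule is available by disabling the template. Removal
computes the average blink-locked template (−200 to +400 ms around each
detection), takes its leading spatial principal component(s), and removes
them from the continuous data by least squares — with orthonormal
topographies this is a projection, hence idempotent when the topographies
are reused; with no detected blinks the data pass through unchanged.
Epoching slices half-open windows, subtracts the per-channel baseline mean
(default −200–0 ms), and flags (rather than drops) events whose window
leaves the recording, keeping trial tables and epochs aligned. Artifact
rejection replaces visual inspection with explicit thresholds:
peak-to-peak above a limit, or below a flatness limit, on any channel
marks the epoch; the mask is stored, the data untouched.

## Time-frequency regression

Morlet wavelets with centre-frequency-to-bandwidth ratio 5 (σ_t =
5/(2πf)), truncated at ±3σ_t and normalized to unit energy; power is the
squared magnitude of the 'same'-aligned complex convolution (FFT-based).
The default grid is 40 bins linearly spaced 1–40 Hz; the power time axis
is decimated to 25 ms. Bins within half the wavelet support of either
epoch edge are flagged invalid and excluded from peak searches and cluster
statistics — convolution edges are biased and the bias is largest exactly
where slow wavelets meet the epoch boundary. Power units are arbitrary:
the per-subject summary β̂/SE is scale-invariant, so no normalisation of
power is needed (raw power is regressed by default; a log transform is
available).

The trial-wise design always contains a constant and a ±1 choice term plus
standardized value regressors; named models cover the analyses of
interest: {V_opt1}, {V_contra, V_ipsi}, {V_chosen, V_unchosen},
{V_opt1, V_opt2}, with harder/nobrainer trial selections. Including choice
as a covariate isolates value variance from choice variance. OLS runs
independently at each (f, t) bin, vectorized through one shared Gram
matrix; SEs come from the residual variance and (XᵀX)⁻¹, and contrasts
(e.g. contra−ipsi, chosen−unchosen) propagate SE via wᵀ(XᵀX)⁻¹w. Rank
deficiency is detected at design construction and reported with the
offending column pair. The "variance-normalized" per-subject summary is
β̂/SE (a per-subject t-value), the standard input to group tests; a strict
β̂/Var reading is available via `kind="beta_over_var"`.

## Cluster permutation inference

The group statistic is a one-sample T per bin (df = n−1). Under the null
each subject's map has a sign-symmetric distribution, so sign-flipping
whole subject maps yields an exact permutation test. Flipped T-maps are
computed in a single matrix product per batch (the second moment is
invariant under sign flips, so only the flipped means vary). For n ≤ 12
subjects, all 2ⁿ assignments can be enumerated; otherwise permutations are
Monte-Carlo with independent fair ±1 per subject, seeded. Corrected
p = (1 + #{null ≥ observed}) / (1 + n_perm) — the observed assignment
counts itself, so p is never zero.

Design choices, made where the convention is genuinely open:

- **Family/tails.** The default is a single two-sided family: clusters are
  contiguous regions of |T| > threshold (default 2.0), the null records
  the maximum |T|-cluster extent. This controls the family-wise error at
  the nominal alpha in one family while remaining sensitive to both
  synchronisation (positive) and desynchronisation (negative) effects.
  Running two separate one-tailed families each at α = 0.05 — also offered
  (`tail="both_onetailed"`, or single `"pos"`/`"neg"`) — would push the
  union error rate towards 0.1 under the symmetric null, which is why it
  is not the default.
- **Adjacency**: 4-connectivity on the (f, t) grid by default,
  8-connectivity via config.
- **Cluster statistic**: extent (bin count) by default, cluster mass
  (summed |T|) via config.
- Zero between-subject variance at a bin yields ±inf T, flagged rather
  than raised.

The pipeline's central statistical guarantee — family-wise error ≤ nominal
alpha on full null simulations from generator to cluster test — is
verified directly (200 simulated datasets of 12 subjects each; see
`tests/test_acceptance.py` and the acceptance script).

## Latency and interaction contrasts

Per subject, the peak of a named effect is the signed extremum of β̂/SE
within a band × window (beta 13–30 Hz; 0–1000 ms after the second option
for sequential analyses, −1000–0 ms before the response for comparison
analyses), excluding edge-flagged bins, with deterministic tie-breaking
(earliest time, then lowest frequency). The expected sign is part of the
analysis spec (negative in motor beta, positive in prefrontal/parietal
beta). Latency orderings are tested with a paired T on per-subject
differences (median reported alongside; zero-variance differences are
flagged as degenerate). The 2×2 region-by-trial-type repeated-measures
interaction is computed from the within-subject double difference d =
(A₁−A₂) − (B₁−B₂); its F(1, n−1) equals the squared paired T on d (an
algebraic identity the tests verify numerically). For the interaction,
peak effect sizes are aligned to each region's expected sign, so "more
effect" is positive in both regions; on raw signed peaks a symmetric
crossover would cancel in the double difference.

## Validation studies and problem sizes

The studies behind `scripts/acceptance.py` (all seeded, all generated at
run time):

- **Null family-wise error**: 200 datasets × 12 subjects × 324 trials;
  20 × 60 (frequency × time) grid — 1 Hz spacing over 8–27 Hz, 25 ms steps
  over 0–1475 ms, chosen so every bin clears the wavelet edge-exclusion
  zone of the simulated epochs; 500 permutations per dataset.
- **Oracles**: 3 random stacks of 10 subjects, Monte-Carlo (2000 flips) vs
  exhaustive (1024) p-values; 3 random OLS instances (20 trials × 3
  regressors) vs per-bin normal equations.
- **Behavioural recovery**: 50 subjects × 648 trials; true parameters
  lognormal around human-typical medians (α 0.8, γ 0.85, β 3) with
  between-subject coefficients of variation matching those reported for
  this task (α 0.51, β 0.70, γ 0.17).
- **Latency recovery**: 50 replicates × 18 subjects, injected value effect
  at 500 ms and choice effect at 700 ms (both g = −0.3, subject jitter
  SD 100 ms), beta-band grid.
- **BIC selection**: 50 datasets alternating between a curved-utility
  generator (α = 0.5) and an objective-EV generator.
- **Interaction power**: 50 replicates × 18 subjects, crossover design at
  |g| = 0.3 on harder trials only (the goods-space analyses are defined on
  harder trials, roughly half a session).

These sizes keep a full validation run to a few minutes on one CPU while
leaving the binomial/Monte-Carlo error of each estimate well inside its
acceptance margin.

## Known limitations

- The signal model injects amplitude-modulated narrowband carriers; real
  beta effects are broader-band and non-sinusoidal.
- Single virtual channel per region: no spatial leakage, no
  cross-regional correlation structure.
- The behavioural model has no lapse rate, loss aversion or
  reference-dependence, and the group logistic analysis is
  fixed-effects-per-subject with parametric group tests (no hierarchical
  shrinkage).
- γ is weakly identified at moderate trial counts (its likelihood is flat
  near 1); recovery guarantees are stated for α and β only.
- The cluster test's exactness relies on between-subject exchangeability
  and per-subject sign symmetry under the null; heavy-tailed or skewed
  subject summaries degrade it gracefully but measurably.
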