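# Methods

## The observer

The full Bayesian decision (fBD) observer treats pain perception as
inference followed by decision. Every variable — stimulus effect *E*,
nociceptor signal *N*, delivered stimulus *S*, reported rating *R* — lives
on one discretized intensity axis (0–100 arbitrary units, step 0.5, 201
points). Probability objects are mass vectors on that grid, normalized to 1
within 1e-9.

**Prior.** Conditioning with two intensities in equal proportion leaves
`Pr(E) = w/2 N(s_low, σ) + w/2 N(s_high, σ) + (1−w) Uniform`. The uniform
floor keeps every intensity possible; *w* measures how much the conditioned
expectation dominates. A cue selects its associated component with full
weight *w* while keeping the `(1−w)` floor; this construction reduces to
the two-component mixture when marginalized over equiprobable cues. The
alternative — keeping `w/2` per component under a cue — would make a cue
carry no information about its own component, which contradicts the
training contingency; the floor weight is kept at `(1−w)` rather than
rescaled because the cue bears on *which* conditioned intensity to expect,
not on whether conditioning took hold.

**Likelihood.** `Pr(N|E)` is Gaussian with mean proportional to the effect
and common width. The discretized, row-renormalized kernel matrix is used
wherever a distribution *over signals* is needed (signal weighting,
simulation); Bayes' rule itself evaluates the untruncated Gaussian density
of the observed signal. The distinction matters only near the grid edges:
row renormalization inflates edge rows, and using those values as a
likelihood function of *E* would pull the posterior mode toward the
boundary for near-edge signals — an artifact of the bounded grid, not of
the model. The same logic applies to the rating mixture: Gaussian rating
components are accumulated as raw densities and the mixture is normalized
once.

**Decision and rating.** Under a uniform cost function the optimal point
estimate is the posterior mode. Exact ties (which occur, e.g., for the
perfectly symmetric posterior at the anchor midpoint) resolve
deterministically to the lowest tied intensity; this necessarily breaks
exact mirror symmetry of the midpoint rating distribution by the weight of
the tied signal column (~0.02 at defaults). Ratings add Gaussian coding
noise `N(Ê, σ_R)`; the predicted rating distribution `Pr(R|S,C)` is an
exact grid marginalization over the signal, never Monte Carlo (sampling
versions exist only as test oracles).

**Mode counting.** A local maximum of a mass profile counts as a mode only
if it reaches 0.1% of the global maximum. Where the uniform floor re-emerges
many s.d. away from both mixture components it creates strict maxima
carrying ~1e-5 of the peak mass; these are numerical dust. Measured
satellite heights are ≤ 2.3e-5 of the peak while genuine secondary modes
are ≥ 0.96, so the threshold sits two orders of magnitude from either side.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| grid | 0–100, step 0.5 | intensity | common arbitrary axis for E, N, S, R |
| σ (prior component s.d.) | 5.7 | intensity | cohort-mean estimate from the conditioning experiment |
| sd_nociceptor | 10.0 | intensity | see below |
| σ_R (rating noise) | 4.0 | intensity | free hyperparameter; gives conditioning-block rating s.d. ≈ 11 intensity units (≈ 17 scaled-VAS units), realistic for VAS data |
| s_low / s_mid / s_high | 35 / 50 / 65 | intensity | mid at the exact midpoint by design; low/high ratio ≈ 54%, typical of conditioned-placebo protocols |

**On the nociceptor width.** Electrophysiological reports put the
dispersion of the nociceptor response at 0.75 in normalized response units;
the gain linking that response scale to the 0–100 intensity axis is not
fixed by those reports ("mean proportional to" leaves the constant free).
Taken literally as 0.75 intensity units, the sensory evidence would be ~40×
sharper than the prior and the observer could produce neither placebo
modulation nor bimodal mid-stimulus ratings — none of the phenomena the
model exists to explain. The default of 10 intensity units (equivalently, a
gain of 0.075 response-units per intensity unit) places the observer in the
demonstrated regime: visible placebo shifts for deceptive cues, sharpened
beliefs for congruent ones, and bimodality emerging for w ≳ 0.8. The value
is a config parameter throughout.

The defaults were fixed once, jointly, by scanning for the regime in which
the model's qualitative behaviour (pre-conditioning linearity, strict and
monotone placebo ordering in w, bimodality emergence, a substantive
correlation between w and placebo magnitude) holds with margin; they were
not adjusted afterwards.

## Synthetic cohorts

The generator emulates the two designs: Experiment 1 (3 blocks × 12
trials; conditioning, conditioning, placebo test) and Experiment 2 (4
blocks × 16 trials; conditioning ×2, uncued test with 4 high / 4 low / 8
mid stimuli, placebo test). Conditioning is modelled as instantaneous:
during training blocks the simulated subject rates with a flat prior (the
conditioned state does not yet exist), and the full mixture prior is in
place from the first test block onward; extinction and trial-by-trial
updating are out of scope. Ratings are truncated at the VAS floor of zero
(by resampling, i.e. the truncated distribution); no ceiling is imposed in
the generator, while the grid representation implicitly truncates at 100 —
negligible for the default anchors. Per-subject seeds derive from the
master seed via `numpy.random.SeedSequence.spawn`, making cohorts exactly
reproducible with independent subjects. A `no_learn` generator mode draws
test-block ratings from the no-learn predictive built from the subject's
own conditioning ratings, for identifiability studies.

What the generator does *not* emulate: extinction across test trials,
attention/anxiety covariates, dropout, scale-use idiosyncrasies (anchoring,
digit preference), or inter-subject variability in σ_R and the nociceptor
width. Passing tests therefore show that the analysis chain recovers the
structure this generative family produces, not that real VAS data obey it.

## VAS scaling and fitting

Scores are scaled per subject per block relative to the mean high-stimulus
rating of that block (placebo blocks: red-cued high stimuli only), mapping
the reference mean to 100. Scaling is idempotent.

Fitting is likelihood-based on deterministic grids — the model defines a
full rating distribution for every (stimulus, cue), so least squares would
discard the predicted shape, and grid search makes estimates exactly
reproducible with no optimizer state. `fit_w` maximizes the joint
log-likelihood of the placebo-block green- and red-cued ratings over w ∈
{0, 0.01, …, 1}; using both cue groups lets the red-cued (no-treatment)
trials constrain the rating spread while the green-cued trials carry the
placebo signal. Ties resolve to the smaller w. `fit_sigma` runs the
analogous joint (σ, w) grid per subject with the prior component locations
fixed at the subject's conditioning-block means. Ratings are evaluated at
the nearest grid point; values beyond the grid are clamped to the boundary
with a warning.

Residual variance is defined as `100 × (1 − r²)`; the percent placebo
magnitude as `100 × (mean red-high − mean green-high) / mean red-high`.

## Model comparison

Following the two-dataset discipline (parameters estimated on the placebo
block, models scored on the held-out uncued mid-intensity ratings; no
BIC/DIC needed), the comparison works on intra-block scaled scores on an
extended 0–160 grid (scaled scores exceed 100 whenever a rating exceeds its
block reference mean). Each subject's conditioning summary calibrates all
three models: the rating means fix the component locations, the pooled
rating s.d. the variability of `Pr(R|Ê)`; the nociceptor and prior widths
are mapped to the scaled axis by the ratio of the conditioned separation on
the two scales. Posterior model probabilities assume equal priors; the
Bayes factor for each model is taken against its best alternative.

Known limitation: the fitted fBD observer *nests* the no-learn model — on
data generated without learning it fits ŵ ≈ 0 and its predictive becomes
the no-learn Gaussian up to a small overdispersion (the conditioning s.d.
used for `Pr(R|Ê)` already contains nociceptor spread). With 8 held-out
ratings per subject the two models are then separated by ~0.6 nats against
~2.4 nats of evaluation noise, so data simulated under no-learn yield
"no-learn wins" in well under 60% of subjects. Data simulated under the
fBD observer (w ≥ 0.7) are identified correctly in ~62–66% of subjects,
with the simple Bayesian model — which also predicts bimodality — taking
most of the remainder, and the no-learn model almost never winning.

## Clustering and bimodality

`kmeans2` computes the k = 2 Hartigan–Wong solution on scalar score
vectors. The deterministic restarts enumerate all contiguous sorted splits
— for one-dimensional data the optimal two-partition is such a split, so
the solution provably equals the brute-force optimum — and the
Hartigan–Wong size-corrected transfer stage confirms convergence. The
separation index is (total SS − within SS) / total SS ∈ [0, 1]. Degenerate
inputs (all scores numerically identical, or squared deviations that
underflow) raise rather than return noise.

The bimodality test compares plug-in likelihoods: a single Gaussian with
the overall moments versus a two-Gaussian mixture with the cluster moments,
weights proportional to cluster sizes (the natural empirical completion of
a construction that is otherwise fully data-determined), equal hypothesis
priors, cluster s.d.s floored at 0.5 scaled-VAS units. Because the mixture
hypothesis reuses parameters fitted to the same scores, the test is
*anticonservative at small n*: for unimodal data at n = 8 the expected
posterior probability of bimodality is ≈ 0.8, not ≤ 0.5. The per-subject
bimodality probabilities are therefore best read as a relative clustering
measure (they do increase with true separation, and correlate with the
expectation weight across a cohort), not as calibrated evidence.

## Rank and correlation tests

Wilcoxon signed-rank and Mann–Whitney rank-sum tests are one-tailed with an
explicit direction argument. P values are exact — full enumeration of sign
patterns (≤ 12 non-zero pairs) or rank splits (≤ 10 per group), computed on
midranks and therefore valid under ties — and tie-corrected normal
approximations (no continuity correction) beyond. All-zero paired
differences raise. Pearson correlation uses the product-moment formula with
the exact t transform for the one-tailed P; constant inputs raise.

## Numerical choices and degenerate inputs

- Discretized Gaussians are density evaluations at grid points,
  renormalized (single distributions) or normalized once after mixing
  (mixtures); edge truncation is handled by renormalization, not
  reflection.
- An unnormalized posterior whose total mass underflows (possible only at
  w = 1 with an observation far from both components) raises
  `DegeneratePosteriorError` rather than returning numeric dust.
- MAP ties break to the lowest intensity, deterministically.
- Zero scaling references, missing cue groups, constant score vectors and
  similar degeneracies raise typed errors naming subject and block where
  applicable.

## Problem sizes

The shipped analyses use the study-scale designs (cohorts of 24 and 31
subjects; 12 or 16 trials per block). The recovery studies use 100
subjects for the expectation weight and 24 for the prior dispersion; the
identifiability study 50 subjects per generator; Monte-Carlo oracles use
1–2 × 10⁶ draws (posterior equivalence) and 10⁵ draws (rating-chain
means). These sizes give the reported checks comfortable statistical
resolution while keeping any single analysis in the minutes range on one
CPU.
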