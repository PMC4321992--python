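# painbayes

Bayesian decision modelling of pain perception and placebo analgesia.

`painbayes` implements a full Bayesian decision (fBD) observer of pain: a
subject who must decide which pain intensity to perceive, given noisy
nociceptor signals and whatever expectations conditioning has instilled. The
package provides the observer itself, two competitor models, a synthetic
generator for the two classic conditioned-placebo psychophysics designs,
per-subject likelihood fitting, and the inferential machinery (Bayes-factor
model comparison, Hartigan–Wong clustering, bimodality testing, one-tailed
rank and correlation tests) used to analyse such experiments. It is intended
for computational psychophysicists who want to simulate, fit and compare
perception-as-inference accounts of placebo/nocebo phenomena.

## The model

All quantities live on one intensity axis (0–100 arbitrary units,
discretized at 0.5). Conditioning with a low and a high stimulus in equal
proportion leaves the prior over the stimulus effect *E*

```
Pr(E) = w/2 · N(s_low, σ) + w/2 · N(s_high, σ) + (1 − w) · Uniform
```

where *w* ∈ [0, 1] is the effectiveness of conditioning/expectation. A
colored cue *C* disambiguates which conditioned intensity to expect
(green ↔ low, red ↔ high), selecting its component with weight *w*.
Perception is two-stage:

1. **Inference** — combine the (cue-conditioned) prior with the Gaussian
   nociceptor likelihood Pr(N|E): `Pr(E|N,C) ∝ Pr(E|C) · Pr(N|E)`.
2. **Decision** — under a uniform cost function, perceive the posterior
   mode: `Ê = argmax_e Pr(e|N,C)`.

Reported ratings add Gaussian coding noise, so the predicted rating
distribution marginalizes the chain over the signal:
`Pr(R|S,C) = Σ_n Pr(n|S) · N(R; Ê(n,C), σ_R)`.

The observer reproduces three signature phenomena: a near-linear
stimulus–rating relation before conditioning; placebo/nocebo shifts when a
cue contradicts the delivered stimulus; and — the model's distinctive
prediction — *bimodal* ratings for uncued intermediate stimuli, clustered
toward the two conditioned levels. Two competitors are provided for model
comparison: a *no-learn* model (unimodal Gaussian, mean interpolating the
conditioning report levels) and a *simple Bayesian* model (conditioning
prior times stimulus likelihood, no decision stage).

## Worked example

Simulate a 24-subject cohort through the four-block design (two
conditioning blocks, an uncued test block, a placebo block), fit each
subject's expectation weight, and summarize:

```python
from painbayes import (CohortSpec, PlaceboExperiment, SubjectParams,
                       rating_distribution, simulate_cohort)

base = SubjectParams(w=0.5)
spec = CohortSpec(n_subjects=24, experiment=2, w=(0.0, 1.0),
                  base_params=base, master_seed=7)
records, truth = simulate_cohort(spec)
results = PlaceboExperiment(records, base).fit()
print(results.summary())
```

```
Placebo conditioning experiment — fBD observer fit
==========================================================
subjects: 24    trials: 1536
fixed params: sigma_prior=5.7 sd_nociceptor=10.0 sigma_rating=4.0 anchors=(35.0, 50.0, 65.0)
w_hat: mean=0.536  sd=0.302  range=[0.00, 0.97]
placebo magnitude (%): mean=9.14  sd=8.77
signed-rank red>green: W=277.0 P(one-tailed)=1.42e-04
corr(w_hat, placebo): r=0.707 P=5.67e-05 residual variance=50.1%
==========================================================
```

The cohort shows a reliable placebo effect (green-cued high stimuli rated
below red-cued ones, one-tailed signed-rank P ≈ 1.4 × 10⁻⁴) and the fitted
expectation weight correlates positively with each subject's placebo
magnitude (r ≈ 0.71), with about half the between-subject variance left
unexplained. The observer's predictions for a strongly conditioned subject
(w = 0.9):

```python
p = SubjectParams(w=0.9)
rating_distribution(p.s_high, "red", p).mean()    # 64.99 — veridical
rating_distribution(p.s_high, "green", p).mean()  # 53.71 — placebo analgesia
rating_distribution(p.s_mid, "none", p).local_maxima()  # [37. 63.] — bimodal
```

The green cue pulls the same high stimulus down by ~17%, and the uncued
mid-intensity stimulus is predicted to be felt as either low-ish or
high-ish pain, almost never as intermediate.

`painbayes` also installs a CLI (`painbayes simulate | scale | fit |
predict | compare | cluster | replicate`) exposing each stage on CSV files.

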