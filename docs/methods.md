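# Methods

## Combination rules

Given learner confidence vectors **c**ᵢ(s) on the K-simplex, the arithmetic
ensemble is their component-wise mean and the geometric ensemble their
component-wise geometric mean. The geometric mean is computed in the log
domain; exact zeros are detected first and short-circuited to zero so no
−∞ arithmetic occurs. Geometric rows are reported unnormalized: only the
argmax is consumed downstream, and both row normalization and the n-th
root rescale every component of a row identically (this same scalar
invariance is why the product rule Πᵢ c_{i,α} yields identical
predictions; the identity is enforced by test). The CLI offers
renormalization of geometric rows for display only.

Argmax ties break deterministically to the smallest class index. A sample
in which every class is vetoed (each class given exactly zero by at least
one learner) cannot be ranked by the geometric rule; rather than abort a
run on real-world files containing hard zeros, the prediction for such a
sample falls back to the arithmetic rule, a warning is logged, and the
sample index is recorded in the result and in the pipeline report.

For two models and two classes the two rules agree: with confidences
(p, 1−p) and (q, 1−q), both "class 0 wins" conditions reduce to
p + q > 1. With three or more models the veto can flip the geometric
argmax away from the arithmetic one; the test suite carries a frozen
witness (two learners at [0.8, 0.2] and one at [0.001, 0.999]).

## Agreement diagnostics

The similarity S is the mean pairwise dot product of the learners'
confidence vectors, generalized from the three-learner form to all
(i, j) pairs so that any learner count is accepted; at n = 3 it reduces
exactly to the three-pair average. The reported uncertainty is the
standard error of the per-sample mean (sample standard deviation / √N).
A plausible alternative — spread over model subsets — is not computed;
with a single cohort of learners there is no subset ensemble to average
over.

Agreement patterns count, per sample, how many learners miss the truth;
the histogram over m = 0..n partitions the test set. Conditional
histograms restrict to samples the (arithmetic or geometric) ensemble
classifies correctly, so conditional counts can only shrink.

The RWW rescue analysis is defined only for exactly three learners and
refuses other cohort sizes rather than silently redefining the pattern.
For each sample with exactly one correct learner it records whether the
ensemble predicted the truth and the ratio of the second- to
third-largest component of the ensembled confidence vector (+∞ when the
third is zero; such samples are assigned to the top bin). Ratios are
binned into quantile bins (default 5) so sparse RWW sets still populate
every bin; both raw and row-renormalized second/third components are
stored, though the ratio itself is scale-invariant and therefore
identical for either choice.

Evaluation uses accuracy and macro-averaged F1. The macro average runs
over the union of classes present in the truth or the predictions;
classes absent from both are excluded, and a class with zero precision
and recall contributes F1 = 0. Balanced class weights follow
w_α = N/(K_present·N_α) with weight 0 (plus a warning) for absent
classes, so evaluation fixtures drawn from label subsets load cleanly.

## Synthetic cohorts

The generator emulates a set of n correlated classifiers without any
trained models. Per sample, truth y is drawn from the class distribution
(uniform by default, arbitrary simplex vectors supported); a shared noise
vector η ~ N(0, I_K) is drawn once; learner i receives logits

    g_i = μ·onehot(y) + √ρ·η + √(1−ρ)·ε_i,     ε_i ~ N(0, I_K),

mapped to the simplex by softmax(g_i/T). The three knobs are orthogonal
by construction:

- **μ ≥ 0** (signal strength, logit units): mean boost of the true class;
  μ = 0 gives chance accuracy. Default 2.0 (≈ 0.87 single-learner accuracy
  at K = 10, T = 1) — a realistic "good but imperfect classifier" regime.
- **ρ ∈ [0, 1]** (correlation): the shared fraction of the unit noise
  variance. Because μ sits outside the variance mixing, each learner's
  marginal logit distribution — hence single-learner accuracy — is
  invariant to ρ; ρ = 1 duplicates learners exactly, ρ = 0 makes their
  errors conditionally independent given the truth. An earlier variant
  that mixed the signal into both noise components was discarded because
  its effective signal (√ρ + √(1−ρ))μ made accuracy, and consequently S,
  non-monotone in ρ. Default 0.3.
- **T > 0** (temperature): divides the logits; larger T flattens the
  vectors (top-1 mean → 1/K, empirical S → 1/K as T → ∞). Default 1.0.

There is no quantitative mapping from ρ to the similarity values observed
for real model families; sweeps therefore report the empirical S next to
ρ rather than claiming an equivalence.

One master seed expands through `numpy.random.SeedSequence` into separate
streams for labels, shared noise, and per-learner noise, so cohorts are
bit-reproducible and changing `n_learners` perturbs neither the labels
nor the existing learners.

`calibrate_signal` bisects on μ against pilot cohorts drawn with a fixed
seed schedule (accuracy is monotone in μ under common random numbers) and
returns a μ whose pilot accuracy is within ±0.01 of the target.
`sweep_correlation` recalibrates μ at every ρ so ensembles are compared at
matched single-model accuracy, then reports empirical S, single and
ensemble accuracies, and the gains.

What the generator does *not* emulate: class-conditional confusion
structure (all wrong classes are exchangeable), calibration error,
heavy-tailed confidence distributions, and learner-specific quality
differences. Passing tests therefore demonstrate the mechanism — lower
inter-learner overlap yields a larger ensembling gain at matched accuracy
— not distributional fidelity to any particular trained-model family.

## Numerical and design choices

- Cube validation renormalizes rows whose sum deviates from 1 by less
  than the tolerance (default 1e−6; hard error beyond it, naming learner
  and sample). Deviations below 1e−12 are treated as exact so validation
  is idempotent. Generated cohorts are validated at 1e−9.
- Pattern tables, reports and ensemble outputs are byte-deterministic for
  identical inputs (JSON with sorted keys, no timestamps); warnings
  (renormalization, veto fallback) are captured into the report.
- Default study sizes (K = 10, N = 2000, three seeds, pilot cohorts of
  4000) keep a full mechanism sweep under a minute on one CPU while
  leaving Monte-Carlo standard errors on accuracies near 0.008.

## Known limitations

- The rescue-ratio analysis reports the raw binned table; no parametric
  curve is fitted to rescue probability versus ratio. In this generator
  the rescue frequency *decreases* with the second/third-component ratio:
  a large ratio typically means both wrong learners concentrated on the
  same wrong class, which then wins the argmax, whereas ratios near 1
  indicate split wrong votes that the single correct learner can beat.
- Weighted or stacked ensembling, learner selection by validation score,
  and confidence calibration are out of scope.
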