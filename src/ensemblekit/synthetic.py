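"""Synthetic cohorts of correlated classifiers.

A latent-Gaussian-logit generator produces confidence vectors for ``n``
learners with three independent knobs: signal strength ``mu`` (mean logit
boost of the true class → single-learner accuracy), correlation ``rho``
(fraction of logit variance shared between learners → inter-learner
similarity S), and temperature ``T`` (flattens the softmax → lower top-1
probability).  For each sample the truth ``y`` is drawn from the class
distribution, a shared latent noise vector ``eta ~ N(0, I_K)`` is drawn
once, and learner ``i`` receives the logits

    g_i = mu * onehot(y) + sqrt(rho) * eta + sqrt(1 - rho) * eps_i,

with ``eps_i ~ N(0, I_K)`` independent across learners, mapped to the
simplex by ``softmax(g_i / T)``.  At rho = 1 all learners coincide; at
rho = 0 their errors are conditionally independent given the truth.  The
signal sits outside the variance mixing, so each learner's logit
distribution — and hence single-learner accuracy — is exactly invariant to
rho, while rho only tunes how much of the unit noise variance is shared.
This keeps the empirical similarity S monotone in rho at fixed (mu, T);
small finite-sample drift in accuracy is absorbed by
:func:`calibrate_signal`.

One master seed expands to separate streams for labels, shared latents and
per-learner noise, so changing ``n_learners`` does not perturb the labels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

from .core import ConfidenceCube, ValidationError, predicted_classes, validate_cube
from .diagnostics import pairwise_similarity
from .ensembling import arithmetic_ensemble, geometric_ensemble

import pandas as pd

_CUBE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of a synthetic correlated-learner cohort.

    signal_strength : mean logit boost of the true class (mu >= 0); 0 means
        chance-level learners.
    correlation : shared fraction rho of the logit variance, in [0, 1].
    temperature : positive divisor of the logits before the softmax; larger
        values flatten the confidence vectors (lower top-1).
    class_probs : class distribution (uniform when None).
    """

    n_learners: int = 3
    n_samples: int = 2000
    n_classes: int = 10
    signal_strength: float = 2.0
    correlation: float = 0.3
    temperature: float = 1.0
    class_probs: tuple[float, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_learners < 1:
            bad.append("n_learners (must be >= 1)")
        if self.n_samples < 1:
            bad.append("n_samples (must be >= 1)")
        if self.n_classes < 2:
            bad.append("n_classes (must be >= 2)")
        if not (self.signal_strength >= 0):
            bad.append("signal_strength (must be >= 0)")
        if not (0.0 <= self.correlation <= 1.0):
            bad.append("correlation (must be in [0, 1])")
        if not (self.temperature > 0):
            bad.append("temperature (must be > 0)")
        if self.class_probs is not None:
            probs = np.asarray(self.class_probs, dtype=float)
            if probs.size != self.n_classes or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-9:
                bad.append("class_probs (must be a length-K simplex vector)")
        if bad:
            raise ValidationError("invalid generator config: " + "; ".join(bad))


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated confidence cube, its ground truth, and the config used."""

    cube: ConfidenceCube
    truth: np.ndarray
    config: GeneratorConfig


def _streams(config: GeneratorConfig) -> tuple[np.random.Generator, np.random.Generator, list[np.random.Generator]]:
    root = np.random.SeedSequence(config.seed)
    labels_ss, shared_ss, noise_ss = root.spawn(3)
    noise = [np.random.Generator(np.random.PCG64(ss)) for ss in noise_ss.spawn(config.n_learners)]
    return (
        np.random.Generator(np.random.PCG64(labels_ss)),
        np.random.Generator(np.random.PCG64(shared_ss)),
        noise,
    )


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw one cohort from the latent-logit model; bit-identical per seed."""
    config.validate()
    n, big_n, k = config.n_learners, config.n_samples, config.n_classes
    mu, rho, temp = config.signal_strength, config.correlation, config.temperature
    labels_rng, shared_rng, noise_rngs = _streams(config)

    probs = (
        np.full(k, 1.0 / k)
        if config.class_probs is None
        else np.asarray(config.class_probs, dtype=float)
    )
    truth = labels_rng.choice(k, size=big_n, p=probs / probs.sum())
    boost = np.zeros((big_n, k))
    boost[np.arange(big_n), truth] = mu

    shared = shared_rng.standard_normal((big_n, k))
    values = np.empty((n, big_n, k))
    for i, rng in enumerate(noise_rngs):
        logits = boost + np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal((big_n, k))
        values[i] = softmax(logits / temp, axis=1)
    learner_names = tuple(f"synthetic_{i}" for i in range(n))
    cube = validate_cube(values, _CUBE_TOLERANCE, learner_names)
    return SyntheticCohort(cube, truth, config)


def mean_single_accuracy(cohort: SyntheticCohort) -> float:
    """Accuracy of the individual learners, averaged over learners."""
    cube, truth = cohort.cube, cohort.truth
    per_learner = [
        float(np.mean(predicted_classes(cube.learner(i)) == truth))
        for i in range(cube.n_learners)
    ]
    return float(np.mean(per_learner))


@dataclass(frozen=True)
class CalibrationResult:
    signal_strength: float
    achieved_accuracy: float


def calibrate_signal(
    target_accuracy: float,
    config: GeneratorConfig,
    n_pilot: int = 4000,
    tolerance: float = 0.01,
    max_iter: int = 40,
) -> CalibrationResult:
    """Find mu such that mean single-learner accuracy hits ``target_accuracy``.

    Bisection over pilot cohorts of ``n_pilot`` samples drawn with a fixed
    seed schedule (accuracy is monotone in mu at fixed rho, T).  Returns the
    calibrated mu and the pilot accuracy, within ``tolerance`` of the target.
    """
    config.validate()
    chance = 1.0 / config.n_classes
    if not (chance < target_accuracy < 1.0):
        raise ValidationError(
            f"target accuracy must lie strictly between chance ({chance:.3g}) and 1"
        )

    def pilot_accuracy(mu: float) -> float:
        pilot = dataclasses.replace(
            config, signal_strength=mu, n_samples=n_pilot, seed=config.seed
        )
        return mean_single_accuracy(generate_cohort(pilot))

    lo, hi = 0.0, 1.0
    while pilot_accuracy(hi) < target_accuracy:
        hi *= 2.0
        if hi > 64.0:
            raise ValidationError(f"target accuracy {target_accuracy} unreachable")
    mu, achieved = hi, pilot_accuracy(hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        acc = pilot_accuracy(mid)
        if abs(acc - target_accuracy) < abs(achieved - target_accuracy):
            mu, achieved = mid, acc
        if abs(achieved - target_accuracy) <= tolerance and hi - lo < 0.05:
            break
        if acc < target_accuracy:
            lo = mid
        else:
            hi = mid
    return CalibrationResult(mu, achieved)


def sweep_correlation(
    config_base: GeneratorConfig,
    rho_grid: list[float],
    matched_accuracy: float,
    n_pilot: int = 4000,
) -> pd.DataFrame:
    """Ensemble gain versus correlation at matched single-learner accuracy.

    For each rho the signal strength is recalibrated to ``matched_accuracy``,
    a cohort is generated, and the table reports the empirical similarity S,
    mean single accuracy, both ensemble accuracies, and the gains
    (ensemble accuracy minus mean single accuracy).  This is the in-silico
    form of the mechanism the diagnostics are built to expose: lower
    inter-learner overlap (lower S) yields a larger ensembling gain.
    """
    rows = []
    for rho in rho_grid:
        if not (0.0 <= rho <= 1.0):
            raise ValidationError(f"rho {rho} outside [0, 1]")
        base = dataclasses.replace(config_base, correlation=rho)
        calibration = calibrate_signal(matched_accuracy, base, n_pilot=n_pilot)
        cohort = generate_cohort(
            dataclasses.replace(base, signal_strength=calibration.signal_strength)
        )
        cube, truth = cohort.cube, cohort.truth
        similarity, _ = pairwise_similarity(cube)
        single = mean_single_accuracy(cohort)
        acc_arith = float(np.mean(arithmetic_ensemble(cube).prediction == truth))
        acc_geom = float(np.mean(geometric_ensemble(cube).prediction == truth))
        rows.append(
            {
                "rho": rho,
                "signal_strength": calibration.signal_strength,
                "similarity": similarity,
                "single_accuracy": single,
                "arithmetic_accuracy": acc_arith,
                "geometric_accuracy": acc_geom,
                "arithmetic_gain": acc_arith - single,
                "geometric_gain": acc_geom - single,
            }
        )
    return pd.DataFrame(rows)
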