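"""Soft-voting combination rules: arithmetic mean, geometric mean, product rule.

The arithmetic ensemble averages confidence vectors component-wise, so its
rows stay on the simplex.  The geometric ensemble takes the per-class
geometric mean; its rows are deliberately left unnormalized because only the
argmax matters and normalization (like the n-th root) rescales every
component identically.  A single zero confidence from any learner therefore
zeroes that class in the geometric combination — the *veto* mechanism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ConfidenceCube, ValidationError, predicted_classes

logger = logging.getLogger("ensemblekit")

RULES = ("arithmetic", "geometric")


@dataclass(frozen=True)
class EnsembleResult:
    """Combined confidence matrix and per-sample prediction for one rule.

    ``fallback_samples`` lists samples where every class was vetoed in the
    geometric combination and the prediction fell back to the arithmetic
    rule (empty for the arithmetic rule itself).
    """

    rule: str
    combined: np.ndarray
    prediction: np.ndarray
    fallback_samples: tuple[int, ...] = field(default=())


def arithmetic_ensemble(cube: ConfidenceCube) -> EnsembleResult:
    """Component-wise mean of the learners' confidence vectors.

    ``combined[s, a] = (1/n) * sum_i cube[i, s, a]``; rows remain on the
    simplex and the prediction is the row argmax (ties to smallest index).
    """
    combined = cube.values.mean(axis=0)
    return EnsembleResult("arithmetic", combined, predicted_classes(combined))


def _geometric_combined(cube: ConfidenceCube) -> np.ndarray:
    """Per-class geometric mean, log-domain, with exact zeros propagated."""
    values = cube.values
    vetoed = (values == 0.0).any(axis=0)
    safe = np.where(values > 0.0, values, 1.0)
    combined = np.exp(np.log(safe).sum(axis=0) / cube.n_learners)
    combined[vetoed] = 0.0
    return combined


def geometric_ensemble(cube: ConfidenceCube) -> EnsembleResult:
    """Per-class geometric mean ``(prod_i cube[i, s, a])^(1/n)``.

    Computed in the log domain for stability; exact zeros short-circuit to
    zero rather than entering -inf arithmetic.  Rows are NOT renormalized.
    A sample whose classes are all vetoed falls back to the arithmetic
    prediction, with a warning.
    """
    combined = _geometric_combined(cube)
    prediction = predicted_classes(combined)
    dead = np.flatnonzero(~combined.any(axis=1))
    if dead.size:
        logger.warning(
            "%d sample(s) had every class vetoed; falling back to the "
            "arithmetic prediction: %s", dead.size, dead.tolist()[:10],
        )
        prediction[dead] = arithmetic_ensemble(cube).prediction[dead]
    return EnsembleResult("geometric", combined, prediction, tuple(int(s) for s in dead))


def product_rule_predict(cube: ConfidenceCube) -> np.ndarray:
    """Prediction by ``argmax_a prod_i cube[i, s, a]``, log-domain.

    Taking the n-th root is a monotone transform, so this is sample-by-sample
    identical to the geometric ensemble's prediction, including the
    all-vetoed fallback.
    """
    values = cube.values
    vetoed = (values == 0.0).any(axis=0)
    scores = np.where(values > 0.0, values, 1.0)
    scores = np.log(scores).sum(axis=0)
    scores[vetoed] = -np.inf
    prediction = np.argmax(scores, axis=1)
    dead = np.flatnonzero(np.all(np.isneginf(scores), axis=1))
    if dead.size:
        prediction[dead] = arithmetic_ensemble(cube).prediction[dead]
    return prediction


def ensemble_predict(cube: ConfidenceCube, rule: str) -> EnsembleResult:
    """Dispatch to :func:`arithmetic_ensemble` or :func:`geometric_ensemble`."""
    if rule == "arithmetic":
        return arithmetic_ensemble(cube)
    if rule == "geometric":
        return geometric_ensemble(cube)
    raise ValidationError(f"unknown combination rule {rule!r}; expected one of {RULES}")
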