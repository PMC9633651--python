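"""Domain types, validation, prediction extraction and evaluation utilities.

The central container is the :class:`ConfidenceCube`: the stacked softmax
outputs of ``n`` learners over ``N`` test samples and ``K`` classes.  Each
``(learner, sample)`` row lives on the probability simplex.  Everything
downstream (combination rules, agreement diagnostics, the synthetic
generator) speaks in terms of this cube plus a ground-truth label vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

logger = logging.getLogger("ensemblekit")

#: Default tolerance on |row sum - 1| below which rows are silently
#: renormalized; softmax outputs written through text round-tripping
#: typically deviate by far less than this.
DEFAULT_ROW_SUM_TOLERANCE = 1e-6

# Deviations at or below this are indistinguishable from floating-point
# round-off; leaving such rows untouched makes validation idempotent.
_EXACT_ROW_SUM_EPS = 1e-12


class ValidationError(ValueError):
    """Raised when confidence values or labels violate their contracts."""


@dataclass(frozen=True)
class ConfidenceCube:
    """Confidence vectors of ``n`` learners over ``N`` samples and ``K`` classes.

    ``values[i, s, a]`` is learner ``i``'s confidence that sample ``s``
    belongs to class ``a``.  Construct via :func:`validate_cube`, which
    enforces the simplex invariants.
    """

    values: np.ndarray
    learner_names: tuple[str, ...]
    class_names: tuple[str, ...]

    @property
    def n_learners(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return self.values.shape[2]

    def learner(self, i: int) -> np.ndarray:
        """The ``(N, K)`` confidence matrix of learner ``i``."""
        return self.values[i]


def validate_cube(
    raw_values: np.ndarray,
    tolerance: float = DEFAULT_ROW_SUM_TOLERANCE,
    learner_names: Sequence[str] | None = None,
    class_names: Sequence[str] | None = None,
) -> ConfidenceCube:
    """Validate a ``(n, N, K)`` array of confidences and wrap it in a cube.

    Rows whose sum deviates from 1 by less than ``tolerance`` are
    renormalized; a larger deviation, or any negative entry, is an error
    naming the offending learner and sample.  Idempotent: validating an
    already-valid cube returns its values unchanged.
    """
    values = np.asarray(raw_values, dtype=float)
    if values.ndim != 3:
        raise ValidationError(
            f"confidence array must have 3 axes (learner, sample, class), got {values.ndim}"
        )
    if tolerance < 0:
        raise ValidationError("tolerance must be non-negative")
    n, n_samples, k = values.shape
    if n < 1 or n_samples < 1 or k < 2:
        raise ValidationError(
            f"need n>=1 learners, N>=1 samples, K>=2 classes; got shape {values.shape}"
        )
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        i, s, _ = np.argwhere((values < 0) | ~np.isfinite(values))[0]
        raise ValidationError(
            f"negative or non-finite confidence at learner {i}, sample {s}"
        )
    sums = values.sum(axis=2)
    dev = np.abs(sums - 1.0)
    if np.any(dev >= max(tolerance, _EXACT_ROW_SUM_EPS)):
        bad = dev >= max(tolerance, _EXACT_ROW_SUM_EPS)
        i, s = np.argwhere(bad)[0]
        raise ValidationError(
            f"row sum {sums[i, s]:.9g} deviates from 1 by >= {tolerance:g} "
            f"at learner {i}, sample {s}"
        )
    fix = dev > _EXACT_ROW_SUM_EPS
    if np.any(fix):
        values = values.copy()
        values[fix] = values[fix] / sums[fix][:, None]
        logger.warning("renormalized %d confidence rows (|sum-1| < %g)", fix.sum(), tolerance)

    if learner_names is None:
        learner_names = tuple(f"learner_{i}" for i in range(n))
    if class_names is None:
        class_names = tuple(f"class_{a}" for a in range(k))
    if len(learner_names) != n or len(class_names) != k:
        raise ValidationError("learner_names/class_names lengths do not match cube shape")
    return ConfidenceCube(values, tuple(learner_names), tuple(class_names))


def validate_labels(truth: Iterable[int], n_classes: int) -> np.ndarray:
    """Validate ground-truth class indices against ``n_classes``.

    Returns an int64 label vector; every entry must lie in ``0..n_classes-1``.
    """
    labels = np.asarray(list(truth) if not isinstance(truth, np.ndarray) else truth)
    labels = labels.astype(np.int64)
    if labels.ndim != 1:
        raise ValidationError("labels must be one-dimensional")
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValidationError(
            f"labels must lie in 0..{n_classes - 1}, got range "
            f"[{labels.min()}, {labels.max()}]"
        )
    return labels


def predicted_class(confidence_row: np.ndarray) -> int:
    """Argmax of a confidence vector; ties break to the smallest class index.

    Invariant under multiplication by any positive scalar, which is why the
    geometric rule can skip the n-th root and normalization.
    """
    row = np.asarray(confidence_row, dtype=float)
    if row.ndim != 1 or row.size == 0:
        raise ValidationError("confidence row must be a non-empty 1-D vector")
    return int(np.argmax(row))


def predicted_classes(confidence_matrix: np.ndarray) -> np.ndarray:
    """Row-wise :func:`predicted_class` over an ``(N, K)`` matrix."""
    mat = np.asarray(confidence_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[1] == 0:
        raise ValidationError("confidence matrix must be 2-D with K >= 1 columns")
    return np.argmax(mat, axis=1)


def class_weights(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Balanced inverse-frequency weights ``w_a = N / (K_present * N_a)``.

    ``K_present`` counts classes that actually occur; absent classes get
    weight 0 with a logged warning so that label subsets remain loadable.
    Matches scikit-learn's ``'balanced'`` convention on the present classes,
    and satisfies ``sum_a w_a * N_a = N``.
    """
    if n_classes < 2:
        raise ValidationError("n_classes must be >= 2")
    labels = validate_labels(labels, n_classes)
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    present = counts > 0
    k_present = int(present.sum())
    if k_present == 0:
        raise ValidationError("cannot compute class weights from an empty label vector")
    weights = np.zeros(n_classes)
    weights[present] = labels.size / (k_present * counts[present])
    if k_present < n_classes:
        absent = np.flatnonzero(~present)
        logger.warning("classes with zero count get weight 0: %s", absent.tolist())
    return weights


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy, macro-F1 and the per-class precision/recall/F1 table."""

    accuracy: float
    macro_f1: float
    per_class: pd.DataFrame = field(repr=False)


def classification_metrics(prediction: np.ndarray, labels: np.ndarray) -> ClassificationMetrics:
    """Accuracy, macro-averaged F1 and per-class precision/recall/F1.

    The macro average runs over the union of classes present in the truth or
    the predictions; a class with zero precision and recall contributes
    F1 = 0 (scikit-learn's ``zero_division=0`` convention).
    """
    prediction = np.asarray(prediction)
    labels = np.asarray(labels)
    if prediction.shape != labels.shape:
        raise ValidationError(
            f"prediction length {prediction.size} != labels length {labels.size}"
        )
    observed = np.union1d(np.unique(labels), np.unique(prediction))
    precision, recall, f1, support = precision_recall_fscore_support(
        labels, prediction, labels=observed, zero_division=0
    )
    per_class = pd.DataFrame(
        {
            "class": observed,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support,
        }
    ).set_index("class")
    return ClassificationMetrics(
        accuracy=float(np.mean(prediction == labels)),
        macro_f1=float(np.mean(f1)),
        per_class=per_class,
    )


# ---------------------------------------------------------------------------
# File interface: one delimited table per learner plus a labels table.
# ---------------------------------------------------------------------------

def read_confidence_table(path: str | Path) -> pd.DataFrame:
    """Read one learner's confidence table (CSV or TSV, delimiter sniffed).

    Expected header: ``sample_id,<class_1>,...,<class_K>``; returns a frame
    indexed by ``sample_id`` with one column per class.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=None, engine="python")
    if frame.columns[0] != "sample_id":
        raise ValidationError(f"{path}: first column must be 'sample_id', got {frame.columns[0]!r}")
    if frame.shape[1] < 3:
        raise ValidationError(f"{path}: need at least two class columns")
    if frame["sample_id"].duplicated().any():
        dup = frame["sample_id"][frame["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicated sample_id {dup!r}")
    return frame.set_index("sample_id")


def load_cohort(
    confidence_paths: Sequence[str | Path],
    labels_path: str | Path,
    tolerance: float = DEFAULT_ROW_SUM_TOLERANCE,
) -> tuple[ConfidenceCube, np.ndarray, list]:
    """Load per-learner confidence files plus a labels file into a cube.

    Samples are aligned by ``sample_id`` (not row order); every learner must
    cover exactly the same id set.  The labels file has columns
    ``sample_id,true_class`` where ``true_class`` is a class name from the
    confidence headers (or an integer class index).

    Returns ``(cube, truth, sample_ids)`` in the first learner's sample order.
    """
    if len(confidence_paths) < 1:
        raise ValidationError("need at least one confidence file")
    frames = [read_confidence_table(p) for p in confidence_paths]
    class_names = tuple(frames[0].columns)
    ids = list(frames[0].index)
    for path, frame in zip(confidence_paths, frames):
        if tuple(frame.columns) != class_names:
            raise ValidationError(f"{path}: class columns differ from {confidence_paths[0]}")
        if set(frame.index) != set(ids):
            missing = set(ids).symmetric_difference(frame.index)
            raise ValidationError(
                f"{path}: sample_id set differs from {confidence_paths[0]} "
                f"(e.g. {sorted(map(str, missing))[:3]})"
            )
    values = np.stack([frame.loc[ids].to_numpy(dtype=float) for frame in frames])
    learner_names = tuple(Path(p).stem for p in confidence_paths)
    cube = validate_cube(values, tolerance, learner_names, class_names)

    labels_frame = pd.read_csv(labels_path, sep=None, engine="python")
    if list(labels_frame.columns[:2]) != ["sample_id", "true_class"]:
        raise ValidationError(f"{labels_path}: expected header 'sample_id,true_class'")
    labels_frame = labels_frame.set_index("sample_id")
    if set(labels_frame.index) != set(ids):
        raise ValidationError(f"{labels_path}: sample_id set differs from the confidence files")
    raw = labels_frame.loc[ids, "true_class"]
    name_to_index: Mapping[str, int] = {name: a for a, name in enumerate(class_names)}
    truth = np.empty(len(ids), dtype=np.int64)
    for s, value in enumerate(raw):
        if str(value) in name_to_index:
            truth[s] = name_to_index[str(value)]
        else:
            try:
                truth[s] = int(value)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{labels_path}: unknown class {value!r} for sample {ids[s]!r}"
                ) from None
    truth = validate_labels(truth, len(class_names))
    return cube, truth, ids
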