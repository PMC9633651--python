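"""Inter-learner agreement diagnostics.

These statistics explain *why* an ensemble beats its members: the mean
pairwise similarity S of the learners' confidence vectors, the R/W
agreement-pattern histogram (RRR/RRW/RWW/WWW for three learners), the same
histogram conditioned on ensemble-correct samples, the rescue analysis of
RWW samples (where only one learner is right yet the ensemble can still
recover the truth), and per-learner top-1 confidence profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import ConfidenceCube, ValidationError, predicted_classes, validate_labels
from .ensembling import ensemble_predict

_DECILES = np.arange(0.1, 1.0, 0.1)


def pattern_label(m_wrong: int, n_learners: int) -> str:
    """Human-readable agreement label: ``m_wrong`` W's after the R's (RRW...)."""
    return "R" * (n_learners - m_wrong) + "W" * m_wrong


@dataclass(frozen=True)
class AgreementReport:
    """Agreement-pattern counts, similarity S with uncertainty, top-1 profile.

    ``pattern_counts`` maps the number of wrong learners ``m = 0..n`` to the
    sample count; for n=3 the labels are RRR, RRW, RWW, WWW.
    """

    n_learners: int
    n_samples: int
    pattern_counts: Mapping[int, int]
    similarity_mean: float
    similarity_se: float
    top1_mean: Mapping[str, float] = field(default_factory=dict)

    @property
    def labelled_counts(self) -> dict[str, int]:
        return {
            pattern_label(m, self.n_learners): int(c)
            for m, c in sorted(self.pattern_counts.items())
        }


def per_sample_similarity(cube: ConfidenceCube) -> np.ndarray:
    """S_s: mean pairwise dot product of the learners' confidence vectors.

    ``S_s = (2 / (n (n-1))) * sum_{i<j} c_i(s) . c_j(s)``; for three learners
    this is exactly ``(c0.c1 + c0.c2 + c1.c2) / 3``.  For simplex rows
    S_s is in [0, 1], hitting 1 only when all learners emit the same
    one-hot vector.
    """
    n = cube.n_learners
    if n < 2:
        raise ValidationError("similarity needs at least two learners")
    dots = np.einsum("isk,jsk->ijs", cube.values, cube.values)
    iu, ju = np.triu_indices(n, k=1)
    return dots[iu, ju].mean(axis=0)


def pairwise_similarity(cube: ConfidenceCube) -> tuple[float, float]:
    """Mean similarity over the test set and its standard error.

    The uncertainty is the standard error of the per-sample mean
    (sample standard deviation / sqrt(N)); 0 when N = 1.
    """
    s = per_sample_similarity(cube)
    se = float(s.std(ddof=1) / np.sqrt(s.size)) if s.size > 1 else 0.0
    return float(s.mean()), se


def wrong_learner_counts(cube: ConfidenceCube, truth: np.ndarray) -> np.ndarray:
    """Per sample, how many learners predict a class other than the truth."""
    truth = validate_labels(truth, cube.n_classes)
    if truth.size != cube.n_samples:
        raise ValidationError("labels length does not match cube sample count")
    per_learner = np.stack([predicted_classes(cube.learner(i)) for i in range(cube.n_learners)])
    return (per_learner != truth[None, :]).sum(axis=0)


def agreement_patterns(cube: ConfidenceCube, truth: np.ndarray) -> dict[int, int]:
    """Histogram of the number of wrong learners, m = 0..n (partitions N)."""
    wrong = wrong_learner_counts(cube, truth)
    counts = np.bincount(wrong, minlength=cube.n_learners + 1)
    return {m: int(c) for m, c in enumerate(counts)}


def conditional_patterns(
    cube: ConfidenceCube, truth: np.ndarray, rule: str
) -> dict[int, int]:
    """Pattern histogram restricted to samples the ensemble classifies correctly."""
    truth = validate_labels(truth, cube.n_classes)
    wrong = wrong_learner_counts(cube, truth)
    correct = ensemble_predict(cube, rule).prediction == truth
    counts = np.bincount(wrong[correct], minlength=cube.n_learners + 1)
    return {m: int(c) for m, c in enumerate(counts)}


def top1_profile(cube: ConfidenceCube) -> pd.DataFrame:
    """Per-learner summary (mean, median, deciles) of the top-1 probability.

    The top-1 probability — the largest component of a confidence vector —
    measures how peaked a learner's predictions are; flatter vectors leave
    more room for ensembling to help.
    """
    top1 = cube.values.max(axis=2)  # (n, N)
    rows = []
    for i, name in enumerate(cube.learner_names):
        row = {"learner": name, "mean": top1[i].mean(), "median": np.median(top1[i])}
        for q, value in zip(_DECILES, np.quantile(top1[i], _DECILES)):
            row[f"d{int(round(q * 100))}"] = value
        rows.append(row)
    return pd.DataFrame(rows).set_index("learner")


def build_report(cube: ConfidenceCube, truth: np.ndarray) -> AgreementReport:
    """Assemble the full agreement report for one cohort."""
    mean, se = pairwise_similarity(cube)
    profile = top1_profile(cube)
    return AgreementReport(
        n_learners=cube.n_learners,
        n_samples=cube.n_samples,
        pattern_counts=agreement_patterns(cube, truth),
        similarity_mean=mean,
        similarity_se=se,
        top1_mean={name: float(profile.loc[name, "mean"]) for name in cube.learner_names},
    )


@dataclass(frozen=True)
class RescueTable:
    """Per-RWW-sample rescue outcomes plus quantile-binned rescue rates.

    ``samples`` has one row per sample where exactly one of three learners
    was right: the ratio of the second- to third-largest component of the
    ensembled confidence vector (``inf`` when the third is 0), whether the
    ensemble rescued the sample (predicted the truth), and the raw and
    renormalized second/third components.  ``binned`` reports the rescue
    frequency per ratio-quantile bin.
    """

    rule: str
    samples: pd.DataFrame = field(repr=False)
    binned: pd.DataFrame = field(repr=False)

    @property
    def n_rww(self) -> int:
        return len(self.samples)


def rww_rescue_analysis(
    cube: ConfidenceCube, truth: np.ndarray, rule: str, n_bins: int = 5
) -> RescueTable:
    """Rescue analysis over RWW samples (exactly one of three learners right).

    The chance that ensembling rescues such a sample depends on the ratio
    between the second and third components of the ensembled confidence
    vector: when the two wrong learners disagree with *each other*, the
    wrong mass is split, the ratio stays near 1, and the single correct
    learner can tip the argmax.  Ratios are binned into ``n_bins`` quantile
    bins (infinite ratios are assigned to the top bin).
    """
    if cube.n_learners != 3:
        raise ValidationError(
            "RWW rescue analysis is defined for exactly three learners, "
            f"got {cube.n_learners}"
        )
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    truth = validate_labels(truth, cube.n_classes)
    wrong = wrong_learner_counts(cube, truth)
    rww = np.flatnonzero(wrong == 2)
    result = ensemble_predict(cube, rule)
    empty_cols = ["sample", "ratio", "rescued", "second_raw", "third_raw",
                  "second_norm", "third_norm"]
    if rww.size == 0:
        return RescueTable(
            rule,
            pd.DataFrame(columns=empty_cols),
            pd.DataFrame(columns=["bin", "n", "rescue_rate"]),
        )
    combined = result.combined[rww]
    ordered = np.sort(combined, axis=1)[:, ::-1]
    second, third = ordered[:, 1], ordered[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(third > 0, second / np.where(third > 0, third, 1.0), np.inf)
    row_sums = combined.sum(axis=1)
    norm = np.where(row_sums > 0, row_sums, 1.0)
    samples = pd.DataFrame(
        {
            "sample": rww,
            "ratio": ratio,
            "rescued": result.prediction[rww] == truth[rww],
            "second_raw": second,
            "third_raw": third,
            "second_norm": second / norm,
            "third_norm": third / norm,
        }
    )
    finite = samples["ratio"][np.isfinite(samples["ratio"])]
    if finite.size:
        bins = pd.qcut(finite, min(n_bins, finite.size), duplicates="drop")
        codes = pd.Series(pd.Categorical(bins).codes, index=finite.index)
        labels = list(pd.Categorical(bins).categories.astype(str))
    else:
        codes = pd.Series(dtype=int)
        labels = []
    top = len(labels) - 1 if labels else 0
    if not labels:
        labels = ["[inf]"]
    bin_index = pd.Series(top, index=samples.index)
    bin_index.loc[codes.index] = codes
    samples["bin"] = bin_index
    binned = (
        samples.groupby("bin")["rescued"]
        .agg(n="size", rescue_rate="mean")
        .reset_index()
    )
    binned["bin"] = binned["bin"].map(lambda c: labels[c])
    return RescueTable(rule, samples, binned)


def compare_reports(report_a: AgreementReport, report_b: AgreementReport) -> pd.DataFrame:
    """Side-by-side diff of two agreement reports.

    One row per pattern with counts and the count ratio b/a (NaN marks a
    zero denominator), followed by rows for the similarity mean, its
    standard error, and the learner-averaged top-1 mean.
    """
    if report_a.n_learners != report_b.n_learners:
        raise ValidationError("reports were built with different learner counts")
    rows = []
    for m in range(report_a.n_learners + 1):
        a = report_a.pattern_counts.get(m, 0)
        b = report_b.pattern_counts.get(m, 0)
        rows.append(
            {
                "quantity": pattern_label(m, report_a.n_learners),
                "a": a,
                "b": b,
                "ratio_b_over_a": b / a if a else np.nan,
            }
        )
    for name, a, b in [
        ("similarity_mean", report_a.similarity_mean, report_b.similarity_mean),
        ("similarity_se", report_a.similarity_se, report_b.similarity_se),
        (
            "top1_mean",
            float(np.mean(list(report_a.top1_mean.values()))) if report_a.top1_mean else np.nan,
            float(np.mean(list(report_b.top1_mean.values()))) if report_b.top1_mean else np.nan,
        ),
    ]:
        rows.append(
            {"quantity": name, "a": a, "b": b, "ratio_b_over_a": b / a if a else np.nan}
        )
    return pd.DataFrame(rows).set_index("quantity")
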