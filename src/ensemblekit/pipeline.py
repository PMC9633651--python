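"""End-to-end pipeline: load confidence files, ensemble, diagnose, report.

Produces deterministic outputs for identical inputs: one combined-confidence
CSV per rule, a machine-readable JSON report (schema version, config echo,
metrics, diagnostics, warnings) and a plain-text agreement-pattern table.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    ConfidenceCube,
    ValidationError,
    classification_metrics,
    load_cohort,
    predicted_classes,
)
from .diagnostics import (
    AgreementReport,
    build_report,
    compare_reports,
    conditional_patterns,
    pattern_label,
    rww_rescue_analysis,
)
from .ensembling import RULES, ensemble_predict

logger = logging.getLogger("ensemblekit")

REPORT_SCHEMA_VERSION = 1


def _labelled(counts: Mapping[int, int], n: int) -> dict[str, int]:
    return {pattern_label(m, n): int(counts.get(m, 0)) for m in range(n + 1)}


def render_pattern_table(rows: Mapping[str, Mapping[str, int]]) -> str:
    """Aligned text table of agreement-pattern counts, one row per panel.

    Columns are the pattern labels (RRR/RRW/RWW/WWW for three learners);
    with exactly two rows a ratio row (second / first) is appended.
    """
    if not rows:
        return "(no reports)"
    names = list(rows)
    columns = list(rows[names[0]])
    table = [["panel", *columns]]
    for name in names:
        table.append([name, *[str(int(rows[name].get(c, 0))) for c in columns]])
    if len(names) == 2:
        ratio_row = ["ratio"]
        for c in columns:
            a, b = rows[names[0]].get(c, 0), rows[names[1]].get(c, 0)
            ratio_row.append(f"{b / a:.2f}" if a else "undef")
        table.append(ratio_row)
    widths = [max(len(r[j]) for r in table) for j in range(len(table[0]))]
    lines = ["  ".join(cell.rjust(w) for cell, w in zip(r, widths)) for r in table]
    return "\n".join(lines)


def render_fig2_style_table(
    unconditional: Mapping[int, int],
    conditional: Mapping[str, Mapping[int, int]],
    n_learners: int,
) -> str:
    """Unconditional and per-rule conditional pattern counts as one table."""
    rows = {"all samples": _labelled(unconditional, n_learners)}
    for rule, counts in conditional.items():
        rows[f"{rule}-correct"] = _labelled(counts, n_learners)
    return render_pattern_table(rows)


class _ReportWarnings(logging.Handler):
    """Capture package warnings (renormalization, veto fallback) for the report."""

    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def run_pipeline(
    inputs: Sequence[str | Path],
    labels_path: str | Path,
    rules: Sequence[str] = RULES,
    out_dir: str | Path = ".",
    n_rescue_bins: int = 5,
) -> dict:
    """Run the full analysis and write ensemble outputs, JSON and text reports.

    Requires at least two learners with aligned sample ids.  Writes
    ``ensemble_<rule>.csv`` (combined matrix plus ``predicted_class``) per
    rule, ``report.json`` and ``summary.txt`` under ``out_dir``, and returns
    the report dictionary.
    """
    if len(inputs) < 2:
        raise ValidationError("pipeline needs at least two learner confidence files")
    for rule in rules:
        if rule not in RULES:
            raise ValidationError(f"unknown combination rule {rule!r}; expected one of {RULES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    capture = _ReportWarnings()
    logger.addHandler(capture)
    try:
        cube, truth, sample_ids = load_cohort(inputs, labels_path)
        report: dict = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "tool_version": __version__,
            "config": {
                "inputs": [str(p) for p in inputs],
                "labels": str(labels_path),
                "rules": list(rules),
                "n_rescue_bins": n_rescue_bins,
            },
            "n_learners": cube.n_learners,
            "n_samples": cube.n_samples,
            "n_classes": cube.n_classes,
            "learners": {},
            "ensembles": {},
        }
        for i, name in enumerate(cube.learner_names):
            metrics = classification_metrics(predicted_classes(cube.learner(i)), truth)
            report["learners"][name] = {
                "accuracy": metrics.accuracy,
                "macro_f1": metrics.macro_f1,
            }
        agreement = build_report(cube, truth)
        report["agreement"] = {
            "pattern_counts": agreement.labelled_counts,
            "similarity_mean": agreement.similarity_mean,
            "similarity_se": agreement.similarity_se,
            "top1_mean": agreement.top1_mean,
        }
        conditional: dict[str, Mapping[int, int]] = {}
        for rule in rules:
            result = ensemble_predict(cube, rule)
            metrics = classification_metrics(result.prediction, truth)
            cond = conditional_patterns(cube, truth, rule)
            conditional[rule] = cond
            entry = {
                "accuracy": metrics.accuracy,
                "macro_f1": metrics.macro_f1,
                "conditional_pattern_counts": _labelled(cond, cube.n_learners),
                "veto_fallback_samples": list(result.fallback_samples),
            }
            if cube.n_learners == 3:
                rescue = rww_rescue_analysis(cube, truth, rule, n_rescue_bins)
                entry["rww_rescue"] = {
                    "n_rww": rescue.n_rww,
                    "n_rescued": int(rescue.samples["rescued"].sum()) if rescue.n_rww else 0,
                    "bins": rescue.binned.to_dict(orient="records"),
                }
            report["ensembles"][rule] = entry

            frame = pd.DataFrame(result.combined, columns=list(cube.class_names))
            frame.insert(0, "sample_id", sample_ids)
            frame["predicted_class"] = [cube.class_names[a] for a in result.prediction]
            frame.to_csv(out_dir / f"ensemble_{rule}.csv", index=False)

        report["warnings"] = capture.messages
        text = render_fig2_style_table(
            agreement.pattern_counts, conditional, cube.n_learners
        )
        (out_dir / "summary.txt").write_text(text + "\n")
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        return report
    finally:
        logger.removeHandler(capture)


def compare_report_files(path_a: str | Path, path_b: str | Path) -> pd.DataFrame:
    """Side-by-side diff of two pipeline JSON reports (pattern counts, S, top-1)."""

    def load(path: str | Path) -> AgreementReport:
        data = json.loads(Path(path).read_text())
        agreement = data["agreement"]
        labelled = agreement["pattern_counts"]
        n = data["n_learners"]
        counts = {m: labelled[pattern_label(m, n)] for m in range(n + 1)}
        return AgreementReport(
            n_learners=n,
            n_samples=data["n_samples"],
            pattern_counts=counts,
            similarity_mean=agreement["similarity_mean"],
            similarity_se=agreement["similarity_se"],
            top1_mean=agreement["top1_mean"],
        )

    return compare_reports(load(path_a), load(path_b))
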