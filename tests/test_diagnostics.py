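"""Similarity S, agreement patterns, conditioning, RWW rescue, top-1 profiles."""

import numpy as np
import pandas as pd
import pytest

from ensemblekit import (
    AgreementReport,
    ValidationError,
    agreement_patterns,
    build_report,
    compare_reports,
    conditional_patterns,
    ensemble_predict,
    pairwise_similarity,
    pattern_label,
    per_sample_similarity,
    predicted_classes,
    rww_rescue_analysis,
    top1_profile,
    validate_cube,
)
from conftest import random_simplex_cube


def one_hot_cube(rows):
    """rows[i][s] = class index learner i bets everything on for sample s."""
    rows = np.asarray(rows)
    k = rows.max() + 2
    values = np.zeros((*rows.shape, k))
    n, n_samples = rows.shape
    values[np.arange(n)[:, None], np.arange(n_samples)[None, :], rows] = 1.0
    return validate_cube(values)


class TestSimilarity:
    def test_identical_one_hots_give_unit_similarity(self):
        cube = one_hot_cube([[1, 0, 2], [1, 0, 2], [1, 0, 2]])
        mean, se = pairwise_similarity(cube)
        assert mean == pytest.approx(1.0)
        assert se == pytest.approx(0.0)

    def test_two_against_one_one_hot(self):
        cube = one_hot_cube([[0], [0], [1]])
        assert per_sample_similarity(cube)[0] == pytest.approx(1 / 3)

    def test_uniform_vectors_give_one_over_k(self):
        cube = validate_cube(np.full((3, 4, 4), 0.25))
        mean, _ = pairwise_similarity(cube)
        assert mean == pytest.approx(0.25)

    def test_single_learner_rejected(self, rng):
        with pytest.raises(ValidationError):
            pairwise_similarity(random_simplex_cube(rng, 1, 5, 3))

    def test_bounds_and_permutation_invariance(self, rng):
        cube = random_simplex_cube(rng, 4, 30, 5)
        s = per_sample_similarity(cube)
        assert np.all((s >= 0) & (s <= 1))
        learner_perm = validate_cube(cube.values[rng.permutation(4)])
        class_perm = validate_cube(cube.values[:, :, rng.permutation(5)])
        assert pairwise_similarity(learner_perm)[0] == pytest.approx(
            pairwise_similarity(cube)[0], abs=1e-12
        )
        assert pairwise_similarity(class_perm)[0] == pytest.approx(
            pairwise_similarity(cube)[0], abs=1e-12
        )

    def test_agrees_with_naive_pair_loop(self, rng):
        cube = random_simplex_cube(rng, 3, 40, 4)
        naive = np.zeros(40)
        for s in range(40):
            for i in range(3):
                for j in range(i + 1, 3):
                    naive[s] += np.dot(cube.values[i, s], cube.values[j, s])
            naive[s] /= 3
        assert np.allclose(per_sample_similarity(cube), naive, atol=1e-12)


class TestAgreementPatterns:
    def test_perfect_learners(self):
        cube = one_hot_cube([[0] * 5, [0] * 5, [0] * 5])
        truth = np.zeros(5, dtype=int)
        assert agreement_patterns(cube, truth) == {0: 5, 1: 0, 2: 0, 3: 0}

    def test_constructed_wrong_counts(self):
        # per-sample wrong learner counts 0, 1, 2, 3
        cube = one_hot_cube(
            [[0, 0, 0, 1], [0, 0, 1, 1], [0, 1, 1, 1]]
        )
        truth = np.zeros(4, dtype=int)
        assert agreement_patterns(cube, truth) == {0: 1, 1: 1, 2: 1, 3: 1}

    def test_counts_partition_sample_set(self, rng):
        cube = random_simplex_cube(rng, 3, 57, 4)
        truth = rng.integers(0, 4, size=57)
        assert sum(agreement_patterns(cube, truth).values()) == 57

    def test_agrees_with_enumeration_oracle(self, rng):
        cube = random_simplex_cube(rng, 3, 40, 4)
        truth = rng.integers(0, 4, size=40)
        oracle = {m: 0 for m in range(4)}
        for s in range(40):
            wrong = sum(
                int(np.argmax(cube.values[i, s]) != truth[s]) for i in range(3)
            )
            oracle[wrong] += 1
        assert agreement_patterns(cube, truth) == oracle

    def test_pattern_labels(self):
        assert [pattern_label(m, 3) for m in range(4)] == ["RRR", "RRW", "RWW", "WWW"]
        assert [pattern_label(m, 2) for m in range(3)] == ["RR", "RW", "WW"]


class TestConditionalPatterns:
    def test_perfect_learners_condition_is_vacuous(self):
        cube = one_hot_cube([[0] * 5, [0] * 5, [0] * 5])
        truth = np.zeros(5, dtype=int)
        for rule in ("arithmetic", "geometric"):
            assert conditional_patterns(cube, truth, rule) == agreement_patterns(cube, truth)

    def test_ensemble_wrong_sample_excluded(self):
        cube = one_hot_cube([[1], [1], [1]])  # all learners wrong, ensemble wrong
        truth = np.zeros(1, dtype=int)
        counts = conditional_patterns(cube, truth, "arithmetic")
        assert sum(counts.values()) == 0

    def test_rescued_rww_sample_is_counted(self):
        values = np.array(
            [[[0.6, 0.3, 0.1]], [[0.2, 0.5, 0.3]], [[0.25, 0.2, 0.55]]]
        )
        cube = validate_cube(values)
        truth = np.zeros(1, dtype=int)
        combined = ensemble_predict(cube, "arithmetic").combined[0]
        assert combined == pytest.approx([0.35, 1.0 / 3.0, 0.95 / 3.0])
        assert conditional_patterns(cube, truth, "arithmetic") == {0: 0, 1: 0, 2: 1, 3: 0}

    def test_conditional_never_exceeds_unconditional(self, rng):
        cube = random_simplex_cube(rng, 3, 80, 4)
        truth = rng.integers(0, 4, size=80)
        unconditional = agreement_patterns(cube, truth)
        for rule in ("arithmetic", "geometric"):
            conditional = conditional_patterns(cube, truth, rule)
            assert all(conditional[m] <= unconditional[m] for m in unconditional)

    def test_identical_learners_concentrate_on_extremes(self, rng):
        learner = rng.dirichlet(np.ones(4), size=30)
        cube = validate_cube(np.stack([learner] * 3))
        truth = rng.integers(0, 4, size=30)
        counts = agreement_patterns(cube, truth)
        assert counts[1] == 0 and counts[2] == 0
        for rule in ("arithmetic", "geometric"):
            assert conditional_patterns(cube, truth, rule)[3] == 0


class TestRescueAnalysis:
    def test_rescued_toy_sample_ratio(self):
        values = np.array(
            [[[0.6, 0.3, 0.1]], [[0.2, 0.5, 0.3]], [[0.25, 0.2, 0.55]]]
        )
        cube = validate_cube(values)
        table = rww_rescue_analysis(cube, np.zeros(1, dtype=int), "arithmetic")
        assert table.n_rww == 1
        row = table.samples.iloc[0]
        assert row["ratio"] == pytest.approx((1.0 / 3.0) / (0.95 / 3.0))
        assert bool(row["rescued"])

    def test_confidently_agreeing_wrong_learners_are_not_rescued(self):
        values = np.array(
            [[[0.6, 0.4, 0.0]], [[0.05, 0.9, 0.05]], [[0.1, 0.85, 0.05]]]
        )
        cube = validate_cube(values)
        table = rww_rescue_analysis(cube, np.zeros(1, dtype=int), "arithmetic")
        assert table.n_rww == 1
        assert not bool(table.samples["rescued"].iloc[0])

    def test_ratio_at_least_one_when_third_positive(self, rng):
        cube = random_simplex_cube(rng, 3, 100, 5)
        truth = rng.integers(0, 5, size=100)
        for rule in ("arithmetic", "geometric"):
            table = rww_rescue_analysis(cube, truth, rule)
            finite = table.samples["ratio"][np.isfinite(table.samples["ratio"])]
            assert (finite >= 1.0).all()

    def test_all_rescued_gives_unit_bin_rates(self):
        values = np.array(
            [[[0.6, 0.3, 0.1]], [[0.2, 0.5, 0.3]], [[0.25, 0.2, 0.55]]]
        )
        cube = validate_cube(values)
        table = rww_rescue_analysis(cube, np.zeros(1, dtype=int), "arithmetic", n_bins=2)
        assert (table.binned["rescue_rate"] == 1.0).all()

    def test_no_rww_samples_yields_empty_table(self):
        cube = one_hot_cube([[0, 0], [0, 0], [0, 0]])
        table = rww_rescue_analysis(cube, np.zeros(2, dtype=int), "geometric")
        assert table.n_rww == 0 and table.binned.empty

    def test_requires_exactly_three_learners(self, rng):
        cube = random_simplex_cube(rng, 2, 10, 3)
        with pytest.raises(ValidationError, match="three learners"):
            rww_rescue_analysis(cube, np.zeros(10, dtype=int), "arithmetic")

    def test_binned_rates_match_naive_recount(self, rng):
        cube = random_simplex_cube(rng, 3, 200, 4)
        truth = rng.integers(0, 4, size=200)
        table = rww_rescue_analysis(cube, truth, "geometric", n_bins=4)
        assert table.binned["n"].sum() == table.n_rww
        recount = table.samples.groupby("bin")["rescued"].mean().to_numpy()
        assert np.allclose(table.binned["rescue_rate"].to_numpy(), recount, atol=1e-12)


class TestTop1Profile:
    def test_one_hot_and_uniform_limits(self):
        one_hot = one_hot_cube([[0, 1], [1, 0]])
        assert (top1_profile(one_hot)["mean"] == 1.0).all()
        uniform = validate_cube(np.full((2, 3, 5), 0.2))
        assert np.allclose(top1_profile(uniform)["mean"], 0.2)

    def test_mixed_fixture_mean(self):
        k = 5
        peaked = np.zeros((1, 4, k))
        peaked[:, :, 0] = 1.0
        flat = np.full((1, 4, k), 1.0 / k)
        values = np.concatenate([peaked, flat], axis=1)  # one learner, half/half
        profile = top1_profile(validate_cube(values))
        assert profile["mean"].iloc[0] == pytest.approx(0.6)

    def test_deciles_are_monotone(self, rng):
        profile = top1_profile(random_simplex_cube(rng, 2, 50, 4))
        deciles = profile[[f"d{d}" for d in range(10, 100, 10)]].to_numpy()
        assert np.all(np.diff(deciles, axis=1) >= 0)


def make_report(pattern_counts, similarity=0.8, se=0.01, top1=None, n=3):
    return AgreementReport(
        n_learners=n,
        n_samples=sum(pattern_counts.values()),
        pattern_counts=pattern_counts,
        similarity_mean=similarity,
        similarity_se=se,
        top1_mean=top1 or {"a": 0.9},
    )


class TestCompareReports:
    def test_identical_reports_have_unit_ratios(self):
        report = make_report({0: 10, 1: 5, 2: 2, 3: 1})
        diff = compare_reports(report, report)
        assert np.allclose(diff["ratio_b_over_a"].dropna(), 1.0)

    def test_doubled_rww_count_has_ratio_two(self):
        # conditional RWW counts 8 vs 16, as printed for the CNN vs DeiT ensembles
        a = make_report({0: 2523, 1: 200, 2: 8, 3: 0})
        b = make_report({0: 2515, 1: 210, 2: 16, 3: 0})
        diff = compare_reports(a, b)
        assert diff.loc["RWW", "ratio_b_over_a"] == pytest.approx(2.0)

    def test_zero_denominator_marked_undefined(self):
        a = make_report({0: 10, 1: 0, 2: 0, 3: 0})
        b = make_report({0: 10, 1: 3, 2: 0, 3: 0})
        diff = compare_reports(a, b)
        assert np.isnan(diff.loc["RRW", "ratio_b_over_a"])

    def test_mismatched_learner_counts_rejected(self):
        a = make_report({0: 1, 1: 0, 2: 0, 3: 0}, n=3)
        b = make_report({0: 1, 1: 0, 2: 0}, n=2)
        with pytest.raises(ValidationError):
            compare_reports(a, b)


def test_build_report_collects_all_diagnostics(rng):
    cube = random_simplex_cube(rng, 3, 60, 4)
    truth = rng.integers(0, 4, size=60)
    report = build_report(cube, truth)
    assert report.n_samples == 60
    assert sum(report.pattern_counts.values()) == 60
    assert 0.0 <= report.similarity_mean <= 1.0
    assert set(report.top1_mean) == set(cube.learner_names)
    assert set(report.labelled_counts) == {"RRR", "RRW", "RWW", "WWW"}
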