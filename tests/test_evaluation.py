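"""Scoring metrics and paired statistics, each against an independent oracle."""

import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechrag.evaluation import (
    ItemResult,
    cliffs_delta,
    compare_runs,
    distribution_summary,
    exact_match,
    mcnemar_p,
    mean_diff_ci,
    net_gain,
    normalize_answer,
    paired_contingency,
    relative_increase,
    semantic_similarity,
    threshold_accuracy,
    wilcoxon_signed_rank,
)


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [(" TNF ", "tnf"), ('"IL6"', "il6"), ("'Abc'", "abc"), ("x", "x")],
    )
    def test_examples(self, raw, expected):
        assert normalize_answer(raw) == expected

    @settings(derandomize=True, max_examples=100)
    @given(st.text(max_size=50))
    def test_idempotent(self, text):
        once = normalize_answer(text)
        assert normalize_answer(once) == once

    def test_exact_match(self):
        assert exact_match("tnf", "TNF")
        assert not exact_match("TNFA", "TNF")
        assert not exact_match(None, "TNF")
        with pytest.raises(ValueError):
            exact_match("x", "")


class TestSemanticSimilarity:
    def test_identical_text_scores_one(self, embedder):
        assert semantic_similarity("glucose", "glucose", embedder) == pytest.approx(1.0)

    def test_absent_prediction_scores_zero(self, embedder):
        assert semantic_similarity(None, "glucose", embedder) == 0.0
        assert semantic_similarity("   ", "glucose", embedder) == 0.0

    def test_agrees_with_cosine_recomputation(self, embedder):
        from mechrag.selection import cosine_similarity

        got = semantic_similarity("lactate", "pyruvate", embedder)
        expected = cosine_similarity(embedder.embed("lactate"),
                                     embedder.embed("pyruvate"))
        assert got == pytest.approx(expected, abs=1e-12)


class TestThresholdAccuracy:
    def test_example(self):
        assert threshold_accuracy([0.95, 0.50, 0.91], 0.90) == (2, 66.7)

    def test_tau_zero_counts_all(self):
        assert threshold_accuracy([0.2, 0.4], 0.0) == (2, 100.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            threshold_accuracy([], 0.5)

    def test_matches_brute_force_and_monotone(self):
        rng = random.Random(5)
        scores = [rng.random() for _ in range(57)]
        previous = None
        for tau in [i / 20 for i in range(21)]:
            count, frac = threshold_accuracy(scores, tau)
            assert count == sum(1 for s in scores if s >= tau)
            assert frac == round(count / len(scores) * 100, 1)
            if previous is not None:
                assert count <= previous
            previous = count


class TestContingency:
    def test_enumeration(self):
        assert paired_contingency([True, False, True, False],
                                  [True, True, False, False]) == (1, 1, 1, 1)

    def test_identical_vectors_no_discordance(self):
        v = [True, False, True]
        a, b, c, d = paired_contingency(v, v)
        assert (b, c) == (0, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_contingency([True], [True, False])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), max_size=50))
    def test_conservation(self, pairs):
        base = [p[0] for p in pairs]
        treat = [p[1] for p in pairs]
        assert sum(paired_contingency(base, treat)) == len(pairs)


def mcnemar_exact_oracle(b, c):
    """Binomial-tail enumeration via math.comb, independent of scipy."""
    n = b + c
    if n == 0:
        return 1.0
    tail = sum(math.comb(n, k) for k in range(min(b, c) + 1)) / 2**n
    return min(1.0, 2 * tail)


class TestMcNemar:
    def test_symmetric_and_degenerate(self):
        assert mcnemar_p(5, 5, "exact") == pytest.approx(1.0)
        assert mcnemar_p(0, 0, "exact") == 1.0
        assert mcnemar_p(0, 0, "chi2") == 1.0

    def test_large_flip_asymmetry_is_extreme(self):
        p = mcnemar_p(245, 47, "exact")
        assert p < 1e-4
        assert p == pytest.approx(mcnemar_exact_oracle(245, 47), rel=1e-9)

    def test_exact_matches_enumeration_all_small_tables(self):
        for n in range(0, 21):
            for b in range(n + 1):
                c = n - b
                assert mcnemar_p(b, c, "exact") == pytest.approx(
                    mcnemar_exact_oracle(b, c), rel=1e-12
                ), (b, c)

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(3, 9), (10, 2), (7, 7), (245, 47)]:
            table = [[10, b], [c, 10]]
            assert mcnemar_p(b, c, "exact") == pytest.approx(
                float(sm_mcnemar(table, exact=True).pvalue), rel=1e-8
            )
            assert mcnemar_p(b, c, "chi2") == pytest.approx(
                float(sm_mcnemar(table, exact=False, correction=False).pvalue),
                rel=1e-8,
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_p(-1, 2)


class TestNetGain:
    @pytest.mark.parametrize(
        "b,c,n,expected",
        [(245, 47, 798, 24.8), (119, 49, 798, 8.8), (0, 0, 100, 0.0)],
    )
    def test_examples(self, b, c, n, expected):
        assert net_gain(b, c, n) == expected

    def test_equals_accuracy_difference(self):
        rng = random.Random(9)
        for _ in range(20):
            n = rng.randrange(2, 200)
            base = [rng.random() < 0.5 for _ in range(n)]
            treat = [rng.random() < 0.5 for _ in range(n)]
            a, b, c, d = paired_contingency(base, treat)
            acc_diff = ((a + b) / n - (a + c) / n) * 100
            assert net_gain(b, c, n) == pytest.approx(acc_diff, abs=0.051)

    def test_invalid(self):
        with pytest.raises(ValueError):
            net_gain(1, 1, 0)
        with pytest.raises(ValueError):
            net_gain(60, 60, 100)


class TestRelativeIncrease:
    @pytest.mark.parametrize(
        "before,after,expected", [(28, 51, 82), (30, 53, 77), (10, 10, 0)]
    )
    def test_reported_rounding(self, before, after, expected):
        assert round(relative_increase(before, after)) == expected

    def test_zero_before_rejected(self):
        with pytest.raises(ValueError):
            relative_increase(0, 5)


def wilcoxon_enum_oracle(diffs):
    """Exhaustive sign-flip enumeration (tie-free, zero-free diffs)."""
    diffs = [d for d in diffs if d != 0]
    n = len(diffs)
    ranks = {i: r + 1 for r, i in
             enumerate(sorted(range(n), key=lambda i: abs(diffs[i])))}
    w_obs = sum(ranks[i] for i in range(n) if diffs[i] > 0)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(ranks[i] for i in range(n) if signs[i]))
    le = sum(1 for w in ws if w <= w_obs) / len(ws)
    ge = sum(1 for w in ws if w >= w_obs) / len(ws)
    return min(1.0, 2 * min(le, ge))


class TestWilcoxon:
    def test_all_zero_diffs(self):
        assert wilcoxon_signed_rank([0.0, 0.0, 0.0]) == 1.0

    def test_three_positive_diffs_exact(self):
        assert wilcoxon_signed_rank([1.0, 2.0, 3.0]) == pytest.approx(0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([])

    def test_matches_sign_flip_enumeration(self):
        rng = random.Random(13)
        for _ in range(25):
            n = rng.randrange(3, 11)
            # distinct magnitudes, no zeros: the exact distribution applies
            magnitudes = rng.sample(range(1, 50), n)
            diffs = [m * rng.choice([-1, 1]) for m in magnitudes]
            assert wilcoxon_signed_rank(diffs) == pytest.approx(
                wilcoxon_enum_oracle(diffs), rel=1e-9
            ), diffs


def cliffs_oracle(x, y):
    gt = sum(1 for xi in x for yj in y if xi > yj)
    lt = sum(1 for xi in x for yj in y if xi < yj)
    return (gt - lt) / (len(x) * len(y))


class TestCliffsDelta:
    def test_dominance(self):
        d, lo, hi = cliffs_delta([5, 6, 7], [1, 2, 3])
        assert d == 1.0 and lo <= d <= hi and hi <= 1.0

    def test_identical_multisets(self):
        d, _, _ = cliffs_delta([1, 2, 2, 3], [3, 2, 1, 2])
        assert d == 0.0

    def test_matches_pair_counting_oracle(self):
        rng = random.Random(21)
        for _ in range(10):
            n, m = rng.randrange(2, 200), rng.randrange(2, 200)
            x = [rng.choice([rng.random(), 0.5]) for _ in range(n)]
            y = [rng.choice([rng.random(), 0.5]) for _ in range(m)]
            d, lo, hi = cliffs_delta(x, y)
            assert d == pytest.approx(cliffs_oracle(x, y), abs=1e-12)
            assert -1 <= lo <= d <= hi <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cliffs_delta([], [1])


class TestMeanDiffCI:
    def test_constant_diffs_degenerate_interval(self):
        mean, lo, hi = mean_diff_ci([0.3] * 10)
        assert mean == lo == hi == pytest.approx(0.3)

    def test_mean_is_arithmetic_mean(self):
        diffs = [0.1, -0.2, 0.4, 0.0]
        mean, lo, hi = mean_diff_ci(diffs, seed=3)
        assert mean == pytest.approx(sum(diffs) / len(diffs))
        assert lo <= mean <= hi

    def test_seeded_reproducibility(self):
        diffs = list(np.random.default_rng(0).normal(0.1, 0.2, 40))
        assert mean_diff_ci(diffs, seed=5) == mean_diff_ci(diffs, seed=5)

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            mean_diff_ci([0.1, 0.2], reps=10)


class TestDistributionSummary:
    def test_direct_binning(self):
        summary = distribution_summary([0.92, 0.93, 0.10], bin_width=0.05)
        counts = dict(zip(summary.bin_edges, summary.counts))
        assert counts[0.90] == 2
        assert counts[0.10] == 1

    def test_last_bin_right_closed(self):
        summary = distribution_summary([1.0], bin_width=0.05)
        assert summary.counts[-1] == 1

    def test_negative_scores_clamped_into_first_bin(self):
        summary = distribution_summary([-0.2, 0.01], bin_width=0.05)
        assert summary.counts[0] == 2 and summary.clamped_negative == 1

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=60))
    def test_conservation_and_sorting(self, scores):
        summary = distribution_summary(scores)
        assert sum(summary.counts) == len(scores)
        assert list(summary.sorted_scores) == sorted(scores)


def binary_results(vector, mode):
    return [ItemResult(f"i{k}", mode, correct=v) for k, v in enumerate(vector)]


def score_results(scores, mode):
    return [ItemResult(f"i{k}", mode, similarity=s) for k, s in enumerate(scores)]


class TestCompareRuns:
    def test_planted_flips(self):
        base = [True] * 360 + [False] * 245 + [True] * 47 + [False] * 146
        treat = [True] * 360 + [True] * 245 + [False] * 47 + [False] * 146
        report = compare_runs(binary_results(base, "llm_only"),
                              binary_results(treat, "rag"), "binary")
        b = report.binary
        assert (b.a, b.b, b.c, b.d) == (360, 245, 47, 146)
        assert b.net_gain_points == 24.8
        assert b.p_exact < 1e-4
        assert b.acc_treatment - b.acc_baseline == pytest.approx(
            b.net_gain_points, abs=0.11
        )

    def test_identical_runs(self):
        v = [True, False] * 10
        report = compare_runs(binary_results(v, "llm_only"),
                              binary_results(v, "rag"), "binary")
        assert report.binary.b == report.binary.c == 0
        assert report.binary.p_exact == 1.0
        assert report.binary.net_gain_points == 0.0

    def test_constant_shift_score_regime(self):
        rng = random.Random(31)
        base = [rng.uniform(0.1, 0.8) for _ in range(60)]
        treat = [s + 0.1 for s in base]
        report = compare_runs(score_results(base, "llm_only"),
                              score_results(treat, "rag"), "score",
                              bootstrap_reps=1000)
        s = report.score
        assert s.mean_diff == pytest.approx(0.1, abs=1e-12)
        assert s.cliffs_delta == pytest.approx(cliffs_oracle(treat, base), abs=1e-12)
        # every paired difference is positive, so the test is maximally extreme
        assert s.wilcoxon_p < 1e-9
        taus = [row.tau for row in report.thresholds.rows]
        assert taus == [0.85, 0.90, 0.95]
        # threshold counts non-increasing in tau
        for series in ("count_baseline", "count_treatment"):
            counts = [getattr(row, series) for row in report.thresholds.rows]
            assert counts == sorted(counts, reverse=True)
        assert sum(report.distribution_baseline.counts) == 60

    def test_item_mismatch_lists_difference(self):
        base = binary_results([True, False], "llm_only")
        treat = [ItemResult("other", "rag", correct=True),
                 ItemResult("i0", "rag", correct=True)]
        with pytest.raises(ValueError, match="other"):
            compare_runs(base, treat, "binary")
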