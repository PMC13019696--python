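"""Exam scoring, recall accuracy, retrieval metrics, and statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from treerag.evaluation import (
    MCQItem,
    RaterMatrix,
    RecallJudgment,
    bootstrap_ci,
    context_entity_recall,
    context_precision,
    context_recall,
    extract_choice,
    kendall_chi_square,
    kendall_w,
    mcnemar_test,
    paired_t_cohens_d,
    recall_accuracy,
    sample_round,
    score_exam,
    semantic_similarity,
)
from treerag.index import HashingEmbedder


def make_bank(n_factual, n_case):
    items = []
    for i in range(n_factual + n_case):
        items.append(
            MCQItem(
                item_id=f"q{i:04d}",
                stem=f"stem {i}",
                options={"A": "a", "B": "b", "C": "c", "D": "d"},
                answer_key="B",
                category="factual" if i < n_factual else "case_analysis",
            )
        )
    return items


def respond(items, n_factual_correct, n_case_correct):
    responses = {}
    f = c = 0
    for item in items:
        if item.category == "factual":
            ok = f < n_factual_correct
            f += 1
        else:
            ok = c < n_case_correct
            c += 1
        responses[item.item_id] = item.answer_key if ok else "zzz"
    return responses


class TestExtractChoice:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("The answer is C.", "C"),
            ("B) is right but A is wrong", "B"),
            ("no label present", None),
            ("CASE analysis mentions nothing standalone", None),
            ("answer: D", "D"),
        ],
    )
    def test_first_standalone_label(self, text, expected):
        assert extract_choice(text) == expected


class TestScoreExam:
    def test_licensing_round_arithmetic(self):
        """A 600-point round split 70/30: 324 factual + 130 case correct
        converts to 454 total and 75.67%."""
        items = make_bank(420, 180)
        result = score_exam(items, respond(items, 324, 130))
        assert (result.factual_score, result.case_score) == (324, 130)
        assert result.total_score == 454
        assert result.percentage == 75.67

    def test_second_round_arithmetic(self):
        items = make_bank(420, 180)
        result = score_exam(items, respond(items, 204, 95))
        assert result.total_score == 299
        assert result.percentage == 49.83

    def test_all_correct(self):
        items = make_bank(420, 180)
        result = score_exam(items, respond(items, 420, 180))
        assert result.percentage == 100.0

    def test_abstention_scores_zero(self):
        items = make_bank(2, 0)
        result = score_exam(items, {i.item_id: "no label here" for i in items})
        assert result.total_score == 0

    def test_missing_response_rejected(self):
        items = make_bank(2, 0)
        with pytest.raises(ValueError):
            score_exam(items, {items[0].item_id: "B"})


class TestSampleRound:
    def test_full_sample_is_permutation(self):
        bank = make_bank(7, 3)
        sampled = sample_round(bank, n=10, seed=5)
        assert sorted(i.item_id for i in sampled) == sorted(i.item_id for i in bank)

    def test_seed_reproducible(self):
        bank = make_bank(70, 30)
        assert sample_round(bank, 20, seed=9) == sample_round(bank, 20, seed=9)

    def test_kb_overlapping_items_excluded(self, small_kb):
        bank = make_bank(7, 3)
        leaked_stem = next(iter(small_kb.chunks.values())).text
        leaked = MCQItem("leak", leaked_stem, {"A": "a", "B": "b"}, "A", "factual")
        sampled = sample_round(bank + [leaked], n=10, seed=0, kb=small_kb)
        assert all(i.item_id != "leak" for i in sampled)
        with pytest.raises(ValueError):
            sample_round(bank + [leaked], n=11, seed=0, kb=small_kb)


class TestRecallAccuracy:
    def test_table_arithmetic(self):
        """10 raters x 10 items x 15 entries with a per-rater total of 57
        gives 57/150 = 0.38."""
        judgments = []
        for r in range(10):
            # spread 57 ones over this rater's 150 entry judgments
            flat = [1] * 57 + [0] * (150 - 57)
            for i in range(10):
                judgments.append(
                    RecallJudgment(f"r{r}", f"q{i}", tuple(flat[i * 15 : (i + 1) * 15]))
                )
        assert recall_accuracy(judgments) == pytest.approx(0.38)

    def test_extremes(self):
        ones = [RecallJudgment("r", "q", (1,) * 15)]
        zeros = [RecallJudgment("r", "q", (0,) * 15)]
        assert recall_accuracy(ones) == 1.0
        assert recall_accuracy(zeros) == 0.0

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ValueError):
            recall_accuracy(
                [RecallJudgment("r", "q", (1,)), RecallJudgment("r", "q2", (1, 0))]
            )


class TestContextMetrics:
    def test_precision_all_relevant(self):
        assert context_precision([1, 1, 1]) == 1.0

    def test_precision_ranks_1_and_3(self):
        assert context_precision([1, 0, 1]) == pytest.approx(5 / 6)

    def test_precision_none(self):
        assert context_precision([0, 0, 0]) == 0.0

    @given(labels=st.lists(st.integers(0, 1), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_precision_equals_average_precision_oracle(self, labels):
        """Cross-check against average precision computed from first principles."""
        hits, ap_terms = 0, []
        for k, rel in enumerate(labels, start=1):
            hits += rel
            if rel:
                ap_terms.append(hits / k)
        expected = sum(ap_terms) / len(ap_terms) if ap_terms else 0.0
        assert context_precision(labels) == pytest.approx(expected)

    def test_recall_full_and_partial_coverage(self):
        contexts = ["ginseng treats fatigue", "licorice soothes cough"]
        assert context_recall(contexts, ["ginseng treats fatigue"]) == 1.0
        assert context_recall(contexts, ["ginseng treats fatigue", "absent fact"]) == 0.5

    def test_entity_recall(self):
        contexts = ["ginseng and licorice appear here"]
        entities = ["ginseng", "licorice", "ephedra", "rhubarb"]
        assert context_entity_recall(contexts, entities) == 0.5

    def test_semantic_similarity_identity(self):
        emb = HashingEmbedder(dim=128)
        assert semantic_similarity("same words", "same words", emb) == pytest.approx(1.0)

    def test_proportions_in_unit_interval(self):
        assert 0.0 <= context_precision([0, 1, 0]) <= 1.0
        assert 0.0 <= context_recall(["a"], ["b"]) <= 1.0


class TestKendallW:
    def test_identical_rankings_give_w_one(self):
        ratings = np.tile(np.arange(1, 9, dtype=float), (5, 1))
        w, chi2, df, p = kendall_w(RaterMatrix(ratings))
        assert w == pytest.approx(1.0)
        assert df == 7
        assert p < 0.001

    def test_chi_square_identity_and_printed_row(self):
        """chi2 = m (n-1) W: at W = 0.4009, m = 10, n = 40 the statistic is
        156.35 with 39 df (matching the printed agreement table within
        rounding)."""
        chi2, df = kendall_chi_square(0.4009, 10, 40)
        assert df == 39
        assert chi2 == pytest.approx(156.35, abs=0.01)

    def test_single_rater_degenerate(self):
        w, chi2, df, _ = kendall_w(RaterMatrix(np.array([[3.0, 1.0, 2.0]])))
        assert w == 1.0 and df == 2

    def test_monotone_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        ratings = rng.integers(1, 6, size=(6, 12)).astype(float)
        w1, *_ = kendall_w(RaterMatrix(ratings))
        w2, *_ = kendall_w(RaterMatrix(ratings * 10 + 3))  # strictly increasing map
        assert w1 == pytest.approx(w2)

    @given(seed=st.integers(0, 999))
    @settings(max_examples=25, deadline=None)
    def test_chi_square_identity_holds_exactly(self, seed):
        rng = np.random.default_rng(seed)
        ratings = rng.integers(1, 6, size=(4, 7)).astype(float)
        w, chi2, df, _ = kendall_w(RaterMatrix(ratings))
        assert chi2 == pytest.approx(4 * 6 * w)
        assert df == 6
        assert 0.0 <= w <= 1.0


class TestMcNemar:
    def test_symmetric_discordance(self):
        a = [True] * 5 + [False] * 5
        b = [False] * 5 + [True] * 5
        stat, p = mcnemar_test(a, b)
        assert stat == 0.0  # continuity correction clipped at zero when b = c
        assert p == 1.0

    def test_hand_arithmetic_b10_c0(self):
        a = [True] * 10 + [True] * 5
        b = [False] * 10 + [True] * 5
        stat, p = mcnemar_test(a, b)
        assert stat == pytest.approx(8.1)
        assert p < 0.01

    def test_fully_concordant(self):
        assert mcnemar_test([True, False], [True, False]) == (0.0, 1.0)

    def test_large_sample_uses_chi_square(self):
        a = [True] * 30 + [False] * 10
        b = [False] * 30 + [True] * 10
        stat, p = mcnemar_test(a, b)
        assert p == pytest.approx(float(sps.chi2.sf(stat, 1)))


class TestPairedTAndBootstrap:
    def test_identical_samples_degenerate(self):
        res = paired_t_cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.d == 0.0

    def test_cohens_d_closed_form(self):
        a, b = [3.0, 5.0, 7.0], [2.0, 2.0, 4.0]  # diffs 1, 3, 3
        res = paired_t_cohens_d(a, b)
        diffs = np.array([1.0, 3.0, 3.0])
        sd = diffs.std(ddof=1)
        assert res.d == pytest.approx(diffs.mean() / sd)
        assert res.t == pytest.approx(diffs.mean() / (sd / np.sqrt(3)))

    def test_constant_data_bootstrap_degenerate(self):
        lo, hi = bootstrap_ci([4.0] * 10, n_resamples=200, seed=1)
        assert lo == hi == 4.0

    def test_bootstrap_seeded_and_brackets_mean(self):
        rng = np.random.default_rng(0)
        data = rng.normal(10, 2, size=50)
        ci1 = bootstrap_ci(data, n_resamples=2000, seed=11)
        ci2 = bootstrap_ci(data, n_resamples=2000, seed=11)
        assert ci1 == ci2
        assert ci1[0] < data.mean() < ci1[1]
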