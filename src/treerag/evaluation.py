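"""Exam scoring, retrieval-quality metrics, and the statistical toolkit.

Covers the evaluation machinery around the pipeline:

* multiple-choice exam rounds — choice extraction from free-text answers,
  per-category scoring (factual vs case-analysis), percentage conversion;
* expert recall judgments — recall accuracy as the averaged fraction of
  retrieved entries judged to contribute to answer correctness;
* retrieval-side quality metrics in the RAGAs family — context precision,
  context recall, context entity recall, semantic similarity. The
  LLM-judged members of that family (faithfulness, answer relevancy, answer
  correctness) are exposed only as a pluggable-judge hook with no offline
  definition;
* inter-rater agreement (Kendall's W with tie correction and its chi-square
  test), McNemar's test on paired correctness, paired t-test with Cohen's d,
  and seeded percentile bootstrap intervals.

Percentages are rounded half-up to 2 decimals; reproducing printed score
tables depends on that rounding rule.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Protocol, Sequence, Tuple

import numpy as np
from scipy import stats

from ._text import content_hash, normalize_ws, word_tokens
from .index import Embedder, cosine_similarity
from .kb import KnowledgeBase

__all__ = [
    "MCQItem",
    "ExamResult",
    "RecallJudgment",
    "RaterMatrix",
    "MetricReport",
    "extract_choice",
    "score_exam",
    "sample_round",
    "recall_accuracy",
    "context_precision",
    "context_recall",
    "context_entity_recall",
    "semantic_similarity",
    "kendall_w",
    "kendall_chi_square",
    "mcnemar_test",
    "paired_t_cohens_d",
    "bootstrap_ci",
    "load_question_bank",
    "save_question_bank",
]

CATEGORIES = ("factual", "case_analysis")


@dataclass(frozen=True)
class MCQItem:
    """One multiple-choice question worth one point."""

    item_id: str
    stem: str
    options: Mapping[str, str]  # label -> option text, labels "A".."E"
    answer_key: str
    category: str  # "factual" | "case_analysis"
    points: int = 1

    def __post_init__(self) -> None:
        if self.answer_key not in self.options:
            raise ValueError(
                f"answer key {self.answer_key!r} not among options "
                f"{sorted(self.options)} (item {self.item_id})"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class ExamResult:
    """Scored round: per-item correctness and per-category totals."""

    correctness: Dict[str, bool]
    factual_score: int
    case_score: int
    total_score: int
    total_points: int
    percentage: float


@dataclass(frozen=True)
class RecallJudgment:
    """One rater's 0/1 contribution scores over one item's retrieved entries."""

    rater_id: str
    item_id: str
    entry_scores: Tuple[int, ...]


@dataclass
class RaterMatrix:
    """Complete raters x items ordinal score matrix."""

    ratings: np.ndarray  # shape (m raters, n items)

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=np.float64)
        if self.ratings.ndim != 2:
            raise ValueError("ratings must be a 2-D raters x items array")
        if not np.all(np.isfinite(self.ratings)):
            raise ValueError("ratings matrix must be complete (no missing cells)")


MetricReport = Dict[str, float]


# -- choice extraction and exam scoring -----------------------------------


def extract_choice(
    answer_text: str, option_labels: Sequence[str] = ("A", "B", "C", "D", "E")
) -> Optional[str]:
    """First standalone option label in the answer text, or ``None`` (abstain).

    A label is standalone when it is not embedded in a longer alphanumeric
    run (``"B)"`` and ``"answer: C."`` match; the ``A`` in ``"CASE"`` does
    not). Abstention scores zero.
    """
    labels = "".join(re.escape(l) for l in option_labels)
    pattern = re.compile(rf"(?<![A-Za-z0-9])([{labels}])(?![A-Za-z0-9])")
    m = pattern.search(answer_text)
    return m.group(1) if m else None


def round_half_up(value: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def score_exam(items: Sequence[MCQItem], responses: Mapping[str, str]) -> ExamResult:
    """Score one response per item; free-text responses go through
    :func:`extract_choice`. Percentage = 100 x total / total points, rounded
    half-up to 2 decimals."""
    missing = [it.item_id for it in items if it.item_id not in responses]
    if missing:
        raise ValueError(f"missing responses for {len(missing)} items, e.g. {missing[:3]}")
    correctness: Dict[str, bool] = {}
    factual = case = 0
    total_points = 0
    for item in items:
        choice = extract_choice(responses[item.item_id], sorted(item.options))
        correct = choice == item.answer_key
        correctness[item.item_id] = correct
        total_points += item.points
        if correct:
            if item.category == "factual":
                factual += item.points
            else:
                case += item.points
    total = factual + case
    pct = round_half_up(100.0 * total / total_points) if total_points else 0.0
    return ExamResult(
        correctness=correctness,
        factual_score=factual,
        case_score=case,
        total_score=total,
        total_points=total_points,
        percentage=pct,
    )


def kb_text_hashes(kb: KnowledgeBase) -> frozenset:
    """Normalized-text hashes of every chunk — the leakage screen for rounds."""
    return frozenset(content_hash(normalize_ws(c.text)) for c in kb.chunks.values())


def sample_round(
    bank: Sequence[MCQItem],
    n: int = 600,
    seed: int = 0,
    kb: Optional[KnowledgeBase] = None,
) -> List[MCQItem]:
    """Uniform sample of *n* items without replacement, deterministic under seed.

    When a knowledge base is supplied, items whose stem text (normalized)
    hashes into the knowledge base's chunk texts are excluded before
    sampling, so test questions are verified absent from the knowledge base.
    """
    eligible = list(bank)
    if kb is not None:
        hashes = kb_text_hashes(kb)
        eligible = [
            it for it in eligible if content_hash(normalize_ws(it.stem)) not in hashes
        ]
    if n > len(eligible):
        raise ValueError(f"cannot sample {n} items from {len(eligible)} eligible")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in idx]


# -- recall accuracy -------------------------------------------------------


def recall_accuracy(judgments: Sequence[RecallJudgment]) -> float:
    """Averaged fraction of retrieved entries judged to contribute.

    Equals (sum of all 0/1 entry scores) / (judgments x entries-per-item),
    i.e. the per-rater total over items x entries, averaged across raters.
    All judgments must score the same number of entries.
    """
    if not judgments:
        raise ValueError("no judgments supplied")
    entries = {len(j.entry_scores) for j in judgments}
    if len(entries) != 1:
        raise ValueError(f"inconsistent entries per item: {sorted(entries)}")
    per_item = entries.pop()
    if per_item == 0:
        raise ValueError("judgments contain no entries")
    total = sum(sum(j.entry_scores) for j in judgments)
    return total / (len(judgments) * per_item)


# -- retrieval-side quality metrics ---------------------------------------


def context_precision(relevance_labels: Sequence[int]) -> float:
    """Rank-weighted precision of the retrieved context list.

    ``relevance_labels[i]`` is 1 when the context at rank i+1 is relevant.
    Returns the mean over relevant ranks k of (relevant in top-k)/k — average
    precision restricted to the retrieved list; 0.0 when nothing relevant was
    retrieved.
    """
    hits = 0
    precisions = []
    for k, rel in enumerate(relevance_labels, start=1):
        if rel:
            hits += 1
            precisions.append(hits / k)
    return float(np.mean(precisions)) if precisions else 0.0


def _covered(fact: str, context: str) -> bool:
    return set(word_tokens(fact)) <= set(word_tokens(context))


def context_recall(
    retrieved_contexts: Sequence[str], ground_truth_facts: Sequence[str]
) -> float:
    """Fraction of ground-truth fact strings lexically covered by the contexts.

    A fact is covered when every one of its word tokens occurs in at least
    one single retrieved context. Empty truth list yields 1.0 (nothing to
    recall).
    """
    if not ground_truth_facts:
        return 1.0
    covered = sum(
        1
        for fact in ground_truth_facts
        if any(_covered(fact, ctx) for ctx in retrieved_contexts)
    )
    return covered / len(ground_truth_facts)


def context_entity_recall(
    retrieved_contexts: Sequence[str], ground_truth_entities: Iterable[str]
) -> float:
    """|entities present in any context| / |ground-truth entities|."""
    truth = {e for e in ground_truth_entities}
    if not truth:
        return 1.0
    context_tokens = set()
    for ctx in retrieved_contexts:
        context_tokens |= set(word_tokens(ctx))
    present = {
        e for e in truth if set(word_tokens(e)) and set(word_tokens(e)) <= context_tokens
    }
    return len(present) / len(truth)


def semantic_similarity(answer: str, reference: str, embedder: Embedder) -> float:
    """Embedding cosine of answer vs reference, rescaled from [-1,1] to [0,1]."""
    cos = cosine_similarity(embedder.embed(answer), embedder.embed(reference))
    return (cos + 1.0) / 2.0


class AnswerJudge(Protocol):
    """Hook for LLM-judged generation metrics (faithfulness, answer relevancy,
    answer correctness). No offline default is provided; scores come from the
    plugged judge verbatim."""

    def score(self, metric: str, question: str, answer: str,
              contexts: Sequence[str], reference: str) -> float: ...


def judged_metrics(
    judge: AnswerJudge,
    question: str,
    answer: str,
    contexts: Sequence[str],
    reference: str,
    metrics: Sequence[str] = ("faithfulness", "answer_relevancy", "answer_correctness"),
) -> MetricReport:
    return {
        m: float(judge.score(m, question, answer, contexts, reference)) for m in metrics
    }


# -- agreement and hypothesis tests ---------------------------------------


def kendall_chi_square(w: float, m: int, n: int) -> Tuple[float, int]:
    """Chi-square statistic and df for Kendall's W: chi2 = m(n-1)W, df = n-1."""
    return m * (n - 1) * w, n - 1


def kendall_w(matrix: RaterMatrix) -> Tuple[float, float, int, float]:
    """Kendall's coefficient of concordance with mid-rank tie correction.

    Returns ``(W, chi_square, df, p_value)`` for m raters ranking n items:
    ``W = 12 S / (m^2 (n^3 - n) - m T)`` with S the sum of squared deviations
    of item rank sums and T the tie correction; ``chi2 = m (n-1) W``. A
    single rater is perfectly concordant with itself: W = 1 (degenerate).
    """
    ratings = matrix.ratings
    m, n = ratings.shape
    if n < 2:
        raise ValueError("need at least 2 items")
    if m == 1:
        chi2, df = kendall_chi_square(1.0, m, n)
        return 1.0, chi2, df, float(stats.chi2.sf(chi2, df))
    ranks = np.vstack([stats.rankdata(row) for row in ratings])
    rank_sums = ranks.sum(axis=0)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    tie_term = 0.0
    for row in ratings:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = m**2 * (n**3 - n) - m * tie_term
    w = 12.0 * s / denom if denom > 0 else 0.0
    chi2, df = kendall_chi_square(w, m, n)
    return w, chi2, df, float(stats.chi2.sf(chi2, df))


def mcnemar_test(
    correct_a: Sequence[bool], correct_b: Sequence[bool]
) -> Tuple[float, float]:
    """McNemar's test on paired per-item correctness.

    Uses the continuity-corrected chi-square statistic
    ``(|b - c| - 1)^2 / (b + c)`` on the discordant counts (clipped at 0 when
    b = c); the p-value switches to the exact two-sided binomial when
    ``b + c < 25``. Fully concordant pairs give (0, 1).
    """
    a = np.asarray(correct_a, dtype=bool)
    b_arr = np.asarray(correct_b, dtype=bool)
    if a.shape != b_arr.shape:
        raise ValueError("paired correctness vectors must have equal length")
    b = int(np.sum(a & ~b_arr))
    c = int(np.sum(~a & b_arr))
    if b + c == 0:
        return 0.0, 1.0
    stat = max(abs(b - c) - 1, 0) ** 2 / (b + c)
    if b + c < 25:
        p = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), b + c, 0.5)))
    else:
        p = float(stats.chi2.sf(stat, 1))
    return float(stat), p


@dataclass
class PairedComparison:
    t: float
    p: float
    d: float
    mean_diff: float
    degenerate: bool = False


def paired_t_cohens_d(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> PairedComparison:
    """Paired t-test on a - b plus paired Cohen's d = mean(diff)/sd(diff).

    Zero-variance differences (identical paired samples up to a constant
    shift of zero) make t undefined; the result is returned as t = 0, p = 1,
    d = 0 with the degenerate flag set.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    diff = a - b
    sd = float(np.std(diff, ddof=1)) if diff.size > 1 else 0.0
    if sd == 0.0:
        return PairedComparison(t=0.0, p=1.0, d=0.0, mean_diff=float(diff.mean()),
                                degenerate=True)
    t, p = stats.ttest_rel(a, b)
    d = float(diff.mean()) / sd
    return PairedComparison(t=float(t), p=float(p), d=d, mean_diff=float(diff.mean()))


def bootstrap_ci(
    values: Sequence[float],
    n_resamples: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> Tuple[float, float]:
    """Seeded percentile bootstrap interval for the mean.

    Resamples the scored units with replacement ``n_resamples`` times and
    returns the (1-level)/2 and 1-(1-level)/2 percentiles of the resampled
    means. Constant data collapses to a degenerate interval at the mean.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    means = rng.choice(arr, size=(n_resamples, arr.size), replace=True).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# -- question bank I/O -----------------------------------------------------


def load_question_bank(path) -> List[MCQItem]:
    """Read a JSONL question bank (item_id, stem, options, answer_key, category)."""
    items: List[MCQItem] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            items.append(
                MCQItem(
                    item_id=rec["item_id"],
                    stem=rec["stem"],
                    options=dict(rec["options"]),
                    answer_key=rec["answer_key"],
                    category=rec["category"],
                    points=int(rec.get("points", 1)),
                )
            )
    return items


def save_question_bank(items: Sequence[MCQItem], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for it in items:
            fh.write(
                json.dumps(
                    {
                        "item_id": it.item_id,
                        "stem": it.stem,
                        "options": dict(it.options),
                        "answer_key": it.answer_key,
                        "category": it.category,
                        "points": it.points,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
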