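"""Self-reflective generate--verify loop over the fused recall.

The loop wraps plain retrieval-augmented generation in four checks:

a. retrieve for the active question and *filter the recalled entries for
   relevance*, discarding what the relevance judge rejects;
b. if nothing relevant survives, *decompose* the question into sub-questions,
   retrieve and filter for each, and pool the survivors; otherwise generate a
   draft answer from the surviving evidence;
c. check the draft is *supported* by the evidence — if not, regenerate (up to
   the regeneration cap);
d. check the draft is *helpful* for the original question — if not,
   *reformulate* the question and restart from retrieval (up to the
   reformulation cap).

All caps are global across one run, so the loop always terminates: generator
calls never exceed ``1 + regen_cap + reform_cap``, and retrieval passes never
exceed ``(reform_cap + 1) * (1 + max sub-questions)``. Cap exhaustion is a
normal terminal state carrying the last draft as a best-effort answer.

With judges that approve everything, the loop reduces exactly to plain RAG
(one retrieval, one generation) — the ablation switch between the reflective
system and the plain SPO-T pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .backends import (
    ClarifyingReformulator,
    ConjunctionDecomposer,
    Decomposer,
    ExtractiveGenerator,
    Generator,
    Judge,
    LexicalJudge,
    Reformulator,
)
from .index import Embedder, KeywordIndex, VectorIndex
from .kb import KnowledgeBase
from .recall import (
    PromptTemplate,
    RecallResult,
    assemble_prompt,
    multi_way_recall,
)

__all__ = [
    "ReflectionCaps",
    "BackendSuite",
    "JudgeVerdict",
    "TraceEvent",
    "GenerationTrace",
    "ReflectionState",
    "assess_relevance",
    "decompose_question",
    "check_support",
    "check_helpfulness",
    "run_reflection_loop",
    "answer_plain_rag",
    "max_generator_calls",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReflectionCaps:
    """Iteration budgets. The source procedure bounds none of its loops
    explicitly ("multiple iterations"); these defaults keep cost bounded
    while allowing each repair path to fire more than once."""

    regen_cap: int = 3
    reform_cap: int = 2
    decomp_cap: int = 1


@dataclass
class BackendSuite:
    """The model-backed stages, defaulting to the deterministic offline set."""

    generator: Generator = field(default_factory=ExtractiveGenerator)
    relevance_judge: Judge = field(default_factory=LexicalJudge)
    support_judge: Judge = field(default_factory=LexicalJudge)
    helpfulness_judge: Judge = field(default_factory=LexicalJudge)
    decomposer: Decomposer = field(default_factory=ConjunctionDecomposer)
    reformulator: Reformulator = field(default_factory=ClarifyingReformulator)


@dataclass(frozen=True)
class JudgeVerdict:
    kind: str  # "relevance" | "support" | "helpfulness"
    subject_id: str
    verdict: bool
    rationale: str = ""


@dataclass(frozen=True)
class TraceEvent:
    step: str
    summary: str
    verdicts: Tuple[JudgeVerdict, ...] = ()


@dataclass
class GenerationTrace:
    """Replayable audit log of every branch decision taken by the loop."""

    events: List[TraceEvent] = field(default_factory=list)
    terminal_status: str = ""  # "answered" | "cap_exhausted"
    best_effort: bool = False

    def log(self, step: str, summary: str, verdicts: Sequence[JudgeVerdict] = ()) -> None:
        self.events.append(TraceEvent(step, summary, tuple(verdicts)))

    def branch_sequence(self) -> List[str]:
        return [e.step for e in self.events]


@dataclass
class ReflectionState:
    original_question: str
    active_question: str
    sub_questions: List[str] = field(default_factory=list)
    relevant_units: List[str] = field(default_factory=list)
    draft_answer: Optional[str] = None
    regen_count: int = 0
    reform_count: int = 0
    decomp_count: int = 0


def _safe_judge(judge: Judge, subject: str, context: str, kind: str, subject_id: str) -> JudgeVerdict:
    """Run a judge; any failure is a conservative negative verdict."""
    try:
        verdict = bool(judge.judge(subject, context))
        rationale = ""
    except Exception as exc:
        verdict = False
        rationale = f"judge failure treated as negative: {exc}"
        logger.warning("%s judge failed on %s: %s", kind, subject_id, exc)
    return JudgeVerdict(kind=kind, subject_id=subject_id, verdict=verdict, rationale=rationale)


def _unit_text(kb: KnowledgeBase, unit_id: str) -> str:
    unit = kb.units[unit_id]
    chunk = kb.chunks[unit.chunk_id]
    t = unit.triple
    return f"{t.subject} {t.predicate} {t.object}. {chunk.text}"


def assess_relevance(
    kb: KnowledgeBase, entries: RecallResult, question: str, judge: Judge
) -> Tuple[List[str], List[JudgeVerdict]]:
    """Keep exactly the recalled units with a positive relevance verdict,
    preserving fused order."""
    kept: List[str] = []
    verdicts: List[JudgeVerdict] = []
    for cand in entries.entries:
        v = _safe_judge(judge, question, _unit_text(kb, cand.unit_id), "relevance", cand.unit_id)
        verdicts.append(v)
        if v.verdict:
            kept.append(cand.unit_id)
    return kept, verdicts


def decompose_question(question: str, decomposer: Decomposer) -> List[str]:
    """Split a question into >= 0 sub-questions (empty means the decomposition
    path yields nothing and the loop falls through to reformulation)."""
    subs = [s for s in decomposer.decompose(question) if s.strip()]
    return subs


def check_support(
    draft: str, evidence_texts: Sequence[str], judge: Judge
) -> JudgeVerdict:
    """Is the draft grounded in the surviving evidence?"""
    context = "\n".join(evidence_texts)
    return _safe_judge(judge, draft, context, "support", "draft")


def check_helpfulness(draft: str, original_question: str, judge: Judge) -> JudgeVerdict:
    """Does the draft actually address the original question?"""
    return _safe_judge(judge, original_question, draft, "helpfulness", "draft")


def max_generator_calls(caps: ReflectionCaps) -> int:
    """Closed-form bound on generator invocations for any judge behavior."""
    return 1 + caps.regen_cap + caps.reform_cap


def _generate(
    generator: Generator, prompt: str, evidence: Sequence[str]
) -> str:
    try:
        return generator.generate(prompt, evidence)
    except Exception:
        logger.warning("generator failed; retrying once")
        try:
            return generator.generate(prompt, evidence)
        except Exception as exc:
            raise RuntimeError("generator failed twice") from exc


def run_reflection_loop(
    question: str,
    kb: KnowledgeBase,
    keyword_index: KeywordIndex,
    vector_index: VectorIndex,
    embedder: Embedder,
    backends: Optional[BackendSuite] = None,
    caps: Optional[ReflectionCaps] = None,
    template: Optional[PromptTemplate] = None,
    keyword_quota: int = 5,
    vector_quota: int = 10,
) -> Tuple[Optional[str], GenerationTrace]:
    """Run the full reflective loop; always terminates within the caps.

    Returns the final answer (``None`` only when the loop exhausted its caps
    without ever producing a draft) and the complete trace. Cap exhaustion is
    not an error: ``terminal_status`` is ``"cap_exhausted"`` and the last
    draft, if any, is flagged best-effort.
    """
    backends = backends or BackendSuite()
    caps = caps or ReflectionCaps()
    state = ReflectionState(original_question=question, active_question=question)
    trace = GenerationTrace()

    def recall_and_filter(q: str) -> Tuple[List[str], RecallResult]:
        result = multi_way_recall(
            kb, keyword_index, vector_index, q, embedder,
            keyword_quota=keyword_quota, vector_quota=vector_quota,
        )
        kept, verdicts = assess_relevance(kb, result, state.original_question,
                                          backends.relevance_judge)
        trace.log(
            "retrieve+filter",
            f"question={q!r} recalled={len(result.entries)} kept={len(kept)}",
            verdicts,
        )
        return kept, result

    while True:
        relevant, _result = recall_and_filter(state.active_question)
        state.relevant_units = relevant

        if not state.relevant_units and state.decomp_count < caps.decomp_cap:
            state.decomp_count += 1
            subs = decompose_question(state.active_question, backends.decomposer)
            state.sub_questions = subs
            trace.log("decompose", f"{len(subs)} sub-questions")
            pooled: List[str] = []
            for sub in subs:
                kept, _ = recall_and_filter(sub)
                for uid in kept:
                    if uid not in pooled:
                        pooled.append(uid)
            state.relevant_units = pooled

        if not state.relevant_units:
            if state.reform_count < caps.reform_cap:
                state.reform_count += 1
                state.active_question = backends.reformulator.reformulate(
                    state.active_question
                )
                trace.log("reformulate", f"empty evidence; reform #{state.reform_count}")
                continue
            trace.log("terminate", "caps exhausted with no relevant evidence")
            trace.terminal_status = "cap_exhausted"
            trace.best_effort = state.draft_answer is not None
            return state.draft_answer, trace

        evidence = [_unit_text(kb, uid) for uid in state.relevant_units]
        fused = RecallResult(
            entries=[c for c in _result.entries if c.unit_id in state.relevant_units],
            quota_used=_result.quota_used,
        )
        prompt = assemble_prompt(kb, fused, state.active_question, template)
        state.draft_answer = _generate(backends.generator, prompt.text, evidence)
        trace.log("generate", f"draft of {len(state.draft_answer)} chars")

        supported = check_support(state.draft_answer, evidence, backends.support_judge)
        trace.log("check_support", str(supported.verdict), [supported])
        while not supported.verdict and state.regen_count < caps.regen_cap:
            state.regen_count += 1
            state.draft_answer = _generate(backends.generator, prompt.text, evidence)
            trace.log("regenerate", f"regen #{state.regen_count}")
            supported = check_support(
                state.draft_answer, evidence, backends.support_judge
            )
            trace.log("check_support", str(supported.verdict), [supported])

        if supported.verdict:
            helpful = check_helpfulness(
                state.draft_answer, state.original_question, backends.helpfulness_judge
            )
            trace.log("check_helpfulness", str(helpful.verdict), [helpful])
            if helpful.verdict:
                trace.log("terminate", "answered")
                trace.terminal_status = "answered"
                return state.draft_answer, trace

        # unsupported after regen budget, or unhelpful: reformulate if possible
        if state.reform_count < caps.reform_cap:
            state.reform_count += 1
            state.active_question = backends.reformulator.reformulate(
                state.active_question
            )
            trace.log("reformulate", f"reform #{state.reform_count}")
            continue
        trace.log("terminate", "caps exhausted; best-effort draft")
        trace.terminal_status = "cap_exhausted"
        trace.best_effort = True
        return state.draft_answer, trace


def answer_plain_rag(
    question: str,
    kb: KnowledgeBase,
    keyword_index: KeywordIndex,
    vector_index: VectorIndex,
    embedder: Embedder,
    generator: Optional[Generator] = None,
    template: Optional[PromptTemplate] = None,
    keyword_quota: int = 5,
    vector_quota: int = 10,
) -> Tuple[str, RecallResult]:
    """Plain retrieval-augmented generation: one recall, one generation.

    This is the reflection-disabled ablation; with all-approve judges the
    reflective loop produces exactly this answer.
    """
    generator = generator or ExtractiveGenerator()
    result = multi_way_recall(
        kb, keyword_index, vector_index, question, embedder,
        keyword_quota=keyword_quota, vector_quota=vector_quota,
    )
    prompt = assemble_prompt(kb, result, question, template)
    evidence = [_unit_text(kb, uid) for uid in result.unit_ids()]
    answer = generator.generate(prompt.text, evidence)
    return answer, result
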