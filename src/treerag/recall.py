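"""Dual-path recall with fixed fusion quotas, and prompt assembly.

Retrieval runs two ways for every question: keyword matching over SPO
triples and cosine similarity over embedded text. The fused candidate list
takes up to ``keyword_quota`` (default 5) keyword hits and fills with vector
hits until it holds ``keyword_quota + vector_quota`` entries (default 15).
A keyword deficit is backfilled from the vector path; the reverse direction
is not compensated. Keyword entries precede vector entries in the prompt —
the structured SPO hits act as importance hints for the attached text.

A unit indexed under several content kinds (chunk / summary / qa) scores as
the maximum over its kinds, i.e. its best-ranked appearance in the k-NN list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Protocol, Tuple

from ._text import word_count
from .index import Embedder, KeywordIndex, VectorIndex, keyword_match, knn_search
from .kb import KnowledgeBase

__all__ = [
    "RecallCandidate",
    "RecallResult",
    "PromptTemplate",
    "PromptBundle",
    "TemplateError",
    "DEFAULT_TEMPLATE",
    "multi_way_recall",
    "assemble_prompt",
    "count_tokens",
]


@dataclass(frozen=True)
class RecallCandidate:
    """One retrieval hit, tagged with the path that produced it."""

    unit_id: str
    source: str  # "keyword" | "vector"
    score: float
    rank: int  # 1-based rank within its source list


@dataclass
class RecallResult:
    """The fused candidate list in final prompt order."""

    entries: List[RecallCandidate] = field(default_factory=list)
    quota_used: Tuple[int, int] = (0, 0)  # (n_keyword, n_vector)

    def unit_ids(self) -> List[str]:
        return [e.unit_id for e in self.entries]


def multi_way_recall(
    kb: KnowledgeBase,
    keyword_index: KeywordIndex,
    vector_index: VectorIndex,
    query_text: str,
    embedder: Embedder,
    keyword_quota: int = 5,
    vector_quota: int = 10,
) -> RecallResult:
    """Fuse keyword and vector recall under the fixed quota with backfill.

    Up to ``keyword_quota`` keyword hits are taken first (source rank order);
    vector hits then fill the list — skipping unit ids already taken — until
    it reaches ``keyword_quota + vector_quota`` entries or candidates run
    out. Fewer keyword hits than the quota simply leave more room for the
    vector path; a short vector list never pulls extra keyword hits.
    """
    total_quota = keyword_quota + vector_quota
    entries: List[RecallCandidate] = []
    taken: set = set()

    for rank, (unit_id, score) in enumerate(
        keyword_match(keyword_index, query_text, limit=keyword_quota), start=1
    ):
        entries.append(RecallCandidate(unit_id, "keyword", float(score), rank))
        taken.add(unit_id)
    n_keyword = len(entries)

    n_vector = 0
    if len(vector_index) and query_text.strip():
        query_vec = embedder.embed(query_text)
        # over-fetch: several kinds may collapse onto one unit, and keyword
        # picks must be skipped
        hits = knn_search(vector_index, query_vec, k=len(vector_index))
        best: Dict[str, Tuple[float, int]] = {}
        order: List[str] = []
        for pos, (unit_id, _kind, sim) in enumerate(hits):
            if unit_id not in best:  # hits are sorted, first occurrence = max kind
                best[unit_id] = (sim, pos)
                order.append(unit_id)
        rank = 0
        for unit_id in order:
            if len(entries) >= total_quota:
                break
            rank += 1
            if unit_id in taken:
                continue
            entries.append(
                RecallCandidate(unit_id, "vector", best[unit_id][0], rank)
            )
            taken.add(unit_id)
            n_vector += 1

    return RecallResult(entries=entries, quota_used=(n_keyword, n_vector))


# -- prompt assembly ------------------------------------------------------


class TemplateError(ValueError):
    """The prompt template is missing a required placeholder."""


REQUIRED_PLACEHOLDERS = ("{role}", "{task}", "{knowledge}", "{question}")

#: Default prompt template; override via a plain-text file with the same
#: placeholders. The exact text is documented in ``docs/formats.md``.
DEFAULT_TEMPLATE = """\
{role}

{task}

Knowledge base content (each entry: triple | context path | source text):
{knowledge}

Question:
{question}
"""

DEFAULT_ROLE = (
    "You are a careful domain assistant answering from the supplied knowledge base."
)
DEFAULT_TASK = (
    "Answer the question using only the knowledge entries below. The "
    "structured (subject, predicate, object) triples signal which entries "
    "matter most. Cite no outside knowledge."
)

EMPTY_KNOWLEDGE_MARKER = "(no knowledge entries retrieved)"


@dataclass(frozen=True)
class PromptTemplate:
    """Prompt skeleton with {role}, {task}, {knowledge}, {question} slots."""

    text: str = DEFAULT_TEMPLATE
    role: str = DEFAULT_ROLE
    task: str = DEFAULT_TASK

    def __post_init__(self) -> None:
        missing = [p for p in REQUIRED_PLACEHOLDERS if p not in self.text]
        if missing:
            raise TemplateError(f"template missing placeholders: {missing}")


@dataclass
class PromptBundle:
    """A fully rendered prompt plus its token estimate."""

    system_text: str
    knowledge_block: str
    question_text: str
    token_estimate: int

    @property
    def text(self) -> str:
        return self.system_text


class TokenCounter(Protocol):
    def count(self, text: str) -> int: ...


def count_tokens(text: str, counter: Optional[TokenCounter] = None) -> int:
    """Token count under a pluggable counter; default = package word rule."""
    if counter is not None:
        return counter.count(text)
    return word_count(text)


def render_entry(kb: KnowledgeBase, candidate: RecallCandidate, position: int) -> str:
    unit = kb.units[candidate.unit_id]
    path = " > ".join(kb.get_context_path(candidate.unit_id))
    chunk = kb.chunks[unit.chunk_id]
    t = unit.triple
    return (
        f"[{position}] ({t.subject}, {t.predicate}, {t.object}) | {path} | "
        f"{chunk.text}"
    )


def assemble_prompt(
    kb: KnowledgeBase,
    result: RecallResult,
    question_text: str,
    template: Optional[PromptTemplate] = None,
) -> PromptBundle:
    """Render the fused recall into the prompt template, deterministically.

    Each entry shows its triple, its root-to-leaf context path, and the
    attached chunk text, in fused order. An empty recall renders an explicit
    empty-knowledge marker. The same template is used for every backend.
    """
    template = template or PromptTemplate()
    if result.entries:
        knowledge = "\n".join(
            render_entry(kb, cand, i) for i, cand in enumerate(result.entries, start=1)
        )
    else:
        knowledge = EMPTY_KNOWLEDGE_MARKER
    system_text = template.text.format(
        role=template.role,
        task=template.task,
        knowledge=knowledge,
        question=question_text,
    )
    return PromptBundle(
        system_text=system_text,
        knowledge_block=knowledge,
        question_text=question_text,
        token_estimate=count_tokens(system_text),
    )
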