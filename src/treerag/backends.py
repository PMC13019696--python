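"""Pluggable model backends and their deterministic offline defaults.

Every stage that the production system delegates to a language model —
answer generation, relevance/support/helpfulness judging, question
decomposition, question reformulation — is a small text-in/text-out (or
boolean-out) interface. The defaults shipped here are deterministic lexical
heuristics so the full pipeline runs and is testable offline; LLM adapters
implement the same protocols against a remote service.

Adapter response grammar (documented for remote implementations):

* Generators return plain answer text.
* Judges must answer with a line starting ``YES`` or ``NO`` (case
  insensitive); anything else parses as a failure, and failures count as a
  negative verdict (fail-safe).
* Decomposers return one sub-question per line.
* Reformulators return the rewritten question as plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Protocol, Sequence

from ._text import word_tokens

__all__ = [
    "Generator",
    "Judge",
    "Decomposer",
    "Reformulator",
    "ExtractiveGenerator",
    "LexicalJudge",
    "ConjunctionDecomposer",
    "ClarifyingReformulator",
    "ScriptedJudge",
    "StaticGenerator",
    "parse_judge_reply",
]


class Generator(Protocol):
    """Produce an answer from a rendered prompt and the evidence texts."""

    def generate(self, prompt: str, evidence_texts: Sequence[str]) -> str: ...


class Judge(Protocol):
    """Binary verdict on (subject_text, context_text)."""

    def judge(self, subject_text: str, context_text: str) -> bool: ...


class Decomposer(Protocol):
    def decompose(self, question: str) -> List[str]: ...


class Reformulator(Protocol):
    def reformulate(self, question: str) -> str: ...


def parse_judge_reply(reply: str) -> bool:
    """Parse a YES/NO adapter reply; unparseable replies raise ValueError."""
    head = reply.strip().split(None, 1)[0].upper().rstrip(".,:;") if reply.strip() else ""
    if head == "YES":
        return True
    if head == "NO":
        return False
    raise ValueError(f"judge reply not YES/NO: {reply[:40]!r}")


def _overlap(a: str, b: str) -> float:
    """Fraction of a's distinct word tokens present in b."""
    at = set(word_tokens(a))
    if not at:
        return 0.0
    return len(at & set(word_tokens(b))) / len(at)


@dataclass
class LexicalJudge:
    """Deterministic judge: positive iff token overlap reaches a threshold.

    The overlap is the fraction of the subject text's distinct word tokens
    that also occur in the context text. Default threshold 0.2 — low on
    purpose: judges gate the reflective loop, and the offline heuristic
    should only reject clearly unrelated pairs.
    """

    threshold: float = 0.2

    def judge(self, subject_text: str, context_text: str) -> bool:
        return _overlap(subject_text, context_text) >= self.threshold


@dataclass
class ExtractiveGenerator:
    """Deterministic generator: answer with the best-overlapping evidence text.

    Scores each evidence text by token overlap with the prompt's question
    line and returns the highest-scoring one verbatim (ties to the earliest),
    so the answer is always supported by the evidence it came from.
    """

    def generate(self, prompt: str, evidence_texts: Sequence[str]) -> str:
        if not evidence_texts:
            return "No supporting knowledge was retrieved."
        question = prompt.rsplit("Question:", 1)[-1]
        scores = [_overlap(text, question) + _overlap(question, text) for text in evidence_texts]
        best = max(range(len(scores)), key=lambda i: (scores[i], -i))
        return evidence_texts[best]


@dataclass
class ConjunctionDecomposer:
    """Deterministic decomposer: split a compound question on ' and '."""

    def decompose(self, question: str) -> List[str]:
        parts = [p.strip(" ?") for p in question.split(" and ")]
        subs = [p + "?" for p in parts if p]
        return subs or [question]


@dataclass
class ClarifyingReformulator:
    """Deterministic reformulator: append a standing clarifier to the question."""

    clarifier: str = "Answer with the key terms involved."

    def reformulate(self, question: str) -> str:
        return f"{question.rstrip()} {self.clarifier}"


# -- scripted test doubles -------------------------------------------------


@dataclass
class ScriptedJudge:
    """Judge returning a scripted sequence of verdicts (repeating the last),
    or delegating to an arbitrary function of the call index."""

    verdicts: Sequence[bool] = (True,)
    fn: Optional[Callable[[int], bool]] = None
    calls: int = field(default=0)

    def judge(self, subject_text: str, context_text: str) -> bool:
        i = self.calls
        self.calls += 1
        if self.fn is not None:
            return self.fn(i)
        return self.verdicts[min(i, len(self.verdicts) - 1)]


@dataclass
class StaticGenerator:
    """Generator returning fixed text (or echoing the first evidence)."""

    text: Optional[str] = None
    calls: int = field(default=0)

    def generate(self, prompt: str, evidence_texts: Sequence[str]) -> str:
        self.calls += 1
        if self.text is not None:
            return self.text
        return evidence_texts[0] if evidence_texts else ""
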