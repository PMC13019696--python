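"""Seeded synthetic corpora, question banks, and rater matrices.

The generator emulates the structure of a multi-book textbook corpus: each
book splits into chapters and each chapter into knowledge points; every
knowledge point owns a distinct vocabulary cluster so that an ideal (or even
a bag-of-tokens) embedder separates points cleanly. A configurable fraction
of knowledge points *cross-links* to a point in another chapter, sharing
some of that point's cluster tokens — the minimal structure on which
cross-chapter reasoning can be exercised. Each point also carries one
planted relation sentence (``<label> treats <entity>.``) whose object is the
ground-truth answer entity for factual questions.

What this emulates — and what it does not: the hierarchy, the topical
locality of vocabulary, planted relations, and answerable questions. It does
not imitate real prose, real exam difficulty, or noisy OCR text; passing
tests on it demonstrates the mechanics of the pipeline, not domain accuracy.

All randomness flows through ``numpy.random.default_rng(seed)`` with
integer draws only, so output is byte-identical across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .evaluation import MCQItem
from .ingest import SourceDocument, parse_document, segment_chunks
from .kb import INCLUDE, KnowledgeBase, build_tree, populate_units

__all__ = [
    "CorpusSpec",
    "PlantedQuestion",
    "PlantedTruth",
    "OracleClusterEmbedder",
    "generate_corpus",
    "build_synthetic_kb",
    "generate_mcq",
    "generate_rater_matrix",
]

OPTION_LABELS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class CorpusSpec:
    """Shape and scale of a synthetic corpus.

    ``words_per_point`` is the approximate word budget of each knowledge
    point's text; ``cross_link_rate`` is the fraction of knowledge points
    that reference a point in another chapter.
    """

    n_books: int = 2
    chapters_per_book: int = 3
    points_per_chapter: int = 4
    words_per_point: int = 250
    vocabulary_size: int = 2000
    cross_link_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_books", "chapters_per_book", "points_per_chapter",
                     "words_per_point", "vocabulary_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.cross_link_rate <= 1.0:
            raise ValueError("cross_link_rate must be in [0, 1]")


@dataclass(frozen=True)
class PlantedQuestion:
    """Ground truth for one generated question."""

    item_id: str
    planted_unit_ids: Tuple[str, ...]  # units whose text entails the answer
    entities: Tuple[str, ...]
    distractor_unit_ids: Tuple[str, ...]
    fact: str  # the planted sentence answering the question


@dataclass
class PlantedTruth:
    by_item: Dict[str, PlantedQuestion] = field(default_factory=dict)


@dataclass
class _Point:
    book: int
    chapter: int
    point: int
    label: str
    cluster: Tuple[str, ...]
    entity: str  # object of the planted relation sentence
    linked_to: Optional[Tuple[int, int, int]] = None  # (book, chapter, point)


CLUSTER_WORDS = 14  # exclusive vocabulary words per knowledge point
SHARED_LINK_WORDS = 4  # cluster words echoed into a cross-linking point


def _point_key(b: int, c: int, p: int) -> Tuple[int, int, int]:
    return (b, c, p)


def _plan_points(spec: CorpusSpec, rng: np.random.Generator) -> Dict[Tuple[int, int, int], _Point]:
    vocab = [f"w{i:05d}" for i in range(spec.vocabulary_size)]
    n_points = spec.n_books * spec.chapters_per_book * spec.points_per_chapter
    needed = n_points * (CLUSTER_WORDS + 1)
    if needed > spec.vocabulary_size:
        raise ValueError(
            f"vocabulary_size {spec.vocabulary_size} too small for "
            f"{n_points} points ({needed} words needed)"
        )
    perm = rng.permutation(spec.vocabulary_size)
    points: Dict[Tuple[int, int, int], _Point] = {}
    cursor = 0
    for b in range(spec.n_books):
        for c in range(spec.chapters_per_book):
            for p in range(spec.points_per_chapter):
                cluster = tuple(
                    vocab[perm[cursor + i]] for i in range(CLUSTER_WORDS)
                )
                entity = vocab[perm[cursor + CLUSTER_WORDS]]
                cursor += CLUSTER_WORDS + 1
                label = f"Point {b + 1}.{c + 1}.{p + 1}"
                points[_point_key(b, c, p)] = _Point(
                    book=b, chapter=c, point=p, label=label,
                    cluster=cluster, entity=entity,
                )
    # plant cross-chapter links
    keys = sorted(points)
    n_links = int(round(spec.cross_link_rate * len(keys)))
    if n_links and len(keys) > 1:
        chosen = rng.choice(len(keys), size=n_links, replace=False)
        for idx in sorted(int(i) for i in chosen):
            src = points[keys[idx]]
            others = [
                k for k in keys if (k[0], k[1]) != (src.book, src.chapter)
            ]
            if not others:
                continue
            target = others[int(rng.integers(len(others)))]
            src.linked_to = target
    return points


def _point_text(
    point: _Point,
    points: Dict[Tuple[int, int, int], _Point],
    spec: CorpusSpec,
    rng: np.random.Generator,
) -> str:
    """Pseudo-prose paragraphs drawn from the point's cluster vocabulary."""
    words: List[str] = []
    budget = spec.words_per_point
    planted = f"{point.label} treats {point.entity}."
    link_sentence = ""
    if point.linked_to is not None:
        other = points[point.linked_to]
        shared = " ".join(other.cluster[:SHARED_LINK_WORDS])
        link_sentence = (
            f"This topic belongs to {other.label} and shares {shared}."
        )
    reserved = len(planted.split()) + len(link_sentence.split())
    while len(words) < max(budget - reserved, 0):
        n = int(rng.integers(6, 12))
        sentence = [
            point.cluster[int(rng.integers(len(point.cluster)))] for _ in range(n)
        ]
        words.extend(sentence)
        words[-1] += "."
    body = " ".join(words)
    paragraphs = [planted]
    if link_sentence:
        paragraphs.append(link_sentence)
    # split the body into a few paragraphs for realistic chunk packing
    toks = body.split()
    third = max(-(-len(toks) // 3), 1)  # ceil: avoids a tiny trailing paragraph
    for i in range(0, len(toks), third):
        paragraphs.append(" ".join(toks[i : i + third]))
    return "\n\n".join(paragraphs)


def generate_corpus(spec: CorpusSpec) -> Tuple[List[SourceDocument], Dict[Tuple[int, int, int], "_Point"]]:
    """Generate the raw documents (and the internal point plan) for a spec.

    Deterministic under ``spec.seed``. Returns one parsed document per book;
    the point plan maps (book, chapter, point) to labels, vocabulary
    clusters, planted entities and cross-links, and is consumed by
    :func:`generate_mcq`.
    """
    rng = np.random.default_rng(spec.seed)
    points = _plan_points(spec, rng)
    docs: List[SourceDocument] = []
    for b in range(spec.n_books):
        lines = [f"# Book {b + 1}", ""]
        for c in range(spec.chapters_per_book):
            lines += [f"## Chapter {b + 1}.{c + 1}", ""]
            for p in range(spec.points_per_chapter):
                point = points[_point_key(b, c, p)]
                lines += [f"### {point.label}", "", _point_text(point, points, spec, rng), ""]
        docs.append(parse_document("\n".join(lines), doc_id=f"book{b + 1}"))
    return docs, points


def build_synthetic_kb(
    spec: CorpusSpec,
    min_words: int = 200,
    max_words: int = 300,
) -> Tuple[KnowledgeBase, Dict[Tuple[int, int, int], "_Point"]]:
    """Generate a corpus and run the full ingestion pipeline over it."""
    docs, points = generate_corpus(spec)
    kb = KnowledgeBase()
    for doc in docs:
        chunks = segment_chunks(doc, min_words=min_words, max_words=max_words)
        kb.merge(build_tree(doc, chunks))
    populate_units(kb)
    kb.validate()
    return kb, points


def _units_for_label(kb: KnowledgeBase, label: str) -> List[str]:
    """All units bound to the knowledge point's chunks (include + relations)."""
    return sorted(
        uid for uid, unit in kb.units.items() if unit.triple.subject == label
    )


class OracleClusterEmbedder:
    """Ideal embedder for synthetic corpora: one dimension per knowledge point.

    Every token of a point's vocabulary cluster (and its planted entity) maps
    to that point's dimension; tokens outside all clusters are ignored.
    Vectors are cluster-hit counts, L2-normalized. This is the embedder under
    which planted-unit retrievability is guaranteed by construction: a
    question phrased in a point's cluster vocabulary is collinear with that
    point's text and orthogonal to unrelated points.
    """

    def __init__(self, points: Dict[Tuple[int, int, int], "_Point"]) -> None:
        keys = sorted(points)
        self.dim = len(keys)
        self._token_to_dim: Dict[str, int] = {}
        for i, key in enumerate(keys):
            pt = points[key]
            for tok in pt.cluster:
                self._token_to_dim[tok] = i
            self._token_to_dim[pt.entity] = i

    def embed(self, text: str) -> np.ndarray:
        if not text or not text.strip():
            raise ValueError("cannot embed empty text")
        vec = np.zeros(self.dim, dtype=np.float64)
        for tok in text.split():
            dim = self._token_to_dim.get(tok.strip(".,!?").lower())
            if dim is not None:
                vec[dim] += 1.0
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        return vec


def generate_mcq(
    kb: KnowledgeBase,
    points: Dict[Tuple[int, int, int], "_Point"],
    n_items: int,
    factual_fraction: float = 0.7,
    seed: int = 0,
) -> Tuple[List[MCQItem], PlantedTruth]:
    """Generate a question bank whose answers are pinned to planted units.

    ``round(n_items * factual_fraction)`` items (half-up) are factual — they
    ask for the entity a knowledge point treats, phrased in that point's
    cluster vocabulary. The remainder are case-analysis items spanning
    exactly two cross-linked points: the stem mixes both clusters and the
    answer is the linked point's entity. Options carry three distractor
    entities from sibling points. Raises if case items are requested but the
    corpus has no cross-links.
    """
    rng = np.random.default_rng(seed)
    keys = sorted(points)
    n_factual = int(np.floor(n_items * factual_fraction + 0.5))
    n_case = n_items - n_factual
    linked = [k for k in keys if points[k].linked_to is not None]
    if n_case > 0 and not linked:
        raise ValueError("case-analysis items need cross-linked points "
                         "(cross_link_rate was 0)")
    bank: List[MCQItem] = []
    truth = PlantedTruth()

    def distractor_entities(exclude: Sequence[str], k: int = 3) -> List[str]:
        pool = [points[key].entity for key in keys if points[key].entity not in exclude]
        idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        return [pool[int(i)] for i in idx]

    def make_item(i: int, category: str) -> None:
        if category == "factual":
            key = keys[int(rng.integers(len(keys)))]
            pt = points[key]
            context = " ".join(pt.cluster[:6])
            stem = (
                f"In the setting of {context}, which entity does "
                f"{pt.label} treat?"
            )
            answer_entity = pt.entity
            planted_labels = [pt.label]
            fact = f"{pt.label} treats {pt.entity}."
        else:
            key = linked[int(rng.integers(len(linked)))]
            pt = points[key]
            other = points[pt.linked_to]
            context = " ".join(pt.cluster[:4] + other.cluster[:4])
            stem = (
                f"A case presents with {context}. Considering that "
                f"{pt.label} belongs to {other.label}, which entity does "
                f"{other.label} treat?"
            )
            answer_entity = other.entity
            planted_labels = [pt.label, other.label]
            fact = f"{other.label} treats {other.entity}."
        wrong = distractor_entities([answer_entity])
        entities = [answer_entity] + wrong
        order = rng.permutation(len(entities))
        options = {
            OPTION_LABELS[pos]: entities[int(order[pos])] for pos in range(len(entities))
        }
        answer_key = next(l for l, v in options.items() if v == answer_entity)
        item_id = f"q{i:04d}"
        item = MCQItem(
            item_id=item_id, stem=stem, options=options,
            answer_key=answer_key, category=category,
        )
        bank.append(item)
        planted_units = tuple(
            uid for label in planted_labels for uid in _units_for_label(kb, label)
        )
        distractor_units = tuple(
            uid
            for label in (points[k].label for k in keys[:4] if points[k].label not in planted_labels)
            for uid in _units_for_label(kb, label)
        )
        truth.by_item[item_id] = PlantedQuestion(
            item_id=item_id,
            planted_unit_ids=planted_units,
            entities=tuple(entities),
            distractor_unit_ids=distractor_units,
            fact=fact,
        )

    for i in range(n_factual):
        make_item(i, "factual")
    for i in range(n_factual, n_items):
        make_item(i, "case_analysis")
    return bank, truth


def generate_rater_matrix(
    n_raters: int = 10,
    n_items: int = 40,
    concordance: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Raters x items ordinal scores with tunable expected agreement.

    Each item has a latent quality (its index in a random permutation); each
    rater ranks a blend ``concordance * latent + (1 - concordance) * noise``.
    At concordance 1 all raters return the identical ranking (W = 1); at 0
    the rankings are independent (E[W] is approximately 1/m). The expected
    agreement increases monotonically with the parameter.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must be in [0, 1]")
    rng = np.random.default_rng(seed)
    latent = rng.permutation(n_items).astype(np.float64)
    ratings = np.empty((n_raters, n_items), dtype=np.float64)
    for r in range(n_raters):
        noise = rng.permutation(n_items).astype(np.float64)
        blend = concordance * latent + (1.0 - concordance) * noise
        # convert the blended value to an ordinal score 1..n
        ratings[r] = np.argsort(np.argsort(blend)) + 1
    return ratings
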