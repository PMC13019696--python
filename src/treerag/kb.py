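"""Tree-organized SPO-T knowledge base.

The knowledge base couples a subject--predicate--object (SPO) graph layer
with the text it came from: each *SPO-T unit* is a triple bound to a text
chunk, plus a generated summary and question--answer pairs. Chunks hang off
the leaves of a book -> chapter -> title -> knowledge-point hierarchy through
the reserved ``include`` predicate, so any recalled unit can be presented
together with its full hierarchical context path (the hook for cross-chapter
reasoning).

Triple extraction and summary/Q&A generation are pluggable backends; the
deterministic defaults shipped here make the whole pipeline runnable and
testable without any language model.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Protocol, Sequence, Tuple

from ._text import content_hash, split_sentences, word_tokens
from .ingest import SourceDocument, TextChunk

__all__ = [
    "INCLUDE",
    "DEFAULT_PREDICATES",
    "SPOTriple",
    "SPOTUnit",
    "TreeNode",
    "KnowledgeBase",
    "ConsistencyError",
    "ContentError",
    "FormatError",
    "TripleExtractor",
    "ContentGenerator",
    "PatternTripleExtractor",
    "TemplateContentGenerator",
    "build_tree",
    "extract_triples",
    "generate_content",
    "lexical_overlap",
    "save_kb",
    "load_kb",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: Reserved predicate linking a tree leaf to a text chunk.
INCLUDE = "include"

#: Default relation vocabulary. The reserved ``include`` edge predicate is
#: always admitted in addition to whatever vocabulary is configured.
DEFAULT_PREDICATES: Tuple[str, ...] = (
    "treats",
    "composed_of",
    "manifests_as",
    "belongs_to",
    "contraindicated_with",
)

LEVEL_KINDS = ("book", "chapter", "title", "knowledge_point")


class ConsistencyError(ValueError):
    """A referential-integrity violation in the knowledge base."""


class ContentError(RuntimeError):
    """Summary/Q&A generation failed for every candidate."""


class FormatError(ValueError):
    """A serialized knowledge base is truncated, malformed, or wrong-version."""


@dataclass(frozen=True)
class SPOTriple:
    """A subject--predicate--object assertion."""

    subject: str
    predicate: str
    object: str

    def __post_init__(self) -> None:
        if not (self.subject and self.predicate and self.object):
            raise ValueError("SPO triple fields must be non-empty")

    def tokens(self) -> List[str]:
        return word_tokens(f"{self.subject} {self.predicate} {self.object}")


@dataclass
class SPOTUnit:
    """An SPO triple bound to the text chunk it was extracted from (SPO-T)."""

    unit_id: str
    triple: SPOTriple
    chunk_id: str
    summary: str = ""
    qa_pairs: List[Tuple[str, str]] = field(default_factory=list)


@dataclass
class TreeNode:
    """One node of the book/chapter/title/knowledge-point hierarchy.

    Only leaf (knowledge-point) nodes carry ``attached_units``; internal
    nodes exist purely to supply the hierarchical context path.
    """

    node_id: str
    label: str
    level_kind: str
    children: List[str] = field(default_factory=list)
    attached_units: List[str] = field(default_factory=list)


@dataclass
class KnowledgeBase:
    """Id-addressed trees, SPO-T units, and chunks with integrity checks."""

    roots: List[str] = field(default_factory=list)
    nodes: Dict[str, TreeNode] = field(default_factory=dict)
    units: Dict[str, SPOTUnit] = field(default_factory=dict)
    chunks: Dict[str, TextChunk] = field(default_factory=dict)

    def validate(self) -> None:
        """Sweep all references; raise :class:`ConsistencyError` on any dangle."""
        for root in self.roots:
            if root not in self.nodes:
                raise ConsistencyError(f"dangling root {root!r}")
        chunk_owner: Dict[str, str] = {}
        for node in self.nodes.values():
            for child in node.children:
                if child not in self.nodes:
                    raise ConsistencyError(f"dangling child {child!r} of {node.node_id!r}")
            if node.attached_units and node.children:
                raise ConsistencyError(
                    f"non-leaf node {node.node_id!r} carries attached units"
                )
            for uid in node.attached_units:
                if uid not in self.units:
                    raise ConsistencyError(f"dangling unit {uid!r} on {node.node_id!r}")
        for unit in self.units.values():
            if unit.chunk_id not in self.chunks:
                raise ConsistencyError(
                    f"unit {unit.unit_id!r} references missing chunk {unit.chunk_id!r}"
                )
            if unit.triple.predicate == INCLUDE:
                prev = chunk_owner.setdefault(unit.chunk_id, unit.unit_id)
                if prev != unit.unit_id:
                    raise ConsistencyError(
                        f"chunk {unit.chunk_id!r} attached by both {prev!r} "
                        f"and {unit.unit_id!r}"
                    )
        attached = {u.chunk_id for u in self.units.values() if u.triple.predicate == INCLUDE}
        for cid in self.chunks:
            if cid not in attached:
                raise ConsistencyError(f"chunk {cid!r} not attached to any leaf")

    # -- path queries -----------------------------------------------------

    def _parents(self) -> Dict[str, str]:
        return {
            child: node.node_id
            for node in self.nodes.values()
            for child in node.children
        }

    def get_context_path(self, unit_id: str) -> List[str]:
        """Labels of the unit's leaf and all its ancestors, root first."""
        unit = self.units.get(unit_id)
        if unit is None:
            raise KeyError(f"unknown unit id {unit_id!r}")
        leaf_id = None
        for node in self.nodes.values():
            if unit_id in node.attached_units:
                leaf_id = node.node_id
                break
        if leaf_id is None:
            raise KeyError(f"unit {unit_id!r} is not attached to any node")
        parents = self._parents()
        path = [leaf_id]
        while path[-1] in parents:
            path.append(parents[path[-1]])
        return [self.nodes[nid].label for nid in reversed(path)]

    def merge(self, other: "KnowledgeBase") -> None:
        """Union another knowledge base into this one (ids must be disjoint)."""
        for attr in ("nodes", "units", "chunks"):
            mine, theirs = getattr(self, attr), getattr(other, attr)
            clash = mine.keys() & theirs.keys()
            if clash:
                raise ConsistencyError(f"id clash merging {attr}: {sorted(clash)[:3]}")
            mine.update(theirs)
        self.roots.extend(other.roots)


def _kind_for(depth: int, is_leaf: bool) -> str:
    if is_leaf:
        return "knowledge_point"
    return LEVEL_KINDS[min(depth, len(LEVEL_KINDS) - 2)]


def build_tree(doc: SourceDocument, chunks: Sequence[TextChunk]) -> KnowledgeBase:
    """Mirror a document's heading tree and attach its chunks via ``include``.

    Each chunk is attached to the node matching its ``heading_path`` through
    an SPO-T unit ``(leaf label, include, chunk_id)``. A chunk whose path is
    absent from the document raises :class:`ConsistencyError`.
    """
    kb = KnowledgeBase()
    path_to_id: Dict[Tuple[str, ...], str] = {}

    def add(node, path: Tuple[str, ...], depth: int) -> str:
        here = path + (node.heading_text,)
        node_id = content_hash(doc.doc_id, *here)
        is_leaf = not node.children
        tree_node = TreeNode(
            node_id=node_id,
            label=node.heading_text,
            level_kind=_kind_for(depth, is_leaf),
        )
        kb.nodes[node_id] = tree_node
        path_to_id[here] = node_id
        for child in node.children:
            tree_node.children.append(add(child, here, depth + 1))
        return node_id

    for top in doc.nodes:
        kb.roots.append(add(top, (), 0))

    for chunk in chunks:
        node_id = path_to_id.get(tuple(chunk.heading_path))
        if node_id is None:
            raise ConsistencyError(
                f"chunk {chunk.chunk_id!r} heading path "
                f"{list(chunk.heading_path)} absent from document tree"
            )
        node = kb.nodes[node_id]
        if node.children:
            # Text under a heading that also has sub-headings attaches to an
            # implicit overview leaf so internal nodes never carry units.
            leaf_id = content_hash(doc.doc_id, *chunk.heading_path, "__overview__")
            if leaf_id not in kb.nodes:
                kb.nodes[leaf_id] = TreeNode(
                    node_id=leaf_id,
                    label=f"{node.label} (overview)",
                    level_kind="knowledge_point",
                )
                node.children.append(leaf_id)
            node = kb.nodes[leaf_id]
        unit = SPOTUnit(
            unit_id=content_hash("include", chunk.chunk_id),
            triple=SPOTriple(node.label, INCLUDE, chunk.chunk_id),
            chunk_id=chunk.chunk_id,
        )
        kb.chunks[chunk.chunk_id] = chunk
        kb.units[unit.unit_id] = unit
        node.attached_units.append(unit.unit_id)
    kb.validate()
    return kb


# -- triple extraction ----------------------------------------------------


class TripleExtractor(Protocol):
    """Backend contract: chunk text in, candidate triples out."""

    def extract(self, chunk: TextChunk) -> List[SPOTriple]: ...


class PatternTripleExtractor:
    """Deterministic default extractor keyed on predicate surface forms.

    For every vocabulary predicate whose surface phrase (underscores as
    spaces) occurs in the chunk text, emits
    ``(deepest heading label, predicate, trailing key-phrase)`` where the
    key-phrase is the run of words after the match, capped at
    ``max_object_words`` and cut at sentence/comma boundaries.
    """

    def __init__(
        self,
        vocabulary: Sequence[str] = DEFAULT_PREDICATES,
        max_object_words: int = 5,
    ) -> None:
        self.vocabulary = tuple(vocabulary)
        self.max_object_words = max_object_words

    def extract(self, chunk: TextChunk) -> List[SPOTriple]:
        subject = chunk.heading_path[-1]
        out: List[SPOTriple] = []
        for predicate in self.vocabulary:
            phrase = predicate.replace("_", " ")
            pattern = re.compile(
                re.escape(phrase) + r"\s+([^.!?。！？,，;；]+)", re.IGNORECASE
            )
            for m in pattern.finditer(chunk.text):
                words = m.group(1).split()[: self.max_object_words]
                if words:
                    out.append(SPOTriple(subject, predicate, " ".join(words)))
        return out


def extract_triples(
    chunk: TextChunk,
    extractor: TripleExtractor,
    vocabulary: Sequence[str] = DEFAULT_PREDICATES,
) -> List[SPOTriple]:
    """Run an extractor and enforce the vocabulary filter and deduplication.

    Triples with predicates outside ``vocabulary`` (plus the reserved
    ``include``) are dropped with a log line; duplicates keep their first
    occurrence. Extractor failures propagate annotated with the chunk id.
    """
    admitted = set(vocabulary) | {INCLUDE}
    try:
        raw = extractor.extract(chunk)
    except Exception as exc:
        raise RuntimeError(f"triple extraction failed on chunk {chunk.chunk_id}") from exc
    seen = set()
    out: List[SPOTriple] = []
    for triple in raw:
        if triple.predicate not in admitted:
            logger.warning(
                "dropping triple with out-of-vocabulary predicate %r (chunk %s)",
                triple.predicate,
                chunk.chunk_id,
            )
            continue
        key = (triple.subject, triple.predicate, triple.object)
        if key in seen:
            continue
        seen.add(key)
        out.append(triple)
    return out


# -- summary / Q&A generation --------------------------------------------


class ContentGenerator(Protocol):
    """Backend contract: chunk in, (summary, qa_pairs) out."""

    def generate(self, chunk: TextChunk) -> Tuple[str, List[Tuple[str, str]]]: ...


class TemplateContentGenerator:
    """Default generator: first sentence as summary, one templated Q&A pair."""

    def generate(self, chunk: TextChunk) -> Tuple[str, List[Tuple[str, str]]]:
        sentences = split_sentences(chunk.text)
        summary = sentences[0] if sentences else chunk.text
        heading = chunk.heading_path[-1]
        qa = [(f"What does the section '{heading}' state?", summary)]
        return summary, qa


def lexical_overlap(candidate: str, reference: str) -> float:
    """Fraction of the candidate's distinct word tokens found in the reference."""
    cand = set(word_tokens(candidate))
    if not cand:
        return 0.0
    ref = set(word_tokens(reference))
    return len(cand & ref) / len(cand)


Selector = Callable[[List[Tuple[str, List[Tuple[str, str]]]], TextChunk], int]


def _default_selector(
    candidates: List[Tuple[str, List[Tuple[str, str]]]], chunk: TextChunk
) -> int:
    scores = [lexical_overlap(summary, chunk.text) for summary, _ in candidates]
    return max(range(len(scores)), key=lambda i: (scores[i], -i))


def generate_content(
    chunk: TextChunk,
    generator: ContentGenerator,
    n_candidates: int = 2,
    selector: Optional[Selector] = None,
) -> Tuple[str, List[Tuple[str, str]]]:
    """Generate ``n_candidates`` summary/Q&A candidates and retain one.

    The selector (default: highest lexical overlap of the summary with the
    chunk text, ties to the earlier candidate) picks the retained version;
    with ``n_candidates=1`` the selector is bypassed. If every generator call
    fails, :class:`ContentError` is raised carrying the last cause.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    candidates: List[Tuple[str, List[Tuple[str, str]]]] = []
    last_exc: Optional[Exception] = None
    for _ in range(n_candidates):
        try:
            candidates.append(generator.generate(chunk))
        except Exception as exc:  # candidate-level failure tolerated
            last_exc = exc
            logger.warning("content generation candidate failed: %s", exc)
    if not candidates:
        raise ContentError(
            f"all {n_candidates} generation candidates failed for chunk {chunk.chunk_id}"
        ) from last_exc
    if len(candidates) == 1:
        return candidates[0]
    pick = (selector or _default_selector)(candidates, chunk)
    return candidates[pick]


def populate_units(
    kb: KnowledgeBase,
    extractor: Optional[TripleExtractor] = None,
    generator: Optional[ContentGenerator] = None,
    vocabulary: Sequence[str] = DEFAULT_PREDICATES,
    n_candidates: int = 2,
) -> None:
    """Extract relation triples and generated content for every chunk in *kb*.

    For each chunk: its ``include`` unit receives the selected summary and
    Q&A pairs, and each extracted relation triple becomes an additional
    SPO-T unit attached to the same leaf.
    """
    extractor = extractor or PatternTripleExtractor(vocabulary)
    generator = generator or TemplateContentGenerator()
    include_units = [u for u in kb.units.values() if u.triple.predicate == INCLUDE]
    for unit in include_units:
        chunk = kb.chunks[unit.chunk_id]
        summary, qa = generate_content(chunk, generator, n_candidates=n_candidates)
        unit.summary, unit.qa_pairs = summary, qa
        leaf = next(n for n in kb.nodes.values() if unit.unit_id in n.attached_units)
        for triple in extract_triples(chunk, extractor, vocabulary):
            rel = SPOTUnit(
                unit_id=content_hash(
                    triple.subject, triple.predicate, triple.object, chunk.chunk_id
                ),
                triple=triple,
                chunk_id=chunk.chunk_id,
                summary=summary,
                qa_pairs=list(qa),
            )
            if rel.unit_id not in kb.units:
                kb.units[rel.unit_id] = rel
                leaf.attached_units.append(rel.unit_id)
    kb.validate()


# -- serialization --------------------------------------------------------

_MANIFEST = "manifest.json"
_FILES = ("nodes.jsonl", "units.jsonl", "chunks.jsonl")


def save_kb(kb: KnowledgeBase, directory: str | Path) -> None:
    """Write the knowledge base as JSONL files plus a versioned manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "nodes.jsonl", "w", encoding="utf-8") as fh:
        for node in kb.nodes.values():
            fh.write(
                json.dumps(
                    {
                        "node_id": node.node_id,
                        "label": node.label,
                        "level_kind": node.level_kind,
                        "children": node.children,
                        "attached_units": node.attached_units,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
    with open(directory / "units.jsonl", "w", encoding="utf-8") as fh:
        for unit in kb.units.values():
            fh.write(
                json.dumps(
                    {
                        "unit_id": unit.unit_id,
                        "subject": unit.triple.subject,
                        "predicate": unit.triple.predicate,
                        "object": unit.triple.object,
                        "chunk_id": unit.chunk_id,
                        "summary": unit.summary,
                        "qa_pairs": [list(p) for p in unit.qa_pairs],
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
    with open(directory / "chunks.jsonl", "w", encoding="utf-8") as fh:
        for chunk in kb.chunks.values():
            fh.write(
                json.dumps(
                    {
                        "chunk_id": chunk.chunk_id,
                        "doc_id": chunk.doc_id,
                        "heading_path": list(chunk.heading_path),
                        "text": chunk.text,
                        "word_count": chunk.word_count,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "roots": kb.roots,
        "counts": {"nodes": len(kb.nodes), "units": len(kb.units), "chunks": len(kb.chunks)},
    }
    (directory / _MANIFEST).write_text(json.dumps(manifest, indent=2), encoding="utf-8")


def _read_jsonl(path: Path) -> Iterable[dict]:
    try:
        with open(path, encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    yield json.loads(line)
                except json.JSONDecodeError as exc:
                    raise FormatError(f"{path.name}:{line_no}: malformed JSON") from exc
    except FileNotFoundError as exc:
        raise FormatError(f"missing knowledge-base file {path.name}") from exc


def load_kb(directory: str | Path) -> KnowledgeBase:
    """Load a knowledge base written by :func:`save_kb`; round-trip lossless."""
    directory = Path(directory)
    try:
        manifest = json.loads((directory / _MANIFEST).read_text(encoding="utf-8"))
    except FileNotFoundError as exc:
        raise FormatError("missing manifest.json") from exc
    except json.JSONDecodeError as exc:
        raise FormatError("malformed manifest.json") from exc
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise FormatError(
            f"schema version mismatch: file has {version!r}, expected {SCHEMA_VERSION}"
        )
    kb = KnowledgeBase(roots=list(manifest.get("roots", [])))
    for rec in _read_jsonl(directory / "nodes.jsonl"):
        kb.nodes[rec["node_id"]] = TreeNode(
            node_id=rec["node_id"],
            label=rec["label"],
            level_kind=rec["level_kind"],
            children=list(rec["children"]),
            attached_units=list(rec["attached_units"]),
        )
    for rec in _read_jsonl(directory / "units.jsonl"):
        kb.units[rec["unit_id"]] = SPOTUnit(
            unit_id=rec["unit_id"],
            triple=SPOTriple(rec["subject"], rec["predicate"], rec["object"]),
            chunk_id=rec["chunk_id"],
            summary=rec["summary"],
            qa_pairs=[tuple(p) for p in rec["qa_pairs"]],
        )
    for rec in _read_jsonl(directory / "chunks.jsonl"):
        kb.chunks[rec["chunk_id"]] = TextChunk(
            chunk_id=rec["chunk_id"],
            doc_id=rec["doc_id"],
            heading_path=tuple(rec["heading_path"]),
            text=rec["text"],
            word_count=rec["word_count"],
        )
    counts = manifest.get("counts", {})
    for name, coll in (("nodes", kb.nodes), ("units", kb.units), ("chunks", kb.chunks)):
        if name in counts and counts[name] != len(coll):
            raise FormatError(
                f"{name}.jsonl truncated: manifest says {counts[name]}, found {len(coll)}"
            )
    kb.validate()
    return kb
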