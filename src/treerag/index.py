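"""Embedding, cosine vector search, and the keyword inverted index.

Two retrieval paths are maintained over the knowledge base:

* a **vector index** over chunk text, summaries, and Q&A pairs, queried by
  cosine similarity with a top-k contract (results in descending similarity,
  ties broken by insertion order). Search is exact brute-force over the
  stored matrix; at the corpus sizes this package targets, exact search is
  both fast and the strongest possible instantiation of the k-NN contract
  (recall 1.0 at any size). The approximate-search parameters in
  :class:`VectorIndexParams` are retained as configuration surface for
  adapter backends.
* a **keyword inverted index** over SPO triple tokens, scored by the number
  of distinct query tokens a unit's triple contains.

The default embedder is a seeded feature-hashing bag-of-tokens embedder, so
the whole pipeline runs deterministically with no model downloads.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Protocol, Sequence, Tuple

import numpy as np

from ._text import word_tokens
from .kb import KnowledgeBase, SPOTriple

__all__ = [
    "Embedder",
    "HashingEmbedder",
    "VectorIndexParams",
    "VectorIndex",
    "KeywordIndex",
    "cosine_similarity",
    "knn_search",
    "keyword_match",
    "build_indexes",
]

CONTENT_KINDS = ("chunk", "summary", "qa")


class Embedder(Protocol):
    """Batch text -> unit-norm vectors. Adapters to remote services plug in here."""

    dim: int

    def embed(self, text: str) -> np.ndarray: ...


class HashingEmbedder:
    """Deterministic feature-hashing bag-of-tokens embedder.

    Token counts are hashed (BLAKE2, keyed by the seed — stable across
    processes and platforms) into ``dim`` buckets with a +/-1 sign hash, then
    L2-normalized. Texts with disjoint vocabularies map to near-orthogonal
    vectors at large ``dim``.
    """

    def __init__(self, dim: int = 256, seed: int = 0) -> None:
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = dim
        self.seed = seed
        self._salt = str(seed).encode()

    def _bucket(self, token: str) -> Tuple[int, int]:
        digest = hashlib.blake2b(token.encode(), key=self._salt, digest_size=8).digest()
        value = int.from_bytes(digest, "big")
        return value % self.dim, 1 if (value >> 60) & 1 else -1

    def embed(self, text: str) -> np.ndarray:
        if not text or not text.strip():
            raise ValueError("cannot embed empty text")
        vec = np.zeros(self.dim, dtype=np.float64)
        for token in word_tokens(text):
            bucket, sign = self._bucket(token)
            vec[bucket] += sign
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        return vec


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between *a* and *b*; zero vectors yield 0.0."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        warnings.warn("cosine similarity with zero vector defined as 0", stacklevel=2)
        return 0.0
    return float(np.dot(a, b) / (na * nb))


@dataclass(frozen=True)
class VectorIndexParams:
    """Approximate-search configuration (graph degree / breadth) kept for
    adapter backends; the in-process index always searches exactly."""

    m: int = 16
    ef_construction: int = 200
    ef_search: int = 64
    brute_force_threshold: int = 1000


@dataclass
class VectorIndex:
    """Exact cosine top-k index over (unit_id, content_kind) entries."""

    dim: int
    params: VectorIndexParams = field(default_factory=VectorIndexParams)
    _keys: List[Tuple[str, str]] = field(default_factory=list)
    _keyset: set = field(default_factory=set, repr=False)
    _rows: List[np.ndarray] = field(default_factory=list)
    _matrix: np.ndarray | None = field(default=None, repr=False)

    def add(self, unit_id: str, content_kind: str, vector: np.ndarray) -> None:
        if content_kind not in CONTENT_KINDS:
            raise ValueError(f"unknown content kind {content_kind!r}")
        vector = np.asarray(vector, dtype=np.float64)
        if vector.shape != (self.dim,):
            raise ValueError(f"expected dim {self.dim}, got {vector.shape}")
        if not np.all(np.isfinite(vector)):
            raise ValueError("vector has non-finite entries")
        key = (unit_id, content_kind)
        if key in self._keyset:
            raise ValueError(f"duplicate index entry {key}")
        self._keyset.add(key)
        self._keys.append(key)
        self._rows.append(vector)
        self._matrix = None

    def __len__(self) -> int:
        return len(self._keys)

    def _dense(self) -> np.ndarray:
        if self._matrix is None:
            self._matrix = (
                np.vstack(self._rows) if self._rows else np.empty((0, self.dim))
            )
        return self._matrix


def knn_search(
    index: VectorIndex, query: np.ndarray, k: int
) -> List[Tuple[str, str, float]]:
    """Top-*k* entries by cosine similarity, descending; ties keep insertion order.

    An empty index returns an empty list; ``k`` larger than the index returns
    everything.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(index) == 0:
        return []
    query = np.asarray(query, dtype=np.float64)
    if query.shape != (index.dim,):
        raise ValueError(f"query dim {query.shape} != index dim {index.dim}")
    matrix = index._dense()
    qnorm = np.linalg.norm(query)
    norms = np.linalg.norm(matrix, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = matrix @ query / np.where(norms * qnorm == 0, 1.0, norms * qnorm)
    sims = np.where((norms == 0) | (qnorm == 0), 0.0, sims)
    k = min(k, len(index))
    # stable sort on descending similarity preserves insertion order on ties
    order = np.argsort(-sims, kind="stable")[:k]
    return [(index._keys[i][0], index._keys[i][1], float(sims[i])) for i in order]


@dataclass
class KeywordIndex:
    """Inverted index token -> sorted unit ids over SPO triple tokens."""

    analyzer: str = "word"
    postings: Dict[str, List[str]] = field(default_factory=dict)
    _unit_tokens: Dict[str, frozenset] = field(default_factory=dict)

    def _analyze(self, text: str) -> List[str]:
        tokens = word_tokens(text)
        if self.analyzer == "cjk_bigram":
            extra = []
            for tok in tokens:
                if len(tok) == 1 and ord(tok) > 0x2E80:
                    extra.append(tok)
            prev = None
            for tok in extra:
                if prev is not None:
                    tokens.append(prev + tok)
                prev = tok
        return tokens

    def add(self, unit_id: str, triple: SPOTriple) -> None:
        tokens = frozenset(
            self._analyze(f"{triple.subject} {triple.predicate} {triple.object}")
        )
        self._unit_tokens[unit_id] = tokens
        for token in tokens:
            lst = self.postings.setdefault(token, [])
            if unit_id not in lst:
                lst.append(unit_id)
                lst.sort()

    def __len__(self) -> int:
        return len(self._unit_tokens)


def keyword_match(
    index: KeywordIndex, query_text: str, limit: int | None = None
) -> List[Tuple[str, int]]:
    """Rank units by the number of distinct query tokens their triple contains.

    Score is invariant to token order and duplication in the query; units with
    score 0 are excluded; ties break by ascending unit id.
    """
    query_tokens = set(index._analyze(query_text))
    scores: Dict[str, int] = {}
    for token in query_tokens:
        for unit_id in index.postings.get(token, ()):
            scores[unit_id] = scores.get(unit_id, 0) + 1
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:limit] if limit is not None else ranked


def build_indexes(
    kb: KnowledgeBase,
    embedder: Embedder,
    params: VectorIndexParams | None = None,
    analyzer: str = "word",
) -> Tuple[KeywordIndex, VectorIndex]:
    """Build both retrieval paths from a knowledge base, deterministically.

    Every unit's triple feeds the keyword index; its chunk text, summary, and
    Q&A pairs (when present) feed the vector index under their content kinds.
    Units iterate in insertion order, so rebuilds are reproducible.
    """
    kw = KeywordIndex(analyzer=analyzer)
    vx = VectorIndex(dim=embedder.dim, params=params or VectorIndexParams())
    for unit_id, unit in kb.units.items():
        kw.add(unit_id, unit.triple)
        chunk = kb.chunks[unit.chunk_id]
        vx.add(unit_id, "chunk", embedder.embed(chunk.text))
        if unit.summary.strip():
            vx.add(unit_id, "summary", embedder.embed(unit.summary))
        if unit.qa_pairs:
            qa_text = " ".join(f"{q} {a}" for q, a in unit.qa_pairs)
            if qa_text.strip():
                vx.add(unit_id, "qa", embedder.embed(qa_text))
    return kw, vx
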