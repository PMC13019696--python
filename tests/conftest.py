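import pytest

from treerag.index import HashingEmbedder, build_indexes
from treerag.ingest import parse_document, segment_chunks
from treerag.kb import build_tree, populate_units
from treerag.synthetic import (
    CorpusSpec,
    OracleClusterEmbedder,
    build_synthetic_kb,
    generate_mcq,
)

TWO_CHAPTER_DOC = """\
# Handbook

## Chapter One

### Point alpha

Alpha content describes the first topic. It treats fever promptly.

### Point beta

Beta content describes the second topic in a few words.

## Chapter Two

### Point gamma

Gamma content covers another area entirely. It treats cough.

### Point delta

Delta content closes the handbook with remarks.
"""


@pytest.fixture
def small_doc():
    return parse_document(TWO_CHAPTER_DOC, doc_id="handbook")


@pytest.fixture
def small_kb(small_doc):
    chunks = segment_chunks(small_doc, min_words=5, max_words=60)
    kb = build_tree(small_doc, chunks)
    populate_units(kb)
    return kb


@pytest.fixture(scope="session")
def synth():
    """A seeded synthetic corpus with its planted truth and oracle embedder."""
    spec = CorpusSpec(seed=7)
    kb, points = build_synthetic_kb(spec)
    embedder = OracleClusterEmbedder(points)
    keyword_index, vector_index = build_indexes(kb, embedder)
    bank, truth = generate_mcq(kb, points, n_items=20, seed=7)
    return {
        "spec": spec,
        "kb": kb,
        "points": points,
        "embedder": embedder,
        "keyword_index": keyword_index,
        "vector_index": vector_index,
        "bank": bank,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def hashing_embedder():
    return HashingEmbedder(dim=256, seed=0)
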