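# Methods

## The pipeline

`treerag` implements a retrieval-augmented question-answering pipeline in
which the knowledge base is *tree-organized*: source books are parsed into a
book → chapter → title → knowledge-point hierarchy, their text is segmented
into 200–300-word chunks that never cross heading boundaries, and each chunk
is bound to its leaf through the reserved `include` predicate. From every
chunk the system extracts subject–predicate–object (SPO) triples, a summary,
and question–answer pairs; the triple plus its chunk (an *SPO-T unit*) is
the retrieval atom. Because each unit knows its leaf, any recalled unit can
be presented with its full root-to-leaf context path, which is what lets
evidence from different chapters be combined coherently.

Retrieval is dual-path: exact keyword matching over triple tokens (an
inverted index) and cosine similarity over embedded chunk/summary/Q&A text.
The fused candidate list takes up to 5 keyword hits and fills with vector
hits to a total of 15; a keyword deficit is backfilled by the vector path,
never the reverse. Generation is wrapped in a self-reflective loop:
relevance-filter the recall, decompose the question if nothing survives,
generate, check support, check helpfulness, reformulate on failure — all
under explicit iteration caps.

## Segmentation

Within one section (one heading's own paragraphs) consecutive paragraphs
are packed greedily: a chunk closes as soon as it reaches `min_words`
(default 200) or when the next paragraph would push it past `max_words`
(default 300). Sections shorter than `min_words` are emitted as-is and never
merged across headings — merging would detach a chunk from its node in the
tree. A paragraph longer than `max_words` is first split at sentence
boundaries (terminal punctuation; see `docs/formats.md`), with a hard token
split as a last resort for run-on sentences, so the upper bound holds
unconditionally whenever a section offers that much material. Chunks do not
merge across sub-headings at any level; where text sits under a heading
that also has sub-headings, it attaches to an implicit overview leaf so
internal nodes never carry units.

## Triple extraction and content generation

Extraction and summary/Q&A generation are backend interfaces; production
deployments plug in an LLM adapter. The shipped deterministic extractor
emits `(deepest heading label, predicate, trailing key-phrase)` for each
occurrence of a vocabulary predicate's surface form in the chunk text. The
predicate vocabulary is configurable; the default set is `treats`,
`composed_of`, `manifests_as`, `belongs_to`, `contraindicated_with`, with
`include` reserved for leaf→chunk edges. Out-of-vocabulary predicates from
any extractor are dropped and logged; duplicates keep first occurrence.

Content generation runs `n_candidates` times (default 2) and a pluggable
selector retains one candidate; the default selector scores each candidate
summary by the fraction of its distinct tokens found in the chunk and takes
the highest (ties to the earlier candidate). This replaces a human
"keep the better version" review with a deterministic, documented criterion.

## Embedding and search

The default embedder is a seeded feature-hashing bag-of-tokens embedder
(default dimension 256): token counts are hashed into buckets with a ±1 sign
hash keyed by the seed (BLAKE2, stable across platforms) and L2-normalized.
It needs no model artifacts, and at large dimension disjoint vocabularies
map to near-orthogonal vectors.

Vector search is exact brute-force cosine over the stored matrix at every
index size. At the corpus scales this package targets (thousands of
entries), exact search is fast, and it is the strongest instantiation of the
k-NN contract the index promises — descending similarity, ties by insertion
order, recall 1.0. The approximate-graph parameters (`m`,
`ef_construction`, `ef_search`, `brute_force_threshold`) remain in the
configuration surface for adapter backends that delegate to an external
approximate-search service. Cosine with a zero vector is defined as 0 with a
warning rather than NaN.

A unit indexed under several content kinds (chunk, summary, qa) scores as
the maximum over its kinds during recall — equivalently its best-ranked
appearance — a documented choice where joint-versus-separate retrieval was
genuinely open.

## Fusion and prompting

Default quotas: 5 keyword + 10 vector = 15 entries. Keyword entries precede
vector entries in the prompt (the structured triples act as importance
hints for the attached text); within each source the original rank order is
kept. Deduplication is keyed on unit id with the keyword path taking
precedence. The prompt template (role / task / knowledge / question
placeholders) is injectable and identical across backends; the default is
documented bit-exactly in `docs/formats.md`.

## The reflective loop

Caps default to `regen_cap=3`, `reform_cap=2`, `decomp_cap=1` and are global
across one run, giving closed-form bounds: at most
`1 + regen_cap + reform_cap` generator calls, at most `reform_cap + 1`
retrieval rounds (each of which may add one decomposition fan-out of
sub-question retrievals, at most `decomp_cap` times in total). Sub-questions
are not themselves decomposed. Judge failures (exceptions, unparseable
replies) are conservative negative verdicts. The default offline judges are
lexical-overlap heuristics with threshold 0.2 — deliberately permissive:
their job in the offline configuration is to reject only clearly unrelated
pairs. Cap exhaustion is a normal terminal state; the last draft, if any, is
returned flagged best-effort. Every branch decision is logged to a
replayable trace.

With all-approve judges the loop reduces exactly to one retrieval plus one
generation — the plain-RAG ablation — which the test suite asserts.

## Evaluation machinery

Exam rounds are one-point multiple-choice items in two categories (factual,
case-analysis, defaulting to a 70/30 mix). Free-text answers are mapped to
options by the first standalone option label in the text; no label means
abstention, scored 0. Percentages are rounded half-up to two decimals —
reproducing printed score tables depends on that rule. Round sampling is
uniform without replacement under a seed, after excluding any item whose
normalized stem text hashes into the knowledge base's chunk texts (a leakage
screen).

Recall accuracy is the sum of all 0/1 entry judgments divided by
(judgments × entries per item): equivalently each rater's total over
items × entries, averaged across raters.

Of the RAGAs-family metrics, the four with model-free definitions are
implemented: context precision (average precision restricted to the
retrieved list), context recall (fraction of ground-truth fact strings whose
tokens are all covered by a single retrieved context), context entity recall
(entity-set coverage), and semantic similarity (embedding cosine rescaled to
[0, 1]). Faithfulness, answer relevancy and answer correctness require an
answer-quality judge and are exposed only as a pluggable-judge hook with no
offline guarantee.

Statistics: Kendall's W with mid-rank tie correction and its chi-square test
(`chi2 = m (n−1) W`, `df = n−1`); McNemar's test on paired correctness with
continuity correction, switching to the exact two-sided binomial when the
discordant count is below 25; paired t with paired Cohen's d
(`mean(diff)/sd(diff)`, degenerate inputs flagged); seeded percentile
bootstrap (default 10,000 resamples of the scored unit) for 95% intervals.

## Synthetic corpora

The generator emulates a multi-book corpus: each knowledge point owns a
distinct cluster of pseudo-words (14 exclusive words plus one answer
entity), carries one planted relation sentence (`<label> treats <entity>.`),
and, at rate `cross_link_rate` (default 0.3), references a point in another
chapter by echoing four of its cluster words — the minimal structure that
exercises cross-chapter evidence pooling. Defaults (2 books × 3 chapters ×
4 points, ~250 words per point) keep the whole suite desk-scale; the text is
cluster-token English pseudo-prose, chosen for test readability over realism.
Factual questions ask for a point's planted entity phrased in its cluster
vocabulary; case-analysis questions span exactly two cross-linked points.

An `OracleClusterEmbedder` (one dimension per knowledge point; cluster
tokens map to their point's dimension, everything else is ignored) is the
ideal-retrieval reference: under it, planted-unit recall@15 is guaranteed
for every factual item, which the suite asserts. Generated rater matrices
blend a latent item quality with independent noise; the concordance
parameter moves expected Kendall's W monotonically from ≈1/m (independent)
to 1 (identical rankings).

What passing on synthetic corpora shows: the mechanics — segmentation
bounds, fusion quotas, loop termination, metric arithmetic — are correct.
What it does not show: behavior on real prose, real models' judgment
quality, or real exam difficulty.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` runs the default synthetic corpus (24 knowledge
points, ~55 SPO-T units) for the fusion quantities, a 700-words-per-point
corpus (72 chunks) for the segmentation bound, and a 600-item round (420
factual / 180 case) for the scoring arithmetic; these sizes make every
quantity recomputable in seconds while matching the documented study
structure.

## Known limitations

- The deterministic extractor and judges are lexical; they validate the
  pipeline's control flow and bookkeeping, not linguistic quality.
- Entity normalization across books, ontology alignment, and OCR/layout
  recovery are out of scope; input must already be in the heading dialect.
- The keyword analyzer's CJK support is the character/bigram mode; no
  dictionary segmentation is attempted.
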