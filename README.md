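# treerag

Tree-organized SPO-triple knowledge bases with quota-fused dual-path recall
and a self-reflective generation loop — a retrieval-augmented
question-answering pipeline for hierarchically structured reference corpora
(textbook-style material with books, chapters and knowledge points), built
so that every stage runs and is tested offline with deterministic backends.

**Who it is for.** Builders of domain question-answering systems over
curated reference texts — the motivating setting is traditional Chinese
medicine licensing-exam and classics-course material — who need the
knowledge base, retrieval, prompting, reflection and evaluation machinery to
be inspectable and reproducible independently of any particular language
model or embedding service.

## The method

1. **Knowledge base.** Documents are parsed into a book → chapter → title →
   knowledge-point tree and segmented into 200–300-word chunks that never
   cross heading boundaries. Each chunk yields an *SPO-T unit*: a
   (subject, predicate, object) triple bound to the chunk, plus a generated
   summary and Q&A pairs; chunks attach to tree leaves through the reserved
   `include` predicate, so every unit carries its root-to-leaf context path.
2. **Recall.** Two paths — keyword matching over triple tokens and cosine
   similarity over embedded text — are fused under a fixed quota: up to 5
   keyword hits, filled with vector hits to 15 total; a keyword deficit is
   backfilled by the vector path. Keyword entries precede vector entries in
   the prompt.
3. **Reflection.** Generation is wrapped in judge-gated checks: filter the
   recall for relevance; decompose the question if nothing survives;
   generate; regenerate while the draft is unsupported (≤ 3 times);
   reformulate and restart while it is unhelpful (≤ 2 times). The loop
   terminates within closed-form call bounds for any judge behavior; with
   all-approve judges it reduces exactly to plain RAG.
4. **Evaluation.** One-point multiple-choice rounds (factual /
   case-analysis categories) with percentage conversion; recall accuracy
   from expert 0/1 entry judgments; context precision/recall, entity recall
   and semantic similarity; Kendall's W (+ χ² = m(n−1)W), McNemar, paired
   t / Cohen's d, and seeded percentile bootstrap intervals.

A seeded synthetic-corpus generator plants vocabulary clusters, relation
facts and cross-chapter links, so retrieval ground truth is known by
construction. See `docs/methods.md` for the full model description and
`docs/formats.md` for every file format.

## Worked example

Generate a small synthetic corpus (2 books × 3 chapters × 4 knowledge
points) with a question bank, then answer one of its questions:

```
$ treerag simulate --out demo --n-questions 6
wrote kb (55 units), 6 questions to demo

$ treerag ask --kb demo/kb --question \
    "In the setting of w00711 w00400 w00118 w00353 w00028 w01867, \
     which entity does Point 2.3.1 treat?"
{
  "answer": "Point 2.3.1 treats w00884. ...",
  "status": "answered",
  "best_effort": false,
  "steps": ["retrieve+filter", "generate", "check_support",
            "check_helpfulness", "terminate"]
}
```

The question is phrased in the vocabulary cluster of knowledge point 2.3.1;
fused recall surfaces that point's units, the extractive offline generator
answers with the best-supported evidence text — whose first sentence is the
planted fact `Point 2.3.1 treats w00884.`, the correct option (`A`) in the
generated question bank — and the trace shows the loop's single clean pass:
retrieval and relevance filtering, one generation, a passed support check,
a passed helpfulness check, termination with status `answered`.

`treerag ask --no-reflect` runs the plain recall-and-generate ablation;
`treerag evaluate --bank demo/questions.jsonl --kb demo/kb --n 6` scores a
round end to end.

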