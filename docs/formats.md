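# File formats and dialects

## Source-document dialect

Plain text (UTF-8). Two constructs only:

1. **Headings** — a line whose first non-blank character is `#`. The number
   of leading `#` characters is the heading level: `#` = book (level 1),
   `##` = chapter, `###` = title, `####` = knowledge point. A heading at
   level *k* must appear while a heading at level *k−1* is open; deeper
   jumps (e.g. `###` directly under `#`) are a structural error naming the
   offending line. Text after the `#` run, stripped of surrounding
   whitespace, is the heading label.
2. **Paragraphs** — maximal runs of non-blank, non-heading lines separated
   by blank lines. Lines within one paragraph are joined with single spaces;
   paragraph text is otherwise preserved verbatim. Paragraph text before the
   first heading is a structural error.

## Word counting (used everywhere)

A *word* is either (a) one CJK ideograph (Unicode ranges U+3400–U+4DBF,
U+4E00–U+9FFF), or (b) a maximal run of non-whitespace, non-CJK characters.
This single rule drives chunk segmentation, the default token counter, and
prompt token estimates. Keyword analysis and the lexical judges use a
stricter variant that keeps only alphanumeric/CJK tokens, lowercased
(`"Fever."` and `"fever"` collide).

Sentence boundaries are terminal-punctuation runs: `.` `!` `?` `。` `！`
`？`. The terminator stays with its sentence.

## Chunk JSONL

One chunk per line: `{"chunk_id", "doc_id", "heading_path": [..],
"text", "word_count"}`.

## Knowledge-base directory

- `manifest.json` — `{"schema_version": 1, "roots": [node ids], "counts":
  {"nodes": N, "units": N, "chunks": N}}`. Loading any other
  `schema_version` is a format error; counts that disagree with the JSONL
  files mean truncation.
- `nodes.jsonl` — `{"node_id", "label", "level_kind", "children": [ids],
  "attached_units": [ids]}`.
- `units.jsonl` — `{"unit_id", "subject", "predicate", "object",
  "chunk_id", "summary", "qa_pairs": [[q, a], ..]}`.
- `chunks.jsonl` — as Chunk JSONL above.

All ids are 12-hex-digit content hashes, so rebuilding the same corpus
yields the same ids.

## Question-bank JSONL

`{"item_id", "stem", "options": {"A": .., ...}, "answer_key", "category":
"factual"|"case_analysis", "points": 1}`.

## Prompt template

Plain text with the four named placeholders `{role}`, `{task}`,
`{knowledge}`, `{question}`; all four are required. The shipped default is
exactly:

```
{role}

{task}

Knowledge base content (each entry: triple | context path | source text):
{knowledge}

Question:
{question}
```

Each knowledge entry renders as
`[k] (subject, predicate, object) | root > ... > leaf | chunk text` in
fused order; an empty recall renders `(no knowledge entries retrieved)`.

## Backend adapter grammar

Generators return plain answer text. Judges must reply with a line starting
`YES` or `NO` (case-insensitive); anything else is a parse failure and
counts as a negative verdict. Decomposers return one sub-question per line;
reformulators return the rewritten question as plain text.
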