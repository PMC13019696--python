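"""Hierarchical document parsing and word-bounded chunk segmentation.

Source documents arrive as plain text in a Markdown-like dialect: a line of
``#`` characters encodes heading level (``#`` = book, ``##`` = chapter, ...),
and blank lines separate paragraphs. Each heading's paragraphs form a
*section*; sections are segmented into chunks of ``min_words``..``max_words``
words that never cross a heading boundary, so every chunk maps cleanly onto
one node of the knowledge tree.

The dialect is documented bit-exactly in ``docs/formats.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Sequence, Tuple

from ._text import content_hash, split_sentences, tokenize, word_count

__all__ = [
    "HeadingNode",
    "SourceDocument",
    "TextChunk",
    "StructureError",
    "parse_document",
    "segment_chunks",
    "iter_sections",
]


class StructureError(ValueError):
    """Raised when heading nesting in the input dialect is malformed."""


@dataclass
class HeadingNode:
    """One heading with its own paragraphs and sub-headings.

    ``level`` is 1 for the top (book) heading; a child's level is always its
    parent's level + 1.
    """

    level: int
    heading_text: str
    paragraphs: List[str] = field(default_factory=list)
    children: List["HeadingNode"] = field(default_factory=list)


@dataclass
class SourceDocument:
    """A parsed document: an ordered forest of heading trees."""

    doc_id: str
    title: str
    nodes: List[HeadingNode] = field(default_factory=list)


@dataclass(frozen=True)
class TextChunk:
    """A contiguous piece of one section's text, bounded in word count.

    ``heading_path`` holds the heading texts from the document root down to
    the section the chunk came from; ``word_count`` follows the package-wide
    counting rule (whitespace tokens; one per CJK ideograph).
    """

    chunk_id: str
    doc_id: str
    heading_path: Tuple[str, ...]
    text: str
    word_count: int


def parse_document(raw: str, doc_id: str = "doc") -> SourceDocument:
    """Parse the plain-text heading dialect into a :class:`SourceDocument`.

    Parameters
    ----------
    raw:
        Input text. Lines matching ``^#+ `` open a heading whose level is the
        number of ``#`` characters; non-blank line runs between headings are
        paragraphs. Paragraph text is preserved verbatim (sans the newline
        joins within a paragraph, which become spaces).
    doc_id:
        Identifier recorded on the document and its chunks.

    Raises
    ------
    StructureError
        If a heading is nested more than one level below its parent, or a
        paragraph appears before any heading.
    """
    doc = SourceDocument(doc_id=doc_id, title="")
    stack: List[HeadingNode] = []  # open headings, stack[i].level == i+1
    para_lines: List[str] = []
    para_start = 0

    def flush_paragraph(line_no: int) -> None:
        nonlocal para_lines
        if not para_lines:
            return
        if not stack:
            raise StructureError(
                f"line {para_start}: paragraph text before any heading"
            )
        stack[-1].paragraphs.append(" ".join(para_lines))
        para_lines = []

    for line_no, line in enumerate(raw.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            flush_paragraph(line_no)
            continue
        if stripped.startswith("#"):
            flush_paragraph(line_no)
            hashes = len(stripped) - len(stripped.lstrip("#"))
            text = stripped[hashes:].strip()
            level = hashes
            if level > len(stack) + 1:
                raise StructureError(
                    f"line {line_no}: heading level {level} nested under "
                    f"level {len(stack)} (child deeper than parent+1)"
                )
            node = HeadingNode(level=level, heading_text=text)
            del stack[level - 1 :]
            if stack:
                stack[-1].children.append(node)
            else:
                doc.nodes.append(node)
                if not doc.title:
                    doc.title = text
            stack.append(node)
        else:
            if not para_lines:
                para_start = line_no
            para_lines.append(stripped)
    flush_paragraph(-1)
    return doc


def iter_sections(doc: SourceDocument) -> Iterator[Tuple[Tuple[str, ...], List[str]]]:
    """Yield ``(heading_path, paragraphs)`` for every heading that carries text,
    in reading order."""

    def walk(node: HeadingNode, path: Tuple[str, ...]) -> Iterator:
        here = path + (node.heading_text,)
        if node.paragraphs:
            yield here, node.paragraphs
        for child in node.children:
            yield from walk(child, here)

    for root in doc.nodes:
        yield from walk(root, ())


def _split_oversized(paragraph: str, max_words: int) -> List[str]:
    """Split a paragraph longer than *max_words* at sentence boundaries.

    Sentences are greedily packed into pieces of at most *max_words* words; a
    single sentence longer than the cap is hard-split on token runs as a last
    resort so the bound always holds.
    """
    if word_count(paragraph) <= max_words:
        return [paragraph]
    pieces: List[str] = []
    current: List[str] = []
    current_words = 0
    for sentence in split_sentences(paragraph):
        n = word_count(sentence)
        if n > max_words:  # degenerate run-on sentence
            if current:
                pieces.append(" ".join(current))
                current, current_words = [], 0
            toks = tokenize(sentence)
            for i in range(0, len(toks), max_words):
                pieces.append(" ".join(toks[i : i + max_words]))
            continue
        if current and current_words + n > max_words:
            pieces.append(" ".join(current))
            current, current_words = [], 0
        current.append(sentence)
        current_words += n
    if current:
        pieces.append(" ".join(current))
    return pieces


def segment_chunks(
    doc: SourceDocument, min_words: int = 200, max_words: int = 300
) -> List[TextChunk]:
    """Greedily pack each section's paragraphs into word-bounded chunks.

    Within one section (one heading's own paragraphs), consecutive paragraphs
    accumulate into a chunk; the chunk closes as soon as it reaches
    ``min_words``, or earlier when appending the next paragraph would push it
    past ``max_words``. Chunks never span heading boundaries, so a section
    shorter than ``min_words`` yields one short chunk. Paragraphs longer than
    ``max_words`` are first split at sentence boundaries.

    Every source word lands in exactly one chunk, and no chunk exceeds
    ``max_words`` whenever its section offers that much material.
    """
    if min_words >= max_words:
        raise ValueError("min_words must be < max_words")
    chunks: List[TextChunk] = []
    for path, paragraphs in iter_sections(doc):
        units: List[str] = []
        for para in paragraphs:
            units.extend(_split_oversized(para, max_words))
        current: List[str] = []
        current_words = 0

        def close() -> None:
            nonlocal current, current_words
            if not current:
                return
            text = "\n".join(current)
            chunk_id = content_hash(doc.doc_id, "/".join(path), text, str(len(chunks)))
            chunks.append(
                TextChunk(
                    chunk_id=chunk_id,
                    doc_id=doc.doc_id,
                    heading_path=tuple(path),
                    text=text,
                    word_count=current_words,
                )
            )
            current, current_words = [], 0

        for i, unit in enumerate(units):
            n = word_count(unit)
            if current and current_words + n > max_words:
                close()
            current.append(unit)
            current_words += n
            if current_words >= min_words:
                close()
        close()
    return chunks
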