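"""Article ingestion and token-budgeted chunking.

Articles arrive as PDF or UTF-8 plain-text files, one document per file.
Extracted text is split into chunks that each stay strictly under a token
budget (default 4,000) so a language-model backend can read them
sequentially. The default tokenizer is whitespace splitting — reproducible
with zero dependencies; a model-specific tokenizer can be plugged in.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

from ._pdf import EncryptedPdfError, PdfError, extract_pdf_text

__all__ = [
    "Document",
    "Chunk",
    "CorpusError",
    "read_document",
    "load_corpus",
    "chunk_document",
    "whitespace_tokenizer",
]

DEFAULT_MAX_TOKENS = 4000

Tokenizer = Callable[[str], list[str]]


class CorpusError(ValueError):
    """Unreadable corpus input; carries the offending path in its message."""


@dataclass(frozen=True)
class Document:
    """One article: an opaque identifier plus its full extracted text.

    ``raw_text`` may be empty — that signals a failed or empty extraction
    and is handled downstream (an empty document yields zero chunks).
    """

    article_id: str
    source_path: str
    raw_text: str

    def __post_init__(self) -> None:
        if not self.article_id:
            raise ValueError("article_id must be non-empty")


@dataclass(frozen=True)
class Chunk:
    """A token-budgeted slice of one document."""

    article_id: str
    chunk_index: int
    text: str
    token_count: int


def whitespace_tokenizer(text: str) -> list[str]:
    """Default tokenizer: whitespace-delimited words."""
    return text.split()


def read_document(path: str | Path, article_id: str | None = None) -> Document:
    """Read one article file; dispatch on extension (.pdf vs plain text).

    PDF extraction preserves per-page reading order; plain text is read
    verbatim as UTF-8. ``article_id`` defaults to the filename stem.
    Unreadable, corrupt or encrypted files raise :class:`CorpusError`
    naming the path.
    """
    path = Path(path)
    if article_id is None:
        article_id = path.stem
    if not path.exists():
        raise CorpusError(f"no such file: {path}")
    try:
        if path.suffix.lower() == ".pdf":
            text = extract_pdf_text(path)
        else:
            text = path.read_text(encoding="utf-8")
    except EncryptedPdfError as exc:
        raise CorpusError(str(exc)) from exc
    except (PdfError, UnicodeDecodeError, OSError) as exc:
        raise CorpusError(f"cannot read {path}: {exc}") from exc
    return Document(article_id=article_id, source_path=str(path), raw_text=text)


def load_corpus(source: str | Path) -> list[Document]:
    """Load a corpus from a manifest CSV (columns article_id, path) or by
    scanning a directory for ``*.txt`` / ``*.pdf`` (article_id = file stem).

    Duplicate article ids are rejected.
    """
    source = Path(source)
    docs: list[Document] = []
    if source.is_dir():
        for path in sorted(source.iterdir()):
            if path.suffix.lower() in (".txt", ".pdf"):
                docs.append(read_document(path))
    else:
        with open(source, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"article_id", "path"} <= set(
                reader.fieldnames
            ):
                raise CorpusError(
                    f"manifest {source} must have columns article_id, path"
                )
            base = source.parent
            for row in reader:
                p = Path(row["path"])
                if not p.is_absolute():
                    p = base / p
                docs.append(read_document(p, article_id=row["article_id"]))
    seen: set[str] = set()
    for d in docs:
        if d.article_id in seen:
            raise CorpusError(f"duplicate article_id {d.article_id!r} in corpus")
        seen.add(d.article_id)
    return docs


def chunk_document(
    doc: Document,
    max_tokens: int = DEFAULT_MAX_TOKENS,
    tokenizer: Tokenizer = whitespace_tokenizer,
) -> list[Chunk]:
    """Split a document into chunks each strictly below the token budget.

    Greedy left-to-right fill: tokens are appended to the current chunk
    until adding one more would reach the budget, so every chunk carries at
    most ``max_tokens - 1`` tokens. Single tokens are never split; chunk
    texts are the tokens joined by single spaces. Empty documents produce
    zero chunks.
    """
    if max_tokens < 1:
        raise ValueError(f"max_tokens must be >= 1, got {max_tokens}")
    tokens = tokenizer(doc.raw_text)
    if not tokens:
        return []
    capacity = max_tokens - 1
    if capacity < 1:
        raise ValueError("max_tokens=1 leaves no room for any token")
    chunks: list[Chunk] = []
    for start in range(0, len(tokens), capacity):
        piece = tokens[start : start + capacity]
        chunks.append(
            Chunk(
                article_id=doc.article_id,
                chunk_index=len(chunks),
                text=" ".join(piece),
                token_count=len(piece),
            )
        )
    return chunks


def chunk_corpus(
    docs: Iterable[Document],
    max_tokens: int = DEFAULT_MAX_TOKENS,
    tokenizer: Tokenizer = whitespace_tokenizer,
) -> dict[str, list[Chunk]]:
    """Chunk every document; returns article_id -> chunks."""
    return {d.article_id: chunk_document(d, max_tokens, tokenizer) for d in docs}
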