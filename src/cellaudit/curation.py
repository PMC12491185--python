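"""Post-processing of raw extraction output.

Two steps, applied per article:

* **grounding filter** — drop predicted names that do not literally occur
  in their source chunk (after case/whitespace normalization). This is the
  anti-hallucination step: a backend can only keep what the text supports.
* **clustering** — group duplicates and near-identical surface forms
  (case, hyphenation) by single-linkage over normalized-Levenshtein
  similarity, so one cell line referenced under several spellings counts
  as one predicted name while every member mention still yields its own
  incidence downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .extraction import Mention
from .lexicon_match import normalize_name, similarity

__all__ = [
    "MentionCluster",
    "GroundingError",
    "grounding_filter",
    "cluster_mentions",
    "curate",
]

#: similarity at or above which two surface forms are linked into a cluster;
#: merges case/punctuation variants (MCF7 / MCF-7) without merging distinct
#: lines (HeLa / HeLa S3)
DEFAULT_CLUSTER_THRESHOLD = 0.8


class GroundingError(KeyError):
    """A mention's chunk_index does not resolve to any chunk."""


@dataclass(frozen=True)
class MentionCluster:
    """A group of near-identical mentions with a canonical surface form."""

    canonical: str
    members: tuple[Mention, ...]

    @property
    def count(self) -> int:
        return len(self.members)


def _chunk_texts(chunks) -> Mapping[int, str]:
    if isinstance(chunks, Mapping):
        return chunks
    return {c.chunk_index: c.text for c in chunks}


def grounding_filter(
    mentions: Sequence[Mention],
    chunks,
    word_boundary: bool = False,
) -> list[Mention]:
    """Keep only mentions whose normalized surface occurs in the normalized
    text of their own chunk; order is preserved.

    ``chunks`` is a mapping chunk_index -> text, or a sequence of Chunk.
    ``word_boundary=True`` additionally requires the occurrence not to sit
    inside a longer alphanumeric token.
    """
    texts = _chunk_texts(chunks)
    kept: list[Mention] = []
    for m in mentions:
        if m.chunk_index not in texts:
            raise GroundingError(
                f"mention {m.surface_text!r} points at missing chunk "
                f"{m.chunk_index} of article {m.article_id}"
            )
        haystack = normalize_name(texts[m.chunk_index])
        needle = normalize_name(m.surface_text)
        if word_boundary:
            pattern = rf"(?<![0-9a-z]){re.escape(needle)}(?![0-9a-z])"
            hit = re.search(pattern, haystack) is not None
        else:
            hit = needle in haystack
        if hit:
            kept.append(m)
    return kept


def cluster_mentions(
    mentions: Sequence[Mention],
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> list[MentionCluster]:
    """Single-linkage clustering of mentions over normalized surface forms.

    Two distinct surface forms are linked when their similarity is at or
    above ``cluster_threshold``; clusters are the connected components, so
    they partition the input. The canonical form is the most frequent
    member surface, ties broken by longest then lexicographically smallest.
    Deterministic and independent of input order.
    """
    if not mentions:
        return []
    forms = sorted({normalize_name(m.surface_text) for m in mentions})
    parent = {f: f for f in forms}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            # deterministic root: lexicographically smallest
            if rb < ra:
                ra, rb = rb, ra
            parent[rb] = ra

    for i, a in enumerate(forms):
        for b in forms[i + 1 :]:
            if similarity(a, b) >= cluster_threshold:
                union(a, b)

    groups: dict[str, list[Mention]] = {}
    for m in mentions:
        groups.setdefault(find(normalize_name(m.surface_text)), []).append(m)

    clusters: list[MentionCluster] = []
    for root in sorted(groups):
        members = groups[root]
        counts: dict[str, int] = {}
        for m in members:
            counts[m.surface_text] = counts.get(m.surface_text, 0) + 1
        canonical = max(counts, key=lambda s: (counts[s], len(s), _RevStr(s)))
        clusters.append(MentionCluster(canonical=canonical, members=tuple(members)))
    return clusters


class _RevStr(str):
    """Reverse-ordered str: lets 'lexicographically smallest' win in max()."""

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)


def curate(
    raw: Sequence[Mention],
    chunks,
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    word_boundary: bool = False,
) -> list[MentionCluster]:
    """Grounding filter followed by clustering.

    Downstream, one incidence is produced per cluster *member* (every
    mention counts), while "extra output" accounting counts clusters.
    """
    grounded = grounding_filter(raw, chunks, word_boundary=word_boundary)
    return cluster_mentions(grounded, cluster_threshold=cluster_threshold)
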