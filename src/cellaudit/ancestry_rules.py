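"""Ancestry categorization and reporting-practice classification.

Every retained mention of a human cell line or primary culture becomes one
*incidence*. For each incidence three questions are answered:

1. Which ancestry group, under two parallel schemes — US-census labels
   (Black or African American, White, Asian, Native Hawaiian or Pacific
   Islander, American Indian, Two or more races) and genotyping-study labels
   (African, European, Central/South Asian, East Asian, Mixed Ancestry) —
   plus the verbatim descriptor as written in the source.
2. Where the answer came from: the article text itself (``in_text``), a
   secondary knowledge-base lookup (``web``), or nowhere (``none``).
3. The reporting practice: *reported* (ancestry stated in the article),
   *available* (traceable only through a secondary source), or
   *not_available* (indiscernible from either).

Knowledge-base entries may carry a fractional ancestry breakdown; the
assigned group is the one whose fraction strictly exceeds 60%, otherwise
the incidence is categorized as Two or more races / Mixed Ancestry. The
descriptor-to-group mapping is shipped as an editable TSV; descriptors it
does not cover map to Unknown rather than being guessed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .extraction import AncestryStatement, Mention
from .lexicon_match import CellLineRecord, MatchResult, normalize_name

__all__ = [
    "ReportingPractice",
    "AncestryAssignment",
    "Incidence",
    "CENSUS_GROUPS",
    "GENOTYPE_GROUPS",
    "UNKNOWN",
    "assign_majority",
    "majority_label",
    "map_label",
    "classify_incidence",
    "article_practices",
]

logger = logging.getLogger(__name__)

CENSUS_GROUPS = (
    "Black or African American",
    "White",
    "Asian",
    "Native Hawaiian or Pacific Islander",
    "American Indian",
    "Two or more races",
)
GENOTYPE_GROUPS = (
    "African",
    "European",
    "Central/South Asian",
    "East Asian",
    "Mixed Ancestry",
)
UNKNOWN = "Unknown"
MIXED = {"census": "Two or more races", "genotype": "Mixed Ancestry"}

#: a breakdown fraction must strictly exceed this to be the assigned ancestry
DEFAULT_MAJORITY_THRESHOLD = 0.6


class ReportingPractice(str, Enum):
    """How an article handles the ancestry of one incidence."""

    REPORTED = "reported"
    AVAILABLE = "available"
    NOT_AVAILABLE = "not_available"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class AncestryAssignment:
    """The three-way ancestry record for one incidence."""

    census_group: str = UNKNOWN
    genotype_group: str = UNKNOWN
    verbatim_label: str = ""
    source: str = "none"  # in_text | web | none

    def __post_init__(self) -> None:
        if self.source not in ("in_text", "web", "none"):
            raise ValueError(f"bad source {self.source!r}")
        if self.source == "none" and (
            self.census_group != UNKNOWN or self.genotype_group != UNKNOWN
        ):
            raise ValueError("source 'none' requires both groups Unknown")
        if self.source == "in_text" and not self.verbatim_label:
            raise ValueError("source 'in_text' requires a verbatim label")


@dataclass(frozen=True)
class Incidence:
    """One occurrence of human cell/tissue use in one article."""

    article_id: str
    surface_text: str
    culture_kind: str  # cell_line | primary | unspecified
    assignment: AncestryAssignment
    practice: ReportingPractice
    match: MatchResult | None = None
    chunk_index: int = 0


@lru_cache(maxsize=1)
def _mapping_table() -> dict[str, tuple[str, str]]:
    """Casefolded descriptor -> (census_group, genotype_group)."""
    table: dict[str, tuple[str, str]] = {}
    src = resources.files("cellaudit.data") / "ancestry_map.tsv"
    with src.open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[normalize_name(row["verbatim_label"])] = (
                row["census_group"],
                row["genotype_group"],
            )
    return table


def map_label(verbatim: str, scheme: str) -> str:
    """Map a verbatim ancestry descriptor to a group label.

    Lookup is case-insensitive in the shipped mapping TSV. Descriptors the
    table does not cover return ``Unknown`` with a logged warning — never a
    silent guess.
    """
    if scheme not in ("census", "genotype"):
        raise ValueError(f"scheme must be 'census' or 'genotype', got {scheme!r}")
    key = normalize_name(verbatim)
    if not key:
        return UNKNOWN
    entry = _mapping_table().get(key)
    if entry is None:
        logger.warning("unmapped ancestry descriptor %r -> Unknown", verbatim)
        return UNKNOWN
    return entry[0] if scheme == "census" else entry[1]


def majority_label(
    breakdown: Mapping[str, float],
    threshold: float = DEFAULT_MAJORITY_THRESHOLD,
) -> str | None:
    """The label whose fraction strictly exceeds ``threshold``, or None if no
    label does (including an exact tie at the threshold)."""
    for label, frac in breakdown.items():
        if frac > threshold:
            return label
    return None


def assign_majority(
    breakdown: Mapping[str, float],
    threshold: float = DEFAULT_MAJORITY_THRESHOLD,
    scheme: str = "genotype",
) -> str:
    """Assign an ancestry group from a fractional breakdown.

    A label with fraction strictly greater than ``threshold`` (default 60%)
    wins and is mapped into ``scheme``; otherwise the scheme's mixed category
    (Two or more races / Mixed Ancestry) is returned. A fraction exactly at
    the threshold does *not* win. Empty breakdown -> Unknown.
    """
    if not breakdown:
        return UNKNOWN
    winner = majority_label(breakdown, threshold)
    if winner is None:
        return MIXED[scheme]
    return map_label(winner, scheme)


def _assignment_from_breakdown(
    record: CellLineRecord, threshold: float
) -> AncestryAssignment:
    breakdown = record.ancestry_breakdown
    winner = majority_label(breakdown, threshold)
    verbatim = record.verbatim_label or (winner if winner else MIXED["genotype"])
    return AncestryAssignment(
        census_group=assign_majority(breakdown, threshold, "census"),
        genotype_group=assign_majority(breakdown, threshold, "genotype"),
        verbatim_label=verbatim,
        source="web",
    )


def classify_incidence(
    mention: Mention,
    statements: Sequence[AncestryStatement],
    match: MatchResult | None,
    lexicon_record: CellLineRecord | None,
    majority_threshold: float = DEFAULT_MAJORITY_THRESHOLD,
) -> Incidence:
    """Turn one retained mention into an Incidence.

    Decision order:

    1. an in-text ancestry statement for this mention → practice *reported*,
       groups mapped from the verbatim descriptor, source ``in_text``;
    2. else a matched lexicon record with a non-empty ancestry breakdown →
       practice *available*, groups via the >60% majority rule, source
       ``web``;
    3. else practice *not_available*, both groups Unknown, source ``none``
       (this is where primary cultures with no catalogue ancestry and no
       in-text statement land).
    """
    own = [
        s
        for s in statements
        if normalize_name(s.mention_surface) == normalize_name(mention.surface_text)
        and s.chunk_index == mention.chunk_index
    ]
    if own:
        verbatim = own[0].verbatim_label
        assignment = AncestryAssignment(
            census_group=map_label(verbatim, "census"),
            genotype_group=map_label(verbatim, "genotype"),
            verbatim_label=verbatim,
            source="in_text",
        )
        practice = ReportingPractice.REPORTED
    elif (
        match is not None
        and match.matched
        and lexicon_record is not None
        and lexicon_record.ancestry_breakdown
    ):
        assignment = _assignment_from_breakdown(lexicon_record, majority_threshold)
        practice = ReportingPractice.AVAILABLE
    else:
        assignment = AncestryAssignment()
        practice = ReportingPractice.NOT_AVAILABLE
    return Incidence(
        article_id=mention.article_id,
        surface_text=mention.surface_text,
        culture_kind=mention.culture_kind,
        assignment=assignment,
        practice=practice,
        match=match,
        chunk_index=mention.chunk_index,
    )


def article_practices(incidences: Iterable[Incidence]) -> set[ReportingPractice]:
    """The set of reporting practices exhibited by one article — articles can
    possess more than one when ancestry is traceable for some samples but
    not others. All incidences must share one article_id."""
    incidences = list(incidences)
    ids = {inc.article_id for inc in incidences}
    if len(ids) > 1:
        raise ValueError(f"incidences span multiple articles: {sorted(ids)}")
    return {inc.practice for inc in incidences}
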