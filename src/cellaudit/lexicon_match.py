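"""Cell-line lexicon loading and fuzzy entity linking.

Extracted culture names rarely match a knowledge-base entry verbatim
("MCF7" vs "MCF-7", casing, stray whitespace), so mentions are resolved
against a Cellosaurus-style lexicon by *normalized Levenshtein similarity*:

    sim(a, b) = 1 - lev(norm(a), norm(b)) / max(|norm(a)|, |norm(b)|)

where ``norm`` casefolds and collapses whitespace but deliberately keeps
hyphens and digits — cell-line identities hang on them (HEK-293 vs HEK-293T).
A mention links to the record with the highest similarity over canonical
names and synonyms, provided it exceeds the 50% threshold; otherwise it is
left unlinked and no ancestry can be looked up for it.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CellLineRecord",
    "MatchResult",
    "LexiconError",
    "levenshtein",
    "normalize_name",
    "similarity",
    "best_match",
    "load_lexicon",
    "save_lexicon",
]

#: strict lower bound on similarity for a lexicon link (">50%")
DEFAULT_MATCH_THRESHOLD = 0.5

_FRACTION_SLACK = 1e-9

_CULTURE_KINDS = ("cell_line", "primary")


class LexiconError(ValueError):
    """Raised for malformed lexicon files or records."""


@dataclass(frozen=True)
class CellLineRecord:
    """One knowledge-base entry: a catalogued cell line or primary culture.

    ``ancestry_breakdown`` maps population labels to fractions in [0, 1]
    (e.g. ``{"European": 0.7, "African": 0.3}``); empty means the source
    records no donor ancestry. ``verbatim_label`` is the source's own
    descriptor string, if any.
    """

    accession: str
    canonical_name: str
    synonyms: tuple[str, ...] = ()
    culture_kind: str = "cell_line"
    ancestry_breakdown: dict[str, float] = field(default_factory=dict)
    verbatim_label: str = ""

    def __post_init__(self) -> None:
        if not self.canonical_name or not self.canonical_name.strip():
            raise LexiconError(f"record {self.accession!r}: empty canonical_name")
        if self.culture_kind not in _CULTURE_KINDS:
            raise LexiconError(
                f"record {self.accession!r}: culture_kind must be one of "
                f"{_CULTURE_KINDS}, got {self.culture_kind!r}"
            )
        total = 0.0
        for label, frac in self.ancestry_breakdown.items():
            if not (0.0 <= frac <= 1.0):
                raise LexiconError(
                    f"record {self.accession!r}: fraction {frac!r} for "
                    f"{label!r} outside [0, 1]"
                )
            total += frac
        if total > 1.0 + _FRACTION_SLACK:
            raise LexiconError(
                f"record {self.accession!r}: ancestry fractions sum to "
                f"{total:.6f} > 1"
            )

    @property
    def all_names(self) -> tuple[str, ...]:
        return (self.canonical_name, *self.synonyms)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of linking one query string against the lexicon."""

    query: str
    matched_name: str
    accession: str | None
    similarity: float
    matched: bool


def levenshtein(a: str, b: str) -> int:
    """Edit distance: minimum single-character insertions, deletions and
    substitutions turning ``a`` into ``b`` (classic dynamic programme,
    two-row, O(len(a)*len(b)))."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):  # iterate over the longer string, row = shorter
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(
                    prev[j] + 1,  # deletion
                    cur[j - 1] + 1,  # insertion
                    prev[j - 1] + (ca != cb),  # substitution
                )
            )
        prev = cur
    return prev[-1]


_WS_RUN = re.compile(r"\s+")


def normalize_name(s: str) -> str:
    """Casefold, strip, and collapse internal whitespace runs to one space.

    Hyphens, digits and all punctuation survive: cell-line names are
    distinguished by them.
    """
    return _WS_RUN.sub(" ", s.casefold().strip())


def similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity in [0, 1] after name normalization.

    1.0 iff the normalized strings are equal (both empty counts as equal).
    """
    na, nb = normalize_name(a), normalize_name(b)
    longer = max(len(na), len(nb))
    if longer == 0:
        return 1.0
    return 1.0 - levenshtein(na, nb) / longer


def best_match(
    query: str,
    lexicon: Sequence[CellLineRecord],
    match_threshold: float = DEFAULT_MATCH_THRESHOLD,
) -> MatchResult:
    """Link ``query`` to the closest lexicon record by similarity.

    Every canonical name and synonym of every record is a candidate; the
    maximum similarity wins. Ties break on (longer candidate name, then
    lexicographically smallest accession) so the result is independent of
    lexicon order. ``matched`` requires similarity strictly above
    ``match_threshold``; unmatched results carry ``accession=None``.
    """
    best_sim = -1.0
    best_name = ""
    best_acc: str | None = None
    for rec in lexicon:
        for name in rec.all_names:
            sim = similarity(query, name)
            if sim > best_sim:
                better = True
            elif sim == best_sim:
                better = (len(name), _neg_lex(rec.accession)) > (
                    len(best_name),
                    _neg_lex(best_acc or ""),
                )
            else:
                better = False
            if better:
                best_sim, best_name, best_acc = sim, name, rec.accession
    if best_sim < 0.0:  # empty lexicon
        return MatchResult(query, "", None, 0.0, False)
    matched = best_sim > match_threshold
    return MatchResult(
        query=query,
        matched_name=best_name,
        accession=best_acc if matched else None,
        similarity=best_sim,
        matched=matched,
    )


class _neg_lex(str):
    """str whose ordering is reversed — lets 'smallest accession wins' sit
    inside a max-style tuple comparison."""

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)


# ---------------------------------------------------------------------------
# lexicon file I/O

_TSV_COLUMNS = (
    "accession",
    "canonical_name",
    "synonyms",
    "culture_kind",
    "ancestry_breakdown",
    "verbatim_label",
)


def _record_from_dict(d: dict, where: str) -> CellLineRecord:
    if not isinstance(d, dict):
        raise LexiconError(f"{where}: record is not an object")
    unknown = set(d) - set(_TSV_COLUMNS)
    if unknown:
        raise LexiconError(f"{where}: unknown fields {sorted(unknown)}")
    for key in ("accession", "canonical_name"):
        if key not in d or not isinstance(d[key], str):
            raise LexiconError(f"{where}: missing or non-string {key!r}")
    syns = d.get("synonyms", [])
    if not (isinstance(syns, list) and all(isinstance(s, str) for s in syns)):
        raise LexiconError(f"{where}: synonyms must be a list of strings")
    breakdown = d.get("ancestry_breakdown", {})
    if not isinstance(breakdown, dict):
        raise LexiconError(f"{where}: ancestry_breakdown must be an object")
    clean: dict[str, float] = {}
    for label, frac in breakdown.items():
        if not isinstance(frac, (int, float)) or isinstance(frac, bool):
            raise LexiconError(f"{where}: fraction for {label!r} is not a number")
        clean[str(label)] = float(frac)
    try:
        return CellLineRecord(
            accession=d["accession"],
            canonical_name=d["canonical_name"],
            synonyms=tuple(syns),
            culture_kind=d.get("culture_kind", "cell_line"),
            ancestry_breakdown=clean,
            verbatim_label=d.get("verbatim_label", ""),
        )
    except LexiconError:
        raise
    except ValueError as exc:  # pragma: no cover - defensive
        raise LexiconError(f"{where}: {exc}") from exc


def _parse_breakdown_field(text: str, where: str) -> dict[str, float]:
    """'European:0.7;African:0.3' -> {'European': 0.7, 'African': 0.3}"""
    breakdown: dict[str, float] = {}
    if not text:
        return breakdown
    for part in text.split(";"):
        label, sep, frac = part.rpartition(":")
        if not sep or not label:
            raise LexiconError(f"{where}: malformed breakdown part {part!r}")
        try:
            breakdown[label] = float(frac)
        except ValueError as exc:
            raise LexiconError(f"{where}: non-numeric fraction in {part!r}") from exc
    return breakdown


def load_lexicon(path: str | Path) -> list[CellLineRecord]:
    """Load a lexicon from JSON (a list of record objects) or TSV.

    Record invariants are enforced and duplicate accessions rejected; errors
    name the offending record.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise LexiconError(f"{path}: top level must be a JSON array")
        records = [
            _record_from_dict(d, f"{path} record #{i}") for i, d in enumerate(data)
        ]
    else:
        records = []
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or set(reader.fieldnames) != set(_TSV_COLUMNS):
                raise LexiconError(
                    f"{path}: TSV header must be exactly {list(_TSV_COLUMNS)}"
                )
            for i, row in enumerate(reader):
                where = f"{path} row #{i}"
                records.append(
                    _record_from_dict(
                        {
                            "accession": row["accession"],
                            "canonical_name": row["canonical_name"],
                            "synonyms": [
                                s for s in (row["synonyms"] or "").split("|") if s
                            ],
                            "culture_kind": row["culture_kind"] or "cell_line",
                            "ancestry_breakdown": _parse_breakdown_field(
                                row["ancestry_breakdown"] or "", where
                            ),
                            "verbatim_label": row["verbatim_label"] or "",
                        },
                        where,
                    )
                )
    seen: set[str] = set()
    for rec in records:
        if rec.accession in seen:
            raise LexiconError(f"{path}: duplicate accession {rec.accession!r}")
        seen.add(rec.accession)
    return records


def save_lexicon(records: Iterable[CellLineRecord], path: str | Path) -> Path:
    """Write records as JSON or TSV (chosen by extension); inverse of
    :func:`load_lexicon`."""
    path = Path(path)
    records = list(records)
    if path.suffix.lower() == ".json":
        payload = [
            {
                "accession": r.accession,
                "canonical_name": r.canonical_name,
                "synonyms": list(r.synonyms),
                "culture_kind": r.culture_kind,
                "ancestry_breakdown": r.ancestry_breakdown,
                "verbatim_label": r.verbatim_label,
            }
            for r in records
        ]
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n", "utf-8")
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(_TSV_COLUMNS)
            for r in records:
                writer.writerow(
                    [
                        r.accession,
                        r.canonical_name,
                        "|".join(r.synonyms),
                        r.culture_kind,
                        ";".join(
                            f"{label}:{frac:g}"
                            for label, frac in r.ancestry_breakdown.items()
                        ),
                        r.verbatim_label,
                    ]
                )
    return path
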