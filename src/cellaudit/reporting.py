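"""Results table and corpus-level summaries.

The per-incidence results table has seven fixed columns — article id, the
cell culture found in the text, the name the knowledge-base lookup
resolved it to, whether ancestry is available, the reported/available/
not-available decision, the ancestry descriptor extracted from the text,
and the ancestry found via the knowledge base — laid out for side-by-side
validation against the source.

Corpus summaries aggregate reporting practices at the article level
(articles can fall under several practices, so percentages may sum past
100), incidence counts by culture kind, and ancestry-group distributions
under both the census and genotyping schemes, overall and split by
culture kind.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ancestry_rules import (
    CENSUS_GROUPS,
    GENOTYPE_GROUPS,
    Incidence,
    ReportingPractice,
    UNKNOWN,
    article_practices,
)

__all__ = [
    "RESULTS_COLUMNS",
    "CorpusSummary",
    "write_results",
    "results_dataframe",
    "summarize",
    "share_among_ascertainable",
    "round_pct",
]

RESULTS_COLUMNS = (
    "article_id",
    "cell_culture_found",
    "cell_name_identified_on_web",
    "ancestry_available",
    "reported_decision",
    "ancestry_identified_by_extraction",
    "ancestry_found_on_web",
)

CULTURE_KINDS = ("cell_line", "primary", "unspecified")


def round_pct(value: float, places: int = 1) -> float:
    """Round half away from zero, to one decimal by default."""
    q = Decimal(10) ** -places
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _incidence_row(inc: Incidence) -> dict[str, str]:
    matched = inc.match is not None and inc.match.matched
    src = inc.assignment.source
    return {
        "article_id": inc.article_id,
        "cell_culture_found": inc.surface_text,
        "cell_name_identified_on_web": inc.match.matched_name if matched else "",
        "ancestry_available": "yes"
        if inc.practice
        in (ReportingPractice.REPORTED, ReportingPractice.AVAILABLE)
        else "no",
        "reported_decision": inc.practice.value,
        "ancestry_identified_by_extraction": inc.assignment.verbatim_label
        if src == "in_text"
        else "",
        "ancestry_found_on_web": inc.assignment.verbatim_label
        if src == "web"
        else "",
    }


def _sorted_incidences(incidences: Iterable[Incidence]) -> list[Incidence]:
    return sorted(
        incidences, key=lambda i: (i.article_id, i.chunk_index, i.surface_text)
    )


def write_results(incidences: Iterable[Incidence], path: str | Path) -> Path:
    """Write the seven-column results CSV, one row per incidence, in
    deterministic (article_id, chunk_index, surface_text) order."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=RESULTS_COLUMNS, lineterminator="\n"
        )
        writer.writeheader()
        for inc in _sorted_incidences(incidences):
            writer.writerow(_incidence_row(inc))
    return path


def results_dataframe(incidences: Iterable[Incidence]) -> pd.DataFrame:
    """The results table as a DataFrame with the fixed column order."""
    rows = [_incidence_row(i) for i in _sorted_incidences(incidences)]
    return pd.DataFrame(rows, columns=list(RESULTS_COLUMNS))


@dataclass
class CorpusSummary:
    """Aggregate statistics over one corpus.

    Percentages are rounded to one decimal (half away from zero); None
    marks an undefined percentage (empty denominator). Article-level
    percentages use the number of included articles as denominator and may
    sum past 100 because one article can exhibit several practices.
    """

    n_articles: int
    total_incidences: int
    practice_article_counts: dict[str, int]
    practice_article_pct: dict[str, float | None]
    culture_kind_counts: dict[str, int]
    census_counts: dict[str, int]
    census_pct: dict[str, float | None]
    genotype_counts: dict[str, int]
    genotype_pct: dict[str, float | None]
    by_kind_genotype_counts: dict[str, dict[str, int]]
    top_cell_names: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def to_markdown(self) -> str:
        lines = [
            f"articles: {self.n_articles}; incidences: {self.total_incidences}",
            "",
            "| practice | articles | % of articles |",
            "|---|---|---|",
        ]
        for p, n in self.practice_article_counts.items():
            pct = self.practice_article_pct[p]
            lines.append(f"| {p} | {n} | {'-' if pct is None else pct} |")
        lines += ["", "| genotype group | incidences | % |", "|---|---|---|"]
        for g, n in self.genotype_counts.items():
            pct = self.genotype_pct[g]
            lines.append(f"| {g} | {n} | {'-' if pct is None else pct} |")
        return "\n".join(lines)


def summarize(
    incidences: Sequence[Incidence],
    articles: Sequence[str],
    top_k: int = 10,
) -> CorpusSummary:
    """Aggregate incidences into a :class:`CorpusSummary`.

    ``articles`` is the full list of included article ids (denominator for
    article-level percentages — it may include articles that yielded no
    incidences). Pure: identical inputs give identical summaries.
    """
    incidences = list(incidences)
    n_articles = len(articles)
    total = len(incidences)

    by_article: dict[str, list[Incidence]] = {}
    for inc in incidences:
        by_article.setdefault(inc.article_id, []).append(inc)

    practice_counts = {p.value: 0 for p in ReportingPractice}
    for aid, incs in by_article.items():
        for p in article_practices(incs):
            practice_counts[p.value] += 1
    practice_pct = {
        p: (round_pct(100.0 * n / n_articles) if n_articles else None)
        for p, n in practice_counts.items()
    }

    kind_counts = {k: 0 for k in CULTURE_KINDS}
    census_counts = {g: 0 for g in (*CENSUS_GROUPS, UNKNOWN)}
    genotype_counts = {g: 0 for g in (*GENOTYPE_GROUPS, UNKNOWN)}
    by_kind_genotype = {
        k: {g: 0 for g in (*GENOTYPE_GROUPS, UNKNOWN)} for k in CULTURE_KINDS
    }
    name_counts: dict[str, int] = {}
    name_groups: dict[str, tuple[str, str]] = {}
    for inc in incidences:
        kind_counts[inc.culture_kind] += 1
        census_counts[inc.assignment.census_group] += 1
        genotype_counts[inc.assignment.genotype_group] += 1
        by_kind_genotype[inc.culture_kind][inc.assignment.genotype_group] += 1
        name_counts[inc.surface_text] = name_counts.get(inc.surface_text, 0) + 1
        name_groups.setdefault(
            inc.surface_text,
            (inc.assignment.census_group, inc.assignment.genotype_group),
        )

    def pct_map(counts: dict[str, int]) -> dict[str, float | None]:
        return {
            g: (round_pct(100.0 * n / total) if total else None)
            for g, n in counts.items()
        }

    top = sorted(name_counts, key=lambda s: (-name_counts[s], s))[:top_k]
    top_cell_names = [
        {
            "name": s,
            "count": name_counts[s],
            "census_group": name_groups[s][0],
            "genotype_group": name_groups[s][1],
        }
        for s in top
    ]

    return CorpusSummary(
        n_articles=n_articles,
        total_incidences=total,
        practice_article_counts=practice_counts,
        practice_article_pct=practice_pct,
        culture_kind_counts=kind_counts,
        census_counts=census_counts,
        census_pct=pct_map(census_counts),
        genotype_counts=genotype_counts,
        genotype_pct=pct_map(genotype_counts),
        by_kind_genotype_counts=by_kind_genotype,
        top_cell_names=top_cell_names,
    )


def share_among_ascertainable(
    overall_share_pct: float, unreported_share_pct: float
) -> float:
    """Rescale an overall group share to the ascertainable subset.

    E.g. a group holding 39.2% of all samples while 47% of samples have no
    ascertainable ancestry holds 39.2 / (100 - 47) * 100 ≈ 74% of the
    ascertainable ones.
    """
    denom = 100.0 - unreported_share_pct
    if denom <= 0:
        raise ValueError("unreported share leaves no ascertainable samples")
    return 100.0 * overall_share_pct / denom
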