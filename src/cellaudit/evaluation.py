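"""Scoring pipeline predictions against a manually curated reference.

Within each article, predicted names are assigned one-to-one to reference
names greedily in descending similarity order; pairs below the good-match
threshold (50%, inclusive) are never assigned. From the assignment:

* **exact matches** — assigned pairs identical after normalization;
* **good matches** — all assigned pairs; rate over the reference size;
* **overall similarity** — mean over *all* predictions of the similarity
  to their closest reference name in the same article (0–100 scale);
* **ancestry accuracy** — among assigned pairs whose reference carries an
  ancestry label, the fraction whose predicted label maps to the same
  genotyping-scheme group as the reference label;
* **extra outputs** — predictions left unassigned.

When the pipeline also carries a reporting-practice label per prediction,
practice agreement over assigned pairs is reported as well.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .ancestry_rules import ReportingPractice, map_label
from .lexicon_match import normalize_name, similarity

__all__ = [
    "ReferenceRecord",
    "PredictedEntry",
    "MatchedPair",
    "Assignment",
    "EvaluationReport",
    "load_reference",
    "save_reference",
    "match_predictions",
    "score",
    "evaluate",
]

#: inclusive similarity threshold for a "good match" (>=50%)
DEFAULT_GOOD_THRESHOLD = 0.5


@dataclass(frozen=True)
class ReferenceRecord:
    """One human-curated ground-truth row."""

    article_id: str
    cell_name: str
    ancestry_label: str = ""  # empty = not determined
    practice: str = ""  # reported | available | not_available | ""

    def __post_init__(self) -> None:
        if not self.cell_name.strip():
            raise ValueError("reference cell_name must be non-empty")


@dataclass(frozen=True)
class PredictedEntry:
    """One pipeline prediction: a (curated) name with optional ancestry and
    practice labels carried along for accuracy scoring."""

    article_id: str
    name: str
    ancestry_label: str = ""
    practice: str | None = None


@dataclass(frozen=True)
class MatchedPair:
    prediction_index: int
    reference_index: int
    similarity: float


@dataclass(frozen=True)
class Assignment:
    """Outcome of the per-article greedy one-to-one matching."""

    pairs: tuple[MatchedPair, ...]
    extra_prediction_indices: tuple[int, ...]
    unmatched_reference_indices: tuple[int, ...]


@dataclass
class EvaluationReport:
    """Aggregate scores; rates are percentages, None marks an undefined
    value (e.g. any rate on an empty reference)."""

    n_reference: int
    n_predictions: int
    exact_matches: int
    good_matches: int
    good_match_rate: float | None
    overall_similarity: float | None
    ancestry_accuracy: float | None
    extra_outputs: int
    practice_agreement: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def __str__(self) -> str:
        def fmt(v):
            return "undefined" if v is None else (f"{v:.2f}" if isinstance(v, float) else v)

        return (
            f"reference rows      {self.n_reference}\n"
            f"predictions         {self.n_predictions}\n"
            f"exact matches       {self.exact_matches}\n"
            f"good matches        {self.good_matches}"
            f" (rate {fmt(self.good_match_rate)})\n"
            f"overall similarity  {fmt(self.overall_similarity)}\n"
            f"ancestry accuracy   {fmt(self.ancestry_accuracy)}\n"
            f"practice agreement  {fmt(self.practice_agreement)}\n"
            f"extra outputs       {self.extra_outputs}"
        )


def load_reference(path: str | Path) -> list[ReferenceRecord]:
    """Read a curated reference CSV (article_id, cell_name, ancestry_label,
    practice)."""
    records: list[ReferenceRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"article_id", "cell_name"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"reference {path} must have columns {sorted(required)}")
        for row in reader:
            records.append(
                ReferenceRecord(
                    article_id=row["article_id"],
                    cell_name=row["cell_name"],
                    ancestry_label=row.get("ancestry_label", "") or "",
                    practice=row.get("practice", "") or "",
                )
            )
    return records


def save_reference(records: Sequence[ReferenceRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["article_id", "cell_name", "ancestry_label", "practice"])
        for r in records:
            writer.writerow([r.article_id, r.cell_name, r.ancestry_label, r.practice])
    return path


def match_predictions(
    predictions: Sequence[PredictedEntry],
    reference: Sequence[ReferenceRecord],
    good_threshold: float = DEFAULT_GOOD_THRESHOLD,
) -> Assignment:
    """Greedy one-to-one assignment of predictions to reference rows.

    Candidate pairs are restricted to the same article, sorted by
    descending similarity with lexicographic tie-break on the
    (prediction name, reference name) pair, and consumed greedily; each
    reference row absorbs at most one prediction. Pairs below
    ``good_threshold`` are never assigned.
    """
    by_article: dict[str, tuple[list[int], list[int]]] = {}
    for i, p in enumerate(predictions):
        by_article.setdefault(p.article_id, ([], []))[0].append(i)
    for j, r in enumerate(reference):
        by_article.setdefault(r.article_id, ([], []))[1].append(j)

    pairs: list[MatchedPair] = []
    used_pred: set[int] = set()
    used_ref: set[int] = set()
    for article in sorted(by_article):
        pred_idx, ref_idx = by_article[article]
        candidates = []
        for i in pred_idx:
            for j in ref_idx:
                sim = similarity(predictions[i].name, reference[j].cell_name)
                if sim >= good_threshold:
                    candidates.append(
                        (-sim, predictions[i].name, reference[j].cell_name, i, j)
                    )
        for neg_sim, _, _, i, j in sorted(candidates):
            if i in used_pred or j in used_ref:
                continue
            used_pred.add(i)
            used_ref.add(j)
            pairs.append(MatchedPair(i, j, -neg_sim))
    extras = tuple(i for i in range(len(predictions)) if i not in used_pred)
    unmatched = tuple(j for j in range(len(reference)) if j not in used_ref)
    return Assignment(tuple(pairs), extras, unmatched)


def _closest_similarity(
    pred: PredictedEntry, reference: Sequence[ReferenceRecord]
) -> float:
    sims = [
        similarity(pred.name, r.cell_name)
        for r in reference
        if r.article_id == pred.article_id
    ]
    return max(sims, default=0.0)


def score(
    assignment: Assignment,
    predictions: Sequence[PredictedEntry],
    reference: Sequence[ReferenceRecord],
) -> EvaluationReport:
    """Compute the evaluation report from an assignment.

    An empty reference yields undefined (None) rates rather than zeros.
    """
    n_ref = len(reference)
    n_pred = len(predictions)
    exact = sum(
        1
        for p in assignment.pairs
        if normalize_name(predictions[p.prediction_index].name)
        == normalize_name(reference[p.reference_index].cell_name)
    )
    good = len(assignment.pairs)
    good_rate = 100.0 * good / n_ref if n_ref else None
    overall = (
        100.0 * sum(_closest_similarity(p, reference) for p in predictions) / n_pred
        if n_pred
        else None
    )

    anc_total = 0
    anc_agree = 0
    prac_total = 0
    prac_agree = 0
    for pair in assignment.pairs:
        pred = predictions[pair.prediction_index]
        ref = reference[pair.reference_index]
        if ref.ancestry_label.strip():
            anc_total += 1
            if map_label(pred.ancestry_label, "genotype") == map_label(
                ref.ancestry_label, "genotype"
            ):
                anc_agree += 1
        if ref.practice and pred.practice is not None:
            prac_total += 1
            pred_practice = (
                pred.practice.value
                if isinstance(pred.practice, ReportingPractice)
                else str(pred.practice)
            )
            if pred_practice == ref.practice:
                prac_agree += 1
    ancestry_accuracy = 100.0 * anc_agree / anc_total if anc_total else None
    practice_agreement = 100.0 * prac_agree / prac_total if prac_total else None

    report = EvaluationReport(
        n_reference=n_ref,
        n_predictions=n_pred,
        exact_matches=exact,
        good_matches=good,
        good_match_rate=good_rate,
        overall_similarity=overall,
        ancestry_accuracy=ancestry_accuracy,
        extra_outputs=len(assignment.extra_prediction_indices),
        practice_agreement=practice_agreement,
    )
    assert report.exact_matches <= report.good_matches <= n_ref
    return report


def evaluate(
    predictions: Sequence[PredictedEntry],
    reference: Sequence[ReferenceRecord],
    good_threshold: float = DEFAULT_GOOD_THRESHOLD,
) -> EvaluationReport:
    """Convenience: :func:`match_predictions` followed by :func:`score`."""
    return score(
        match_predictions(predictions, reference, good_threshold),
        predictions,
        reference,
    )
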