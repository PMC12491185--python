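"""End-to-end orchestration: documents in, incidence table out.

Per article: chunk the text, run the three-step extraction over each chunk
(identify, refine, ancestry), curate the retained mentions (grounding
filter + clustering), link each mention to the lexicon, and classify every
cluster member into an incidence. Evaluation-facing predictions are one
per cluster (the canonical form with the ancestry/practice of its
representative incidence), while the incidence table keeps one row per
mention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .ancestry_rules import Incidence, classify_incidence
from .corpus_io import Document, chunk_document
from .curation import DEFAULT_CLUSTER_THRESHOLD, MentionCluster, curate
from .evaluation import (
    EvaluationReport,
    PredictedEntry,
    ReferenceRecord,
    evaluate,
)
from .extraction import (
    AncestryStatement,
    CompletionBackend,
    Mention,
    extract_ancestry_statements,
    extract_mentions,
    refine_mentions,
)
from .lexicon_match import (
    CellLineRecord,
    DEFAULT_MATCH_THRESHOLD,
    best_match,
)
from .reporting import CorpusSummary, summarize, write_results

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds for one pipeline run."""

    max_tokens: int = 4000
    match_threshold: float = DEFAULT_MATCH_THRESHOLD  # strict > for linking
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD
    majority_threshold: float = 0.6
    grounding_word_boundary: bool = False


@dataclass
class PipelineResult:
    """Everything one run produced."""

    incidences: list[Incidence]
    clusters: dict[str, list[MentionCluster]]  # article_id -> clusters
    predictions: list[PredictedEntry]  # one per cluster
    raw_mentions: list[Mention]  # refined, pre-curation
    statements: list[AncestryStatement]
    article_ids: list[str]

    def write_results_csv(self, path: str | Path) -> Path:
        return write_results(self.incidences, path)

    def summary(self, top_k: int = 10) -> CorpusSummary:
        return summarize(self.incidences, self.article_ids, top_k=top_k)

    def evaluate(
        self, reference: Sequence[ReferenceRecord], good_threshold: float = 0.5
    ) -> EvaluationReport:
        return evaluate(self.predictions, reference, good_threshold)


def _prediction_label(inc: Incidence) -> str:
    src = inc.assignment.source
    if src == "in_text":
        return inc.assignment.verbatim_label
    if src == "web":
        return inc.assignment.genotype_group
    return ""


def run_pipeline(
    documents: Sequence[Document],
    lexicon: Sequence[CellLineRecord],
    backend: CompletionBackend,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run extraction, curation, linking and classification over a corpus."""
    by_accession = {r.accession: r for r in lexicon}
    all_incidences: list[Incidence] = []
    all_clusters: dict[str, list[MentionCluster]] = {}
    predictions: list[PredictedEntry] = []
    all_raw: list[Mention] = []
    all_statements: list[AncestryStatement] = []

    for doc in documents:
        chunks = chunk_document(doc, max_tokens=config.max_tokens)
        chunk_texts = {c.chunk_index: c.text for c in chunks}
        refined: list[Mention] = []
        statements: list[AncestryStatement] = []
        for chunk in chunks:
            candidates = extract_mentions(chunk, backend)
            kept = refine_mentions(candidates, chunk, backend)
            refined.extend(kept)
            statements.extend(extract_ancestry_statements(chunk, kept, backend))
        all_raw.extend(refined)
        all_statements.extend(statements)

        clusters = curate(
            refined,
            chunk_texts,
            cluster_threshold=config.cluster_threshold,
            word_boundary=config.grounding_word_boundary,
        )
        all_clusters[doc.article_id] = clusters

        match_cache: dict[str, tuple] = {}
        for cluster in clusters:
            rep_incidence: Incidence | None = None
            for member in cluster.members:
                key = member.surface_text.casefold()
                if key not in match_cache:
                    m = best_match(
                        member.surface_text, lexicon, config.match_threshold
                    )
                    match_cache[key] = (m, by_accession.get(m.accession or ""))
                match, record = match_cache[key]
                inc = classify_incidence(
                    member,
                    statements,
                    match,
                    record,
                    majority_threshold=config.majority_threshold,
                )
                all_incidences.append(inc)
                if rep_incidence is None and member.surface_text == cluster.canonical:
                    rep_incidence = inc
            if rep_incidence is None:  # canonical surface absent: first member
                rep_incidence = all_incidences[-1]
            predictions.append(
                PredictedEntry(
                    article_id=doc.article_id,
                    name=cluster.canonical,
                    ancestry_label=_prediction_label(rep_incidence),
                    practice=rep_incidence.practice.value,
                )
            )

    return PipelineResult(
        incidences=all_incidences,
        clusters=all_clusters,
        predictions=predictions,
        raw_mentions=all_raw,
        statements=all_statements,
        article_ids=[d.article_id for d in documents],
    )
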