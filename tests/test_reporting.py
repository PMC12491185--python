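"""Results table emission and corpus summaries."""

import csv

import pytest

from cellaudit.ancestry_rules import (
    AncestryAssignment,
    Incidence,
    ReportingPractice,
)
from cellaudit.lexicon_match import MatchResult
from cellaudit.reporting import (
    RESULTS_COLUMNS,
    results_dataframe,
    round_pct,
    share_among_ascertainable,
    summarize,
    write_results,
)


def _inc(
    article_id="art1",
    surface="HeLa",
    kind="cell_line",
    practice=ReportingPractice.AVAILABLE,
    census="Black or African American",
    genotype="African",
    verbatim="African",
    source="web",
    matched=True,
    chunk_index=0,
):
    assignment = (
        AncestryAssignment(census, genotype, verbatim, source)
        if source != "none"
        else AncestryAssignment()
    )
    match = MatchResult(surface, surface, "CVCL-X", 1.0, True) if matched else None
    return Incidence(article_id, surface, kind, assignment, practice, match, chunk_index)


class TestWriteResults:
    def test_header_only_for_no_incidences(self, tmp_path):
        path = write_results([], tmp_path / "r.csv")
        rows = list(csv.reader(path.open()))
        assert rows == [list(RESULTS_COLUMNS)]

    def test_single_available_incidence(self, tmp_path):
        path = write_results([_inc()], tmp_path / "r.csv")
        row = next(csv.DictReader(path.open()))
        assert row["reported_decision"] == "available"
        assert row["ancestry_available"] == "yes"
        assert row["ancestry_found_on_web"] == "African"
        assert row["ancestry_identified_by_extraction"] == ""

    def test_reported_incidence_fills_extraction_column(self, tmp_path):
        inc = _inc(
            practice=ReportingPractice.REPORTED,
            census="Asian",
            genotype="East Asian",
            verbatim="Han Chinese",
            source="in_text",
        )
        path = write_results([inc], tmp_path / "r.csv")
        row = next(csv.DictReader(path.open()))
        assert row["ancestry_identified_by_extraction"] == "Han Chinese"
        assert row["ancestry_found_on_web"] == ""

    def test_round_trip_preserves_fields(self, tmp_path):
        incs = [
            _inc(),
            _inc(
                surface="T cells",
                kind="primary",
                practice=ReportingPractice.NOT_AVAILABLE,
                source="none",
                matched=False,
            ),
        ]
        path = write_results(incs, tmp_path / "r.csv")
        rows = list(csv.DictReader(path.open()))
        assert [r["cell_culture_found"] for r in rows] == ["HeLa", "T cells"]
        assert rows[1]["ancestry_available"] == "no"
        assert rows[1]["cell_name_identified_on_web"] == ""

    def test_deterministic_row_order(self, tmp_path):
        incs = [
            _inc(article_id="b", surface="Z9"),
            _inc(article_id="a", surface="B2", chunk_index=1),
            _inc(article_id="a", surface="A1", chunk_index=1),
            _inc(article_id="a", surface="M5", chunk_index=0),
        ]
        df = results_dataframe(incs)
        assert list(df["cell_culture_found"]) == ["M5", "A1", "B2", "Z9"]
        assert list(df.columns) == list(RESULTS_COLUMNS)


class TestSummarize:
    def test_culture_kind_counts_sum_to_total(self):
        incs = (
            [_inc(surface=f"L{i}") for i in range(5)]
            + [_inc(surface=f"P{i}", kind="primary") for i in range(3)]
            + [_inc(surface="U0", kind="unspecified")]
        )
        s = summarize(incs, ["art1"])
        assert s.culture_kind_counts == {
            "cell_line": 5,
            "primary": 3,
            "unspecified": 1,
        }
        assert sum(s.culture_kind_counts.values()) == s.total_incidences == 9

    def test_printed_corpus_counts_reproduce_total(self):
        # the audited corpus: 510 cell lines + 218 primaries + 15 unspecified
        incs = (
            [_inc(surface=f"L{i}") for i in range(510)]
            + [_inc(surface=f"P{i}", kind="primary") for i in range(218)]
            + [_inc(surface=f"U{i}", kind="unspecified") for i in range(15)]
        )
        s = summarize(incs, [f"a{i}" for i in range(326)])
        assert s.total_incidences == 743

    def test_ancestry_groups_partition_incidences(self):
        incs = [
            _inc(surface="A"),
            _inc(surface="B", census="White", genotype="European", verbatim="European"),
            _inc(
                surface="C",
                practice=ReportingPractice.NOT_AVAILABLE,
                source="none",
                matched=False,
            ),
        ]
        s = summarize(incs, ["art1"])
        assert sum(s.genotype_counts.values()) == 3
        assert sum(s.census_counts.values()) == 3
        assert s.genotype_counts["Unknown"] == 1

    def test_article_practice_percentages_use_article_denominator(self):
        incs = [
            _inc(article_id="a1"),
            _inc(article_id="a1", surface="T cells", kind="primary",
                 practice=ReportingPractice.NOT_AVAILABLE, source="none",
                 matched=False),
            _inc(article_id="a2"),
        ]
        s = summarize(incs, ["a1", "a2", "a3", "a4"])
        assert s.practice_article_counts["available"] == 2
        assert s.practice_article_pct["available"] == 50.0
        assert s.practice_article_counts["not_available"] == 1

    def test_empty_corpus_undefined_percentages(self):
        s = summarize([], [])
        assert s.total_incidences == 0
        assert all(v is None for v in s.genotype_pct.values())
        assert all(v is None for v in s.practice_article_pct.values())

    def test_pure_function(self):
        incs = [_inc(), _inc(surface="X1")]
        assert summarize(incs, ["art1"]).to_dict() == summarize(incs, ["art1"]).to_dict()

    def test_top_k_ties_alphabetical(self):
        incs = [_inc(surface=s) for s in ["B1", "A1", "B1", "A1", "C1"]]
        s = summarize(incs, ["art1"], top_k=2)
        assert [t["name"] for t in s.top_cell_names] == ["A1", "B1"]


class TestShares:
    def test_ascertainable_share_matches_printed_value(self):
        # 39.2% overall White/European with 47% unreported -> ~74%
        assert round(share_among_ascertainable(39.2, 47.0)) == 74

    def test_all_unreported_rejected(self):
        with pytest.raises(ValueError):
            share_among_ascertainable(10.0, 100.0)

    def test_rounding_half_away_from_zero(self):
        assert round_pct(2.15) == 2.2
        assert round_pct(74.25) == 74.3
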