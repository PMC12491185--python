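"""Majority rule, descriptor mapping, incidence classification."""

import pytest

from cellaudit.ancestry_rules import (
    AncestryAssignment,
    ReportingPractice,
    article_practices,
    assign_majority,
    classify_incidence,
    map_label,
)
from cellaudit.extraction import AncestryStatement, Mention
from cellaudit.lexicon_match import CellLineRecord, MatchResult


class TestAssignMajority:
    @pytest.mark.parametrize(
        "breakdown,scheme,expected",
        [
            ({"European": 0.7, "African": 0.3}, "genotype", "European"),
            ({"European": 0.5, "African": 0.5}, "genotype", "Mixed Ancestry"),
            ({"Central/South Asian": 1.0}, "genotype", "Central/South Asian"),
            ({"European": 0.7, "African": 0.3}, "census", "White"),
            ({"European": 0.5, "African": 0.5}, "census", "Two or more races"),
        ],
    )
    def test_majority_rule(self, breakdown, scheme, expected):
        assert assign_majority(breakdown, scheme=scheme) == expected

    def test_fraction_exactly_at_threshold_is_mixed(self):
        # ">60%" is strict: 60% exactly does not win
        assert assign_majority({"European": 0.6, "African": 0.4}) == "Mixed Ancestry"

    def test_empty_breakdown_unknown(self):
        assert assign_majority({}) == "Unknown"

    def test_threshold_configurable(self):
        assert assign_majority({"European": 0.55}, threshold=0.5) == "European"


class TestMapLabel:
    @pytest.mark.parametrize(
        "verbatim,scheme,expected",
        [
            ("Han Chinese", "genotype", "East Asian"),
            ("Han Chinese", "census", "Asian"),
            ("han chinese", "census", "Asian"),  # case-insensitive
            ("Klingon", "census", "Unknown"),
            ("", "genotype", "Unknown"),
            ("African American", "genotype", "African"),
            ("Caucasian", "census", "White"),
        ],
    )
    def test_mapping(self, verbatim, scheme, expected):
        assert map_label(verbatim, scheme) == expected

    def test_bad_scheme_rejected(self):
        with pytest.raises(ValueError):
            map_label("European", "phenotype")


def _mention(surface="HeLa", kind="cell_line"):
    return Mention("art1", 0, surface, kind)


def _matched(query="HeLa", accession="CVCL-T001"):
    return MatchResult(query, query, accession, 1.0, True)


HELA = CellLineRecord(
    "CVCL-T001", "HeLa", (), "cell_line", {"African": 1.0}, "African"
)


class TestClassifyIncidence:
    def test_in_text_statement_wins(self):
        stmt = AncestryStatement("art1", 0, "HeLa", "Han Chinese")
        inc = classify_incidence(_mention(), [stmt], _matched(), HELA)
        assert inc.practice is ReportingPractice.REPORTED
        assert inc.assignment.source == "in_text"
        assert (inc.assignment.census_group, inc.assignment.genotype_group) == (
            "Asian",
            "East Asian",
        )

    def test_lexicon_breakdown_gives_available(self):
        inc = classify_incidence(_mention(), [], _matched(), HELA)
        assert inc.practice is ReportingPractice.AVAILABLE
        assert inc.assignment.source == "web"
        assert (inc.assignment.census_group, inc.assignment.genotype_group) == (
            "Black or African American",
            "African",
        )

    def test_unmatched_primary_is_not_available(self):
        unmatched = MatchResult("T cells", "", None, 0.2, False)
        inc = classify_incidence(
            _mention("T cells", "primary"), [], unmatched, None
        )
        assert inc.practice is ReportingPractice.NOT_AVAILABLE
        assert inc.assignment.source == "none"
        assert inc.assignment.census_group == "Unknown"

    def test_matched_record_without_breakdown_is_not_available(self):
        rec = CellLineRecord("X1", "HEK-293")
        inc = classify_incidence(_mention("HEK-293"), [], _matched("HEK-293", "X1"), rec)
        assert inc.practice is ReportingPractice.NOT_AVAILABLE

    def test_statement_for_other_mention_ignored(self):
        stmt = AncestryStatement("art1", 0, "monocytes", "African")
        inc = classify_incidence(_mention(), [stmt], _matched(), HELA)
        assert inc.practice is ReportingPractice.AVAILABLE

    def test_reported_always_has_verbatim_label(self):
        stmt = AncestryStatement("art1", 0, "HeLa", "European")
        inc = classify_incidence(_mention(), [stmt], None, None)
        assert inc.practice is ReportingPractice.REPORTED
        assert inc.assignment.verbatim_label == "European"


class TestAssignmentInvariants:
    def test_source_none_forces_unknown(self):
        with pytest.raises(ValueError):
            AncestryAssignment(census_group="White", source="none")

    def test_in_text_requires_verbatim(self):
        with pytest.raises(ValueError):
            AncestryAssignment(
                census_group="White",
                genotype_group="European",
                verbatim_label="",
                source="in_text",
            )


class TestArticlePractices:
    def _inc(self, practice, article_id="art1"):
        return classify_incidence(
            Mention(article_id, 0, "X cells"),
            [AncestryStatement(article_id, 0, "X cells", "European")]
            if practice == "reported"
            else [],
            None,
            None,
        )

    def test_union(self):
        incs = [self._inc("reported"), self._inc("none")]
        assert article_practices(incs) == {
            ReportingPractice.REPORTED,
            ReportingPractice.NOT_AVAILABLE,
        }

    def test_single_practice(self):
        assert article_practices([self._inc("none")]) == {
            ReportingPractice.NOT_AVAILABLE
        }

    def test_empty(self):
        assert article_practices([]) == set()

    def test_mixed_articles_rejected(self):
        with pytest.raises(ValueError):
            article_practices([self._inc("none", "a"), self._inc("none", "b")])
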