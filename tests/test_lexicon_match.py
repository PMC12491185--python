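"""Edit distance, normalized similarity, fuzzy linking, lexicon I/O."""

import itertools
import random

import edlib
import pytest
from hypothesis import given, settings, strategies as st

from cellaudit.lexicon_match import (
    CellLineRecord,
    LexiconError,
    best_match,
    levenshtein,
    load_lexicon,
    normalize_name,
    save_lexicon,
    similarity,
)
from levoracle import lev_recursive


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("", "abc", 3), ("HeLa", "HeLa", 0), ("MCF7", "MCF-7", 1), ("kitten", "sitting", 3)],
    )
    def test_known_distances(self, a, b, expected):
        assert levenshtein(a, b) == expected

    def test_agrees_with_recursive_oracle_exhaustively(self):
        alphabet = "abc"
        strings = [
            "".join(t)
            for n in range(5)
            for t in itertools.product(alphabet, repeat=n)
        ]
        for a in strings:
            for b in strings:
                assert levenshtein(a, b) == lev_recursive(a, b), (a, b)

    def test_agrees_with_oracles_on_random_pairs(self):
        rng = random.Random(42)
        alphabet = "abcdef-3"
        for _ in range(500):
            a = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 6)))
            b = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 6)))
            d = levenshtein(a, b)
            assert d == lev_recursive(a, b)
            if a and b:  # edlib: independent second oracle
                assert d == edlib.align(a, b, task="distance")["editDistance"]

    @given(st.text(max_size=12), st.text(max_size=12))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_symmetry_and_bounds(self, a, b):
        d = levenshtein(a, b)
        assert d == levenshtein(b, a)
        assert abs(len(a) - len(b)) <= d <= max(len(a), len(b))


class TestNormalizeName:
    @pytest.mark.parametrize(
        "raw,expected",
        [("  HeLa ", "hela"), ("MCF  7", "mcf 7"), ("HEK-293", "hek-293")],
    )
    def test_rules(self, raw, expected):
        assert normalize_name(raw) == expected


class TestSimilarity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("HeLa", "hela", 1.0), ("MCF7", "MCF-7", 0.8), ("", "abc", 0.0), ("", "", 1.0)],
    )
    def test_known_values(self, a, b, expected):
        assert similarity(a, b) == pytest.approx(expected)

    @given(st.text(max_size=10), st.text(max_size=10))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_symmetric_bounded_and_identity(self, a, b):
        s = similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert s == similarity(b, a)
        assert (s == 1.0) == (normalize_name(a) == normalize_name(b))
        assert similarity(a, a) == 1.0


class TestBestMatch:
    @pytest.fixture()
    def lexicon(self):
        return [
            CellLineRecord("A1", "MCF7", ("MCF-7",)),
            CellLineRecord("A2", "HeLa"),
        ]

    def test_verbatim_canonical_name(self, lexicon):
        m = best_match("HeLa", lexicon)
        assert (m.accession, m.similarity, m.matched) == ("A2", 1.0, True)

    def test_closest_wins(self, lexicon):
        m = best_match("MCF-7", lexicon)
        assert m.accession == "A1" and m.similarity == pytest.approx(1.0)

    def test_below_threshold_unmatched(self):
        m = best_match("QQQQQQQQ", [CellLineRecord("A2", "HeLa")])
        assert not m.matched and m.accession is None and m.similarity <= 0.5

    def test_exactly_at_threshold_is_unmatched(self):
        # similarity("ab","aXbY")... craft exactly 0.5: "abcd" vs "ab" -> 0.5
        m = best_match("ab", [CellLineRecord("Z", "abcd")])
        assert m.similarity == pytest.approx(0.5) and not m.matched

    def test_empty_lexicon(self):
        m = best_match("HeLa", [])
        assert m == best_match("HeLa", [])
        assert not m.matched and m.similarity == 0.0

    def test_order_independent_tie_break(self):
        recs = [
            CellLineRecord("B2", "ABXD"),
            CellLineRecord("B1", "ABYD"),
        ]
        a = best_match("ABCD", recs)
        b = best_match("ABCD", list(reversed(recs)))
        assert a == b
        assert a.accession == "B1"  # equal similarity/length -> smallest accession


class TestLexiconIO:
    def _records(self):
        return [
            CellLineRecord(
                "C1", "HeLa", ("hela",), "cell_line", {"African": 1.0}, "African"
            ),
            CellLineRecord("C2", "MCF7", ("MCF-7", "mcf7"), "cell_line", {}, ""),
        ]

    @pytest.mark.parametrize("ext", ["json", "tsv"])
    def test_round_trip(self, tmp_path, ext):
        path = tmp_path / f"lex.{ext}"
        save_lexicon(self._records(), path)
        assert load_lexicon(path) == self._records()

    def test_single_record_json(self, tmp_path):
        path = tmp_path / "one.json"
        save_lexicon(self._records()[:1], path)
        assert len(load_lexicon(path)) == 1

    def test_fractions_over_one_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(
            '[{"accession": "X", "canonical_name": "N", '
            '"ancestry_breakdown": {"African": 0.6, "European": 0.6}}]',
            "utf-8",
        )
        with pytest.raises(LexiconError, match="X"):
            load_lexicon(path)

    def test_duplicate_accessions_rejected(self, tmp_path):
        path = tmp_path / "dup.json"
        path.write_text(
            '[{"accession": "X", "canonical_name": "A"},'
            ' {"accession": "X", "canonical_name": "B"}]',
            "utf-8",
        )
        with pytest.raises(LexiconError, match="duplicate"):
            load_lexicon(path)

    def test_record_invariants(self):
        with pytest.raises(LexiconError):
            CellLineRecord("X", "")
        with pytest.raises(LexiconError):
            CellLineRecord("X", "N", ancestry_breakdown={"A": 1.5})
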