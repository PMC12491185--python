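"""Greedy assignment and scoring against a curated reference."""

import pytest

from cellaudit.evaluation import (
    PredictedEntry,
    ReferenceRecord,
    evaluate,
    load_reference,
    match_predictions,
    save_reference,
    score,
)


def _pred(name, article_id="a1", ancestry="", practice=None):
    return PredictedEntry(article_id, name, ancestry, practice)


def _ref(name, article_id="a1", ancestry="", practice=""):
    return ReferenceRecord(article_id, name, ancestry, practice)


class TestMatchPredictions:
    def test_verbatim_predictions_all_assigned(self):
        refs = [_ref("HeLa"), _ref("MCF7")]
        preds = [_pred("HeLa"), _pred("MCF7")]
        a = match_predictions(preds, refs)
        assert len(a.pairs) == 2
        assert all(p.similarity == 1.0 for p in a.pairs)
        assert a.extra_prediction_indices == ()

    def test_good_match_threshold_inclusive(self):
        a = match_predictions([_pred("MCF7")], [_ref("MCF-7")])
        assert len(a.pairs) == 1 and a.pairs[0].similarity == pytest.approx(0.8)
        # exactly 0.5 still assigns (>= semantics for good matches)
        b = match_predictions([_pred("ab")], [_ref("abcd")])
        assert len(b.pairs) == 1

    def test_reference_consumed_once(self):
        preds = [_pred("HeLa"), _pred("HeLa-variant-x")]
        a = match_predictions(preds, [_ref("HeLa")])
        assert len(a.pairs) == 1
        assert a.pairs[0].prediction_index == 0  # the closer one wins
        assert a.extra_prediction_indices == (1,)

    def test_articles_do_not_cross(self):
        a = match_predictions([_pred("HeLa", "a1")], [_ref("HeLa", "a2")])
        assert a.pairs == ()

    def test_tie_break_is_order_invariant(self):
        refs = [_ref("ABXD"), _ref("ABYD")]
        preds = [_pred("ABCD")]
        a = match_predictions(preds, refs)
        b = match_predictions(preds, list(reversed(refs)))
        ref_name_a = refs[a.pairs[0].reference_index].cell_name
        ref_name_b = list(reversed(refs))[b.pairs[0].reference_index].cell_name
        assert ref_name_a == ref_name_b == "ABXD"  # lexicographic tie-break


class TestScore:
    def test_perfect_predictions(self):
        refs = [
            _ref("HeLa", ancestry="African"),
            _ref("MCF7", ancestry="European"),
        ]
        preds = [
            _pred("HeLa", ancestry="African"),
            _pred("MCF7", ancestry="European"),
        ]
        r = evaluate(preds, refs)
        assert r.exact_matches == 2
        assert r.good_match_rate == 100.0
        assert r.ancestry_accuracy == 100.0
        assert r.extra_outputs == 0

    def test_empty_predictions(self):
        r = evaluate([], [_ref("HeLa")])
        assert (r.exact_matches, r.good_matches, r.extra_outputs) == (0, 0, 0)
        assert r.overall_similarity is None

    def test_empty_reference_is_undefined_not_zero(self):
        r = evaluate([_pred("HeLa")], [])
        assert r.good_match_rate is None
        assert r.ancestry_accuracy is None
        assert r.extra_outputs == 1

    def test_three_prediction_worked_example(self):
        # HeLa->HeLa exact, MCF7->MCF-7 at 0.8, QQQQ unassigned at 0.0:
        # overall = 100 * mean(1.0, 0.8, 0.0) = 60.0
        refs = [
            _ref("HeLa", ancestry="African"),
            _ref("MCF-7", ancestry="European"),
        ]
        preds = [
            _pred("HeLa", ancestry="African"),
            _pred("MCF7", ancestry="European"),
            _pred("QQQQ"),
        ]
        r = evaluate(preds, refs)
        assert r.exact_matches == 1
        assert r.good_matches == 2
        assert r.extra_outputs == 1
        assert r.overall_similarity == pytest.approx(60.0)
        assert r.ancestry_accuracy == 100.0

    def test_ancestry_accuracy_via_genotype_groups(self):
        # different verbatim labels that map to the same genotype group agree
        refs = [_ref("HeLa", ancestry="Black")]
        preds = [_pred("HeLa", ancestry="African American")]
        assert evaluate(preds, refs).ancestry_accuracy == 100.0
        preds = [_pred("HeLa", ancestry="Japanese")]
        assert evaluate(preds, refs).ancestry_accuracy == 0.0

    def test_denominator_excludes_unlabelled_references(self):
        refs = [_ref("HeLa", ancestry="African"), _ref("MCF7", ancestry="")]
        preds = [_pred("HeLa", ancestry="African"), _pred("MCF7", ancestry="")]
        assert evaluate(preds, refs).ancestry_accuracy == 100.0

    def test_practice_agreement(self):
        refs = [_ref("HeLa", practice="available")]
        preds = [_pred("HeLa", practice="available")]
        assert evaluate(preds, refs).practice_agreement == 100.0
        preds = [_pred("HeLa", practice="reported")]
        assert evaluate(preds, refs).practice_agreement == 0.0

    def test_adding_prediction_never_decreases_good_matches(self):
        refs = [_ref("HeLa"), _ref("MCF7")]
        preds = [_pred("HeLa")]
        base = evaluate(preds, refs).good_matches
        more = evaluate(preds + [_pred("MCF7")], refs).good_matches
        assert more >= base

    def test_self_scoring_is_perfect(self):
        refs = [
            _ref("HeLa", ancestry="African"),
            _ref("MCF7", ancestry="European"),
            _ref("T cells"),
        ]
        preds = [
            _pred(r.cell_name, ancestry=r.ancestry_label) for r in refs
        ]
        r = evaluate(preds, refs)
        assert r.exact_matches == r.n_reference == 3
        assert r.extra_outputs == 0
        assert r.ancestry_accuracy == 100.0


class TestReferenceIO:
    def test_round_trip(self, tmp_path):
        refs = [
            ReferenceRecord("a1", "HeLa", "African", "available"),
            ReferenceRecord("a2", "T cells", "", "not_available"),
        ]
        path = tmp_path / "ref.csv"
        save_reference(refs, path)
        assert load_reference(path) == refs

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("foo,bar\n1,2\n", "utf-8")
        with pytest.raises(ValueError):
            load_reference(path)
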