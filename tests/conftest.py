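import pytest

from cellaudit.extraction import MockBackend, gazetteer_from_lexicon
from cellaudit.fixtures import CorpusSpec, generate_corpus, generate_lexicon
from cellaudit.lexicon_match import CellLineRecord
from cellaudit.pipeline import run_pipeline

DESCRIPTORS = ("Han Chinese", "African", "European", "Caucasian")


@pytest.fixture(scope="session")
def small_lexicon() -> list[CellLineRecord]:
    return [
        CellLineRecord(
            "CVCL-T001", "HeLa", ("hela",), "cell_line", {"African": 1.0}, "African"
        ),
        CellLineRecord(
            "CVCL-T002", "MCF7", ("MCF-7",), "cell_line", {"European": 1.0}, "European"
        ),
        CellLineRecord("CVCL-T003", "HEK-293", ("HEK293", "293"), "cell_line"),
        CellLineRecord(
            "CVCL-T004",
            "FaDu",
            (),
            "cell_line",
            {"Central/South Asian": 1.0},
            "Central/South Asian",
        ),
        CellLineRecord(
            "CVCL-T005",
            "JURKAT",
            ("Jurkat",),
            "cell_line",
            {"European": 0.5, "African": 0.5},
        ),
    ]


@pytest.fixture(scope="session")
def mock(small_lexicon) -> MockBackend:
    from cellaudit.fixtures import DISTRACTOR_LINES

    gazetteer = gazetteer_from_lexicon(small_lexicon)
    for entry in DISTRACTOR_LINES:
        gazetteer[entry.name.casefold()] = entry
    return MockBackend(gazetteer, DESCRIPTORS)


@pytest.fixture(scope="session")
def lexicon30():
    return generate_lexicon(30, seed=1)


@pytest.fixture(scope="session")
def bundle20(lexicon30):
    spec = CorpusSpec(
        n_articles=20, mentions_per_article=(3, 3), typo_edit_distance=0, seed=1
    )
    return generate_corpus(spec, lexicon30)


@pytest.fixture(scope="session")
def result20(bundle20, lexicon30):
    backend = MockBackend(bundle20.gazetteer, bundle20.descriptor_lexicon)
    return run_pipeline(bundle20.documents, lexicon30, backend)
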