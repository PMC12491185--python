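"""Synthetic lexicons, articles and matched references with planted truth.

The real study corpus (hundreds of journal articles plus a hand-curated
incidence database) is not redistributable, so every stage of the pipeline
is exercised against generated data instead: a Cellosaurus-style lexicon
of invented cell-line records, template-prose articles that embed planted
mentions of three classes — *reported* (an in-text donor-ancestry
sentence), *available* (a lexicon name whose record carries an ancestry
breakdown, no in-text descriptor) and *not_available* (primary-culture
terms or names absent from the lexicon) — and a reference CSV listing
every planted incidence with its true practice and ancestry label.

Controlled corruption knobs: single-character typos at a fixed edit
distance (never in the first character, so a typo on a name of length >= 4
keeps similarity >= 0.75 to its source — always recoverable above the 50%
match threshold) and non-human distractor lines (flagged murine etc. in
the gazetteer, giving the refine step a deterministic basis for removal).
Everything is a pure function of (spec, seed, lexicon).
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from .ancestry_rules import majority_label
from .corpus_io import Document
from .evaluation import ReferenceRecord, save_reference
from .extraction import (
    GazetteerEntry,
    Mention,
    PRIMARY_CULTURE_TERMS,
    gazetteer_from_lexicon,
)
from .lexicon_match import CellLineRecord, similarity

__all__ = [
    "CorpusSpec",
    "CorpusBundle",
    "generate_lexicon",
    "generate_corpus",
    "with_redundant_variants",
    "write_corpus",
    "DISTRACTOR_LINES",
    "DESCRIPTOR_POOL",
]

#: non-human lines the generator may sprinkle in; species flags let the
#: refine step remove them deterministically
DISTRACTOR_LINES = (
    GazetteerEntry("NIH 3T3", species="mouse", kind="cell_line"),
    GazetteerEntry("L929", species="mouse", kind="cell_line"),
    GazetteerEntry("RAW 264.7", species="mouse", kind="cell_line"),
    GazetteerEntry("C2C12", species="mouse", kind="cell_line"),
    GazetteerEntry("CHO", species="hamster", kind="cell_line"),
    GazetteerEntry("MDCK", species="dog", kind="cell_line"),
    GazetteerEntry("Vero", species="monkey", kind="cell_line"),
)

#: in-text donor descriptors for reported-class plants; each maps cleanly
#: in the shipped descriptor table
DESCRIPTOR_POOL = (
    "Han Chinese",
    "Japanese",
    "Korean",
    "European",
    "Caucasian",
    "African American",
    "West African",
    "South Asian",
)

#: population labels used in generated ancestry breakdowns (identity rows
#: of the genotype scheme)
_BREAKDOWN_LABELS = ("African", "European", "East Asian", "Central/South Asian")

_FILLERS = (
    "Samples were processed according to institutional protocols.",
    "All experiments were performed in triplicate.",
    "Statistical analysis used a two-sided test with alpha 0.05.",
    "Constructs were verified by sequencing before use.",
    "Imaging was carried out on a confocal microscope.",
    "Supernatants were collected at 24 and 48 hours.",
)


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for a generated corpus.

    The three class fractions must sum to 1; they set the probability that
    a planted incidence is reported / available / not available. Defaults
    mirror the audited literature: direct in-text reporting is rare and
    roughly half of all incidences have no ascertainable ancestry.
    """

    n_articles: int = 20
    mentions_per_article: tuple[int, int] = (3, 3)
    fraction_reported: float = 0.05
    fraction_available: float = 0.48
    fraction_not_available: float = 0.47
    typo_edit_distance: int = 0
    distractor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        total = (
            self.fraction_reported
            + self.fraction_available
            + self.fraction_not_available
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total!r}, expected 1")
        if not (0 <= self.typo_edit_distance <= 2):
            raise ValueError("typo_edit_distance must be in 0..2")
        lo, hi = self.mentions_per_article
        if not (1 <= lo <= hi):
            raise ValueError("mentions_per_article must be a nonempty range")


@dataclass
class CorpusBundle:
    """Everything a generated corpus consists of."""

    documents: list[Document]
    reference: list[ReferenceRecord]
    gazetteer: dict[str, GazetteerEntry]
    descriptor_lexicon: tuple[str, ...]
    spec: CorpusSpec
    planted_mentions: list[Mention] = field(default_factory=list)


def _random_name(rng: random.Random) -> str:
    n_letters = rng.randint(2, 4)
    n_digits = rng.randint(1, 4)
    n_digits = min(max(n_digits, 4 - n_letters), 8 - n_letters)  # length 4-8
    letters = "".join(rng.choice(string.ascii_uppercase) for _ in range(n_letters))
    digits = "".join(rng.choice(string.digits) for _ in range(n_digits))
    return letters + digits


def _dissimilar(name: str, taken: Sequence[str], ceiling: float = 0.5) -> bool:
    return all(similarity(name, t) <= ceiling for t in taken)


def _make_synonyms(name: str, rng: random.Random) -> tuple[str, ...]:
    """1-3 case/hyphen variants of a canonical name."""
    first_digit = next((i for i, c in enumerate(name) if c.isdigit()), None)
    variants = []
    if first_digit:
        variants.append(name[:first_digit] + "-" + name[first_digit:])
        variants.append(name[:first_digit] + " " + name[first_digit:])
    variants.append(name.lower())
    variants.append(name.capitalize())
    rng.shuffle(variants)
    out: list[str] = []
    for v in variants:
        if v != name and v not in out:
            out.append(v)
        if len(out) == rng.randint(1, 3):
            break
    return tuple(out) if out else (name.lower(),)


def generate_lexicon(n_records: int, seed: int) -> list[CellLineRecord]:
    """A synthetic Cellosaurus-style lexicon, deterministic under ``seed``.

    Ancestry breakdowns are drawn so that roughly 70% of records carry a
    single label at fraction 1.0, 20% a clear >60% majority, and 10% a
    no-majority mixture — exercising all three branches of the majority
    rule. Canonical names of distinct records are kept mutually dissimilar
    (similarity <= 0.5) so fuzzy linking is unambiguous.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = random.Random(seed)
    records: list[CellLineRecord] = []
    taken: list[str] = []
    for i in range(n_records):
        while True:
            name = _random_name(rng)
            if _dissimilar(name, taken):
                break
        taken.append(name)
        roll = rng.random()
        labels = rng.sample(_BREAKDOWN_LABELS, 2)
        if roll < 0.7:
            breakdown = {labels[0]: 1.0}
        elif roll < 0.9:
            major = round(rng.uniform(0.65, 0.9), 2)
            breakdown = {labels[0]: major, labels[1]: round(1 - major, 2)}
        else:
            minor = round(rng.uniform(0.4, 0.6), 2)
            breakdown = {labels[0]: minor, labels[1]: round(1 - minor, 2)}
        winner = majority_label(breakdown)
        records.append(
            CellLineRecord(
                accession=f"SYN-C{i:04d}",
                canonical_name=name,
                synonyms=_make_synonyms(name, rng),
                culture_kind="cell_line",
                ancestry_breakdown=breakdown,
                verbatim_label=winner or "Mixed Ancestry",
            )
        )
    return records


def _apply_typo(name: str, distance: int, rng: random.Random) -> str:
    """``distance`` single-character substitutions at seeded positions,
    never in the first character and never a no-op."""
    if distance == 0 or len(name) < 2:
        return name
    chars = list(name)
    positions = rng.sample(range(1, len(chars)), min(distance, len(chars) - 1))
    alphabet = string.ascii_uppercase + string.digits
    for pos in positions:
        repl = rng.choice(alphabet)
        while repl.casefold() == chars[pos].casefold():
            repl = rng.choice(alphabet)
        chars[pos] = repl
    return "".join(chars)


def _pick_class(rng: random.Random, spec: CorpusSpec) -> str:
    r = rng.random()
    if r < spec.fraction_reported:
        return "reported"
    if r < spec.fraction_reported + spec.fraction_available:
        return "available"
    return "not_available"


def generate_corpus(
    spec: CorpusSpec, lexicon: Sequence[CellLineRecord]
) -> CorpusBundle:
    """Generate articles, the matched reference, and the mock's gazetteer.

    Raises for infeasible specs (e.g. an available class requested against
    a lexicon with no ancestry-bearing records). Surfaces planted in one
    article are mutually dissimilar (similarity < 0.8) so each maps to its
    own cluster under curation.
    """
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    ancestry_bearing = [r for r in lexicon if r.ancestry_breakdown]
    if spec.fraction_available > 0 and not ancestry_bearing:
        raise ValueError(
            "available-class mentions requested but no lexicon record "
            "carries an ancestry breakdown"
        )
    rng = random.Random(spec.seed)
    gazetteer = gazetteer_from_lexicon(lexicon)
    for term in PRIMARY_CULTURE_TERMS:
        gazetteer[term.casefold()] = GazetteerEntry(term, "human", "primary")
    for entry in DISTRACTOR_LINES:
        gazetteer[entry.name.casefold()] = entry

    lexicon_names = [n for r in lexicon for n in r.all_names]
    safe_primary_terms = [
        t for t in PRIMARY_CULTURE_TERMS if _dissimilar(t, lexicon_names)
    ]

    documents: list[Document] = []
    reference: list[ReferenceRecord] = []
    planted: list[Mention] = []
    orphan_taken: list[str] = list(lexicon_names)

    for a in range(spec.n_articles):
        article_id = f"art{a:03d}"
        n_mentions = rng.randint(*spec.mentions_per_article)
        sentences: list[str] = [
            f"Study {article_id}: engineered platforms for in vitro modelling.",
            rng.choice(_FILLERS),
        ]
        used_surfaces: list[str] = []
        used_records: set[str] = set()
        used_terms: set[str] = set()

        def fits(surface: str) -> bool:
            return all(similarity(surface, u) < 0.8 for u in used_surfaces)

        for _ in range(n_mentions):
            cls = _pick_class(rng, spec)
            entity_kind: str
            if cls == "reported":
                use_primary = rng.random() < 0.5
                descriptor = rng.choice(DESCRIPTOR_POOL)
                if use_primary:
                    term = _draw_term(rng, safe_primary_terms, used_terms, fits)
                    if term is None:
                        continue
                    used_terms.add(term)
                    surface = clean = term
                    entity_kind = "primary"
                    sentences.append(
                        f"Primary {surface} were isolated from donors of "
                        f"{descriptor} ancestry."
                    )
                else:
                    rec = _draw_record(rng, lexicon, used_records, fits)
                    if rec is None:
                        continue
                    used_records.add(rec.accession)
                    clean = rec.canonical_name
                    surface = _plant_name(rec, spec, rng, gazetteer)
                    entity_kind = "cell_line"
                    sentences.append(
                        f"{surface} cells, derived from a {descriptor} donor, "
                        f"were cultured for downstream assays."
                    )
                reference.append(
                    ReferenceRecord(article_id, clean, descriptor, "reported")
                )
            elif cls == "available":
                rec = _draw_record(rng, ancestry_bearing, used_records, fits)
                if rec is None:
                    continue
                used_records.add(rec.accession)
                clean = rec.canonical_name
                surface = _plant_name(rec, spec, rng, gazetteer)
                entity_kind = "cell_line"
                sentences.append(
                    f"{surface} cells were maintained in DMEM supplemented "
                    f"with 10% FBS."
                )
                label = majority_label(rec.ancestry_breakdown) or "Mixed Ancestry"
                reference.append(
                    ReferenceRecord(article_id, clean, label, "available")
                )
            else:  # not_available
                if rng.random() < 0.5 and safe_primary_terms:
                    term = _draw_term(rng, safe_primary_terms, used_terms, fits)
                    if term is None:
                        continue
                    used_terms.add(term)
                    surface = clean = term
                    entity_kind = "primary"
                    sentences.append(
                        f"Freshly isolated {surface} were expanded without "
                        f"further characterization."
                    )
                else:
                    while True:
                        name = _random_name(rng)
                        if _dissimilar(name, orphan_taken) and fits(name):
                            break
                    orphan_taken.append(name)
                    gazetteer[name.casefold()] = GazetteerEntry(
                        name, "human", "unspecified"
                    )
                    surface = clean = name
                    entity_kind = "unspecified"
                    sentences.append(
                        f"{surface} cells were maintained under standard "
                        f"culture conditions."
                    )
                reference.append(
                    ReferenceRecord(article_id, clean, "", "not_available")
                )
            used_surfaces.append(surface)
            planted.append(
                Mention(
                    article_id=article_id,
                    chunk_index=0,
                    surface_text=surface,
                    culture_kind=entity_kind,
                )
            )
            sentences.append(rng.choice(_FILLERS))

        if rng.random() < spec.distractor_rate:
            distractor = rng.choice(DISTRACTOR_LINES)
            sentences.append(
                f"Control experiments used {distractor.name} cells in parallel."
            )
        documents.append(
            Document(
                article_id=article_id,
                source_path=f"synthetic://{article_id}",
                raw_text=" ".join(sentences),
            )
        )

    return CorpusBundle(
        documents=documents,
        reference=reference,
        gazetteer=gazetteer,
        descriptor_lexicon=DESCRIPTOR_POOL,
        spec=spec,
        planted_mentions=planted,
    )


def _draw_term(rng, pool, used, fits):
    candidates = [t for t in pool if t not in used and fits(t)]
    return rng.choice(candidates) if candidates else None


def _draw_record(rng, pool, used, fits):
    candidates = [
        r for r in pool if r.accession not in used and fits(r.canonical_name)
    ]
    return rng.choice(candidates) if candidates else None


def _plant_name(rec, spec, rng, gazetteer) -> str:
    """The surface form planted in text: the canonical name, optionally
    mutated; mutated surfaces are registered in the gazetteer so the mock
    extracts exactly what is written."""
    surface = _apply_typo(rec.canonical_name, spec.typo_edit_distance, rng)
    if surface.casefold() not in gazetteer:
        gazetteer[surface.casefold()] = GazetteerEntry(
            surface, "human", rec.culture_kind
        )
    return surface


def with_redundant_variants(mentions: Sequence[Mention]) -> list[Mention]:
    """Append upper/lower-case surface variants of every mention — the
    redundancy fixture for curation tests. Variants normalize to the same
    form as their source, so they stay grounded in the source text and
    cluster back onto it."""
    out = list(mentions)
    for m in mentions:
        s = m.surface_text
        for variant in (s.upper(), s.lower(), s.capitalize()):
            if variant != s and variant not in {x.surface_text for x in out}:
                out.append(replace(m, surface_text=variant))
    return out


def write_corpus(bundle: CorpusBundle, out_dir: str | Path) -> Path:
    """Materialize a bundle on disk: ``articles/*.txt`` plus
    ``reference.csv`` — the exact formats the pipeline consumes."""
    out_dir = Path(out_dir)
    articles = out_dir / "articles"
    articles.mkdir(parents=True, exist_ok=True)
    for doc in bundle.documents:
        (articles / f"{doc.article_id}.txt").write_text(doc.raw_text, "utf-8")
    save_reference(bundle.reference, out_dir / "reference.csv")
    return out_dir
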