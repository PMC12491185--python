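# Methods

## The pipeline

`cellaudit` models the metadata audit of human cell-culture use as five
stages: ingest → extract → link → categorize → score.

**Ingestion and chunking.** One document per file, PDF or UTF-8 text.
PDF text extraction is a minimal reader for born-digital files: it walks
content streams in document order, inflates Flate-compressed streams, and
decodes the standard text-showing operators (`Tj`, `TJ`, `'`) with
literal strings; line-advance operators become newlines. Scanned pages,
CID/Type0 fonts and encrypted files are out of scope (encryption raises
explicitly). Chunking is greedy left-to-right over tokens with a strict
budget: every chunk carries at most `max_tokens − 1` tokens (default
budget 4,000), tokens are never split, and empty documents yield zero
chunks. The default tokenizer is whitespace splitting — the budget is a
safety margin for a model's context window, not a semantic unit, so a
reproducible zero-dependency tokenizer is preferred; a model-specific
tokenizer can be passed in. The full text is chunked, including any
bibliography; reference sections are a known source of spurious mentions
in real articles and are not stripped.

**Extraction.** Three backend calls per chunk: identify candidate human
samples; refine to specifically human cell lines / cultures (dropping
media, reagents, non-human lines) and assign a culture kind (cell line,
primary, or unspecified); extract verbatim in-text ancestry descriptors
tied to retained mentions. The backend contract is
`(system_prompt, user_prompt, temperature) → text` with responses parsed
tolerantly (JSON array preferred, newline lists accepted, garbage yields
an empty list plus a warning — never a crash). Prompt texts are
configuration, not logic: everything downstream depends only on the
parsed array. The shipped reference backend is a deterministic mock
driven by a gazetteer with species flags and a descriptor lexicon; it
over-generates on purpose at the identify step (murine lines, media
terms) so the refine step's filtering is genuinely exercised. The live
HTTP adapter is a transport-injected contract with a 3-attempt
exponential-backoff retry policy; it is never used by tests.

**Linking.** Normalized Levenshtein similarity over casefolded,
whitespace-collapsed names; hyphens and digits are deliberately preserved
because cell-line identities hang on them (HEK-293 vs HEK-293T). The
edit-distance core is the classic two-row dynamic programme — adequate
for name-length strings, and verified in the test suite against both an
independent recursive oracle and `edlib`. Candidates are all canonical
names and synonyms; the maximum similarity wins, with ties broken by
longer candidate name then smallest accession, making the result
independent of lexicon order. Linking requires similarity **strictly
above 0.5**; evaluation's good-match criterion is **at least 0.5**. The
two thresholds are deliberately distinct config keys: the linking rule
follows the pipeline's description, the good-match rule follows the
evaluation's, and both readings appear in the method this package
re-implements.

**Ancestry categorization.** Three parallel records per incidence:
US-census group, genotyping-study group, verbatim descriptor. The
descriptor → group mapping is data, not code — an editable TSV shipped
with the package; unmapped descriptors become *Unknown* with a warning,
never a guess (in particular a bare "Asian" maps to census *Asian* but
genotype *Unknown*, since the genotype scheme splits East from
Central/South Asian). Fractional breakdowns resolve by strict majority:
a fraction must exceed 0.6 to win; a fraction of exactly 0.6 yields the
mixed category (the rule's stated bounds leave exactly-60% unaddressed;
the strict reading is applied and the threshold is configurable).
Decision order for the reporting practice: in-text statement ⇒
*reported*; else linked record with non-empty breakdown ⇒ *available*;
else *not_available*. Primary cultures with no catalogue entry land in
the third branch, which is why the audited corpora show primaries as
overwhelmingly unreported.

**Curation.** Grounding is substring containment of the normalized
surface in the normalized source chunk (word-boundary matching is an
option, off by default). Clustering is single linkage at similarity
≥ 0.8 within each article: deterministic, order-independent, and
parameter-light; 0.8 merges case/hyphen variants (MCF7 / MCF-7) without
merging genuinely distinct lines (HeLa / HeLa S3). The 0.8 value is this
package's choice — the method it re-implements names no clustering
threshold. Incidence accounting keeps one incidence per cluster member
(every mention counts), while "extra output" accounting counts clusters.

**Evaluation.** Per-article greedy one-to-one assignment in descending
similarity order with lexicographic tie-breaks; greedy rather than
optimal bipartite matching because it is deterministic, near-linear, and
indistinguishable at these similarity profiles. Ancestry accuracy is
computed over assigned pairs whose reference carries a non-empty ancestry
label, comparing genotype-scheme groups of the predicted and reference
labels; the original method's accuracy denominator is not published, so
this definition is the package's own and is stated here so the number is
interpretable. Rates on an empty reference are reported as undefined
(`null`), not zero.

## Synthetic data

The curated corpus behind the original audit is not redistributable, so
the generator in `cellaudit.fixtures` plants ground truth instead. Each
article embeds 3 planted mentions drawn from three classes with weights
reported = 0.05, available = 0.48, not_available = 0.47 — chosen once to
mirror the audited literature, where roughly half of all incidences had
no ascertainable ancestry and direct in-text reporting was rare — over a
default of 20 articles. Generated lexicon records carry ancestry
breakdowns in a 70/20/10 mix (single label at 1.0 / clear >60% majority /
no-majority mixture) so all three branches of the majority rule occur.
Canonical lexicon names are kept mutually dissimilar (similarity ≤ 0.5)
and surfaces within an article pairwise dissimilar (< 0.8), so linking
and clustering are unambiguous by construction. Typos are single
seeded-position substitutions, never in the first character, giving an
exact edit-distance guarantee: a distance-1 typo on a name of length ≥ 4
keeps similarity ≥ 0.75 to its source, always above the 0.5 linking
threshold. Distractor sentences use non-human lines (NIH 3T3, CHO, …)
flagged by species in the gazetteer.

What passing on this corpus shows — and does not. The generator
guarantees gazetteer coverage of every planted surface, one mention per
sentence, and descriptor sentences that name their mention; under those
conditions the pipeline recovers 100% of plants, so the end-to-end suite
verifies the *plumbing* (chunking, grounding, clustering, linking,
decision order, accounting) rather than extraction quality on real prose.
Real articles bring paraphrase, cross-sentence coreference, tables, and
model misses that no deterministic mock emulates; published recovery
rates of the live-model tool are therefore out of scope here and not
comparable to the synthetic recovery rates.

## Numerical and reporting choices

Percentages are rendered to one decimal, rounding half away from zero.
Summary percentages at article level use the number of included articles
as denominator and may sum past 100 (an article can exhibit several
practices); incidence-level percentages use total incidences. The
ascertainable-share rescaling is `overall_share / (100 − unreported_share)
× 100`. CSV outputs use a fixed seven-column schema and a deterministic
row order (article, chunk, surface), so identical seeds give
byte-identical files.

## Problem sizes

The test and acceptance workloads use 20–30 record lexicons, 20 articles
× 3 mentions, exhaustive oracle comparison over all pairs of strings on a
3-letter alphabet up to length 4 plus 500 random pairs up to length 6 —
sizes at which every check is exact and the whole suite runs in seconds
while still exercising each code path and rule branch.

## Known limitations

* The PDF reader targets simple born-digital files; complex layouts,
  embedded fonts with custom encodings, and OCR are unsupported.
* The mock backend is a gazetteer matcher: it cannot find names it was
  not given and does not model LLM paraphrase or hallucination beyond
  the deliberate over-generation noise.
* Cross-article entity resolution, synonym learning, STR-based identity
  verification, and live web querying are out of scope; the live backend
  and web lookup exist only as adapter contracts.
* Ancestry categories are reporting conventions, not biological claims;
  the package maps descriptors it is given and never infers ancestry.
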