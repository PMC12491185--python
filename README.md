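# cellaudit

Audit how biomedical articles report the ancestry of the human cell lines
and primary cultures they use.

Most *in vitro* studies never state the ancestral background of their
cellular material, even though donor ancestry measurably shifts immune
response, gene expression, and therapeutic relevance. Auditing a journal's
reporting practice by hand means reading every article, recording every
incidence of human cell or tissue use, and chasing each cell line through
a catalogue such as Cellosaurus — slow, error-prone work. `cellaudit`
automates that audit: it extracts cell-culture mentions from article text
with a pluggable completion backend (a deterministic gazetteer mock ships
in the box; a chat-completion adapter contract is provided for live
models), links each mention to a cell-line knowledge base by fuzzy string
matching, determines and categorizes donor ancestry, classifies each
article's reporting practice, curates the raw output, and scores the
result against a curated reference.

It is written for meta-researchers and journal editors studying
representation in biomedical research, and for methods developers who need
a fully offline, deterministic testbed for entity-normalization pipelines.

## Method

* **Chunking.** Article text (PDF or plain text) is split into chunks of
  fewer than 4,000 tokens (whitespace tokens by default; the tokenizer is
  pluggable) and each chunk is processed by a three-step prompt sequence:
  identify candidate human samples, refine to specifically human cell
  lines / cell cultures, extract any in-text ancestry descriptors.
* **Entity linking.** A mention *m* links to the knowledge-base name *r*
  (canonical names and synonyms all compete) maximizing the normalized
  Levenshtein similarity

  ```
  sim(m, r) = 1 − lev(norm(m), norm(r)) / max(|norm(m)|, |norm(r)|)
  ```

  where `norm` casefolds and collapses whitespace but keeps hyphens and
  digits. A link requires `sim > 0.5`; below that, no ancestry lookup is
  attempted.
* **Ancestry categorization.** Each incidence is recorded under two
  parallel schemes — US-census groups and genotyping-study groups — plus
  the verbatim descriptor. Fractional breakdowns from the knowledge base
  are resolved by a strict majority rule: the group whose fraction exceeds
  60% is assigned, otherwise the incidence is *Two or more races* /
  *Mixed Ancestry*.
* **Reporting practice.** In-text descriptor ⇒ *reported*; else a linked
  record with ancestry ⇒ *available*; else *not_available*. Articles
  aggregate to a set of practices.
* **Curation.** A grounding filter removes predicted names that do not
  literally occur in their source chunk, then single-linkage clustering at
  similarity ≥ 0.8 merges case/punctuation variants.
* **Evaluation.** Greedy one-to-one assignment of predictions to reference
  rows per article; *exact matches* (identical after normalization), *good
  matches* (similarity ≥ 0.5), overall similarity (mean closest-match
  similarity over all predictions, 0–100), ancestry accuracy (agreement of
  genotype-scheme groups among assigned pairs with a known reference
  label), and *extra outputs* (unassigned predictions).

See `docs/methods.md` for assumptions, parameter defaults, and the design
of the synthetic corpus generator.

## Worked example

Generate a synthetic corpus with planted ground truth, run the pipeline
with the deterministic mock backend, and score it:

```bash
cellaudit synth --out demo --seed 1 --articles 5
cellaudit run --corpus demo/articles --lexicon demo/lexicon.json \
    --gazetteer demo/gazetteer.json --reference demo/reference.csv \
    --out demo/out
```

which prints

```
15 incidences from 5 articles
reference rows      15
predictions         15
exact matches       15
good matches        15 (rate 100.00)
overall similarity  100.00
ancestry accuracy   100.00
practice agreement  100.00
extra outputs       0
```

Every planted mention was recovered verbatim (15 exact matches out of 15
reference rows, no spurious extras), every reporting-practice decision and
every ancestry group agreed with the planted truth — the expected outcome
on a clean corpus whose gazetteer covers all planted names. The first
rows of `demo/out/results.csv` show the seven-column incidence table:

```
article_id,cell_culture_found,cell_name_identified_on_web,ancestry_available,reported_decision,ancestry_identified_by_extraction,ancestry_found_on_web
art000,MQ59,MQ59,yes,available,,East Asian
art000,MSM291,MSM291,yes,available,,African
art000,PYO7,,no,not_available,,
```

The same flow is available as a library:

```python
from cellaudit import CorpusSpec, MockBackend, generate_corpus, generate_lexicon, run_pipeline

lexicon = generate_lexicon(30, seed=1)
bundle = generate_corpus(CorpusSpec(seed=1), lexicon)
backend = MockBackend(bundle.gazetteer, bundle.descriptor_lexicon)
result = run_pipeline(bundle.documents, lexicon, backend)
print(result.evaluate(bundle.reference))
print(result.summary().to_markdown())
```

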