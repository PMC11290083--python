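# chemnorm

Normalization of chemical mentions in biomedical text to **ChEBI** (Chemical
Entities of Biological Interest) identifiers, combining a hierarchical
dictionary with sentence-similarity disambiguation.

Text-mined chemical mentions (e.g. PubTator/TaggerOne output over PubMed
titles) arrive normalized to MeSH at best. MeSH lacks ontological structure:
no `is_a` hierarchy over chemicals, no roles, no link to structure databases.
Linking mentions to ChEBI instead enables downstream filtering by role
(pharmaceutical, nutrient, metabolite, ...) and cross-vocabulary mapping —
but chemical naming is wildly unstandardized (brand names, systematic names,
abbreviations, plurals, misspellings), so a single dictionary lookup is not
enough.

`chemnorm` is for text-mining practitioners who have mention files and
ontology/synonym dumps on disk and want a reproducible, fully offline linking
pipeline with auditable intermediate artifacts.

## Method

**Candidate generation** probes five dictionary levels in order and stops at
the first hit:

1. exact match to a ChEBI preferred name,
2. exact match to a ChEBI synonym,
3. *relaxed* match to ChEBI names/synonyms — lower-cased, de-pluralized,
   punctuation and whitespace stripped, so `α-keto esters` and `α-ketoester`
   collide on one key,
4. exact match to PubChem synonyms, routed to ChEBI through CID
   cross-references (one surface form may fan out to several entities
   sharing a CID),
5. relaxed match to PubChem synonyms,

with fuzzy matching as the fallback: the Levenshtein ratio

```
ratio(a, b) = round(100 · (|a|+|b| − D₂(a,b)) / (|a|+|b|))
```

where `D₂` is the edit distance with insertion/deletion cost 1 and
substitution cost 2; candidates with ratio > 50 are pooled across all three
surface sources and capped at 500, ranked by ratio. Abbreviations are
resolved first with the Schwartz–Hearst algorithm (short form in
parentheses, long form in the preceding `min(|SF|+5, 2·|SF|)`-word window).

**Disambiguation** treats ambiguous candidate sets as a sentence-pair task:
embed the mention's title, embed each *candidate title* (the title with the
mention span replaced by the candidate's preferred name), and keep the
candidate with maximum cosine similarity. The embedder is a contract —
bundled backends are a deterministic hashed character-trigram embedder
(FNV-1a 64, L2-normalized; no downloads), a stub that realizes prescribed
scores, and an optional mean-pooled transformer backend (`transformer`
extra) that accepts any trained checkpoint, e.g. a PubMedBERT variant
continued-pretrained on the verbalized ontology (learning rate 1e-4,
3 epochs, batch 8) and tuned for sentence similarity on STS (4 epochs,
batch 16, 512-token limit, mean pooling). A Levenshtein-ratio baseline and a
cosine threshold τ for flagging doubtful links are included.

**Downstream**: ontology verbalization (every triple/synonym/definition as a
natural-language sentence, e.g. *"diacylglycerol 44:4, otherwise known as
DAG 44:4, is a diglyceride"*), role classification through the
`is_a`/`has_role` closure, MeSH↔ChEBI mapping derivation and comparison
against a reference mapping, and an evaluation harness (accuracy,
disambiguated-subset accuracy, existence-detection P/R/F1 over a τ sweep).

## Worked example

Everything runs on deterministic generated fixtures — no downloads:

```bash
chemnorm make-fixtures --seed 11 --out fx/
chemnorm normalize --chebi fx/chebi.obo --pubchem fx/pubchem_synonyms.tsv \
    --pubtator fx/corpus.pubtator.txt --seed 11 --out-dir run/
chemnorm evaluate --results run/results.tsv --gold fx/gold.tsv
```

The `normalize` step prints its per-level match counts:

```json
{
  "EXACT_NAME": 13,
  "EXACT_PUBCHEM": 5,
  "EXACT_SYNONYM": 9,
  "FUZZY": 4,
  "RELAXED_CHEBI": 6,
  "UNMATCHED": 1
}
```

i.e. of the 38 active mentions, 13 matched a preferred name exactly, 9 a
synonym, 6 needed the relaxed key (plurals/hyphenation), 5 came from
PubChem, 4 required fuzzy matching, and 1 matched nothing (it is listed in
`run/unmatched.tsv` as a candidate new vocabulary term). `evaluate` then
reports

```
"overall_accuracy": 1.0        (n = 38)
"disambiguated_accuracy": 1.0  (n = 19)
```

— on fixture corpora the planted ground truth is recovered exactly; the
disambiguated subset is the 19 mentions that produced more than one
candidate (or any relaxed/PubChem/fuzzy hit) and were resolved by the
trigram embedder. `run/manifest.json` records the config hash, seed and
counts needed to reproduce the run bit-for-bit.

The argmax selection itself can be replayed with injected scores: for a
title mentioning *epicatechin* with candidates (+)-catechin,
(−)-epicatechin, (+)-epicatechin and catechin scored 0.918 / 0.985 / 0.984 /
0.927, the pipeline links CHEBI:90 ((−)-epicatechin), the 0.985 candidate.

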