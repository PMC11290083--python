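# Methods

This note documents the models and procedures implemented in `chemnorm`,
the parameters that matter, the design choices that were genuinely open,
and what the synthetic fixtures do and do not demonstrate.

## Problem setting

The input is a set of chemical mentions with character spans in PubMed
titles (PubTator format, typically produced by a tagger such as TaggerOne),
plus offline dumps of the ChEBI ontology and a PubChem-style CID→synonym
table. The output is, per mention, a ChEBI accession or an explicit
"unlinked" decision, with the method, score and hierarchy level that
produced it. Mentions of `water` are discarded as uninformatively generic,
and mentions of two characters or fewer are marked unmatchable rather than
risk spurious fuzzy hits.

## Hierarchical dictionary

The five levels (exact name, exact synonym, relaxed ChEBI, exact PubChem,
relaxed PubChem) short-circuit: the first level with ≥1 candidate wins and
lower levels are never probed. Rationale: each successive level trades
precision for recall, so a cheaper, more precise match must suppress
noisier ones. Only ChEBI entities with curation status `C` or `E` and a
2- or 3-star rating enter the lexicon; the status/star filters are
arguments, and edges orphaned by filtering are retained on the entities and
reported as dangling rather than silently dropped (they matter for
verbalization and auditing).

Design choices that were open:

* **Case.** "Exact" matching folds case by default because mention surface
  casing in titles is typographic, not chemical (`Cabazitaxel` vs
  `cabazitaxel`). A strict-case flag restores literal equality. Preferred
  names that collide after folding keep the lowest accession and are
  logged; synonym-level collisions are genuine ambiguity and are kept.
* **Name before synonym.** The two exact sub-levels are probed separately
  (name first) so that the match metadata distinguishes them; a name hit is
  unambiguous by construction and never goes to disambiguation.
* **Fuzzy pooling.** A fuzzy hit on a ChEBI name does not suppress fuzzy
  hits on synonyms or PubChem surfaces: hits are pooled across all three
  sources into one candidate list ranked by ratio, with the source order
  (name < synonym < PubChem) used only to break ratio ties, followed by the
  ascending numeric accession. All tie-breaks in the package are total
  orders so runs are reproducible.
* **Relaxed PubChem symmetry.** The relaxed key is applied to both the
  query and the table side (the PubChem relaxed index stores relax-images of
  the synonym list), so variant spellings collide regardless of which side
  carries the variant.

### Relaxed key

`relax` lower-cases (after NFC normalization), de-pluralizes each
whitespace token, then strips punctuation **and** internal whitespace, so
`α-keto esters` → `αketoester` = `relax("α-ketoester")`. Whitespace removal
is required for spacing variants of systematic names to collide.
De-pluralization is a small rule-based noun lemmatizer (`-sses`→`-ss`,
`-ies`→`-y`, `-es` after sibilants, trailing `-s` with `-ss/-us/-is` and
length guards); there is deliberately no stemming, which would destroy
chemical meaning (`-ic`, `-ous`, `-ate` endings). Because joining tokens
can expose a new trailing plural, the transform is applied to a fixed point,
making it idempotent. By default every Unicode punctuation character is
removed; a restricted mode removes only dashes, parentheses and commas.
Greek letters and symbol characters (`+`, stereo-descriptors) are preserved:
they distinguish entities.

### Edit ratio

`levenshtein_ratio(a, b) = round(100·(|a|+|b|−D₂)/(|a|+|b|))` with
substitution cost 2, insertion/deletion cost 1. Under these costs
`D₂ = |a|+|b| − 2·LCS(a,b)`, so the implementation computes the
longest-common-subsequence length with a two-row DP; the test oracle is an
independent explicit cost-matrix DP. Two empty strings score 100 by
convention; rounding is half-up for cross-platform determinism. The fuzzy
level keeps ratios strictly greater than the threshold (default 50) and
truncates to `max_candidates` (default 500, a cost/recall balance for the
downstream embedding step: each extra candidate costs one embedder call).

### Abbreviations

Schwartz–Hearst pairing: a candidate short form of 2–10 characters (≤2
words, ≥1 letter, alphanumeric first character) inside parentheses; the
long form is searched in the preceding window of `min(|SF|+5, 2·|SF|)`
words by right-to-left character matching, with the first short-form
character required to start a long-form word. Greek letters are expanded to
their spelled names (`β`→`beta`) during matching only — biomedical
abbreviations routinely mix scripts (`Aβ` / "amyloid beta") — while the
returned map preserves original surfaces. Short-form lookup at expansion
time is case-sensitive by default (chemical acronym case is meaningful);
the mention's surface string and span are never rewritten, only the lookup
text, so reporting stays anchored to the source text.

## Disambiguation

Candidate sets needing disambiguation (more than one candidate, or any
relaxed/PubChem/fuzzy hit) are resolved by a sentence-pair task: embed the
title once, embed each candidate title (mention span spliced out, candidate
preferred name spliced in), select the argmax cosine. Ties break toward the
earlier surface source and then the lower accession, so candidate order
cannot affect the outcome. Flagging with threshold τ marks embedder links
scoring below τ but keeps the link; the evaluation layer decides whether a
flagged link counts as "no entity". This separation lets one prediction set
be swept over thresholds without re-running the embedder.

Embedder backends:

* **Trigram embedder** (default for tests and desk runs): bag of character
  trigrams over the lower-cased, space-padded text, bucketed with FNV-1a 64
  (a fixed published hash; the seed is folded into the offset basis) modulo
  the dimension (default 256), L2-normalized. Fully deterministic across
  platforms and processes.
* **Stub embedder**: realizes prescribed cosine scores geometrically
  (reference text → first basis vector; text with score *s* →
  `(s, √(1−s²))`), so worked examples flow through the real argmax path.
* **Transformer backend** (optional extra): mean pooling over the final
  hidden states, 512-token truncation, any Hugging Face checkpoint. The
  intended recipe is a biomedical BERT continued-pretrained on the
  verbalized ontology corpus and then tuned for sentence similarity on an
  STS dataset; training loops are out of scope for this package.

The fuzzy-ratio baseline (`fuzzy_disambiguate`) selects the candidate
surface with the largest ratio against the lookup text — the comparison
point for measuring what contextual disambiguation adds.

## Verbalization

Every triple, synonym and definition of a retained entity becomes at least
one sentence. `is_a` triples are merged with at most one plain synonym each
("X, otherwise known as S, is a P") — one synonym per sentence keeps
sentences short enough for typical 512-token transformer limits; remaining
synonyms, typed synonyms ("has preferred name" for IUPAC names), other
relations ("is partially made up of" for `has_part`, "has role", a
spaces-for-underscores fallback otherwise) and definitions are rendered
standalone. The phrase table is injectable. The train/validation split is a
seeded permutation at sentence granularity (no split rule is canonical
here; a deterministic per-sentence split was chosen for simplicity), and
entities are visited in accession order, so the corpus is byte-reproducible.

## Roles, mapping comparison, evaluation

**Roles.** The roles of an entity are the upward `is_a` closure of every
`has_role` target asserted on the entity or any of its `is_a` ancestors.
Entity-side inheritance is a judgment call (a subclass of a prodrug is
plausibly a prodrug, but assertions are made at specific levels); it
defaults on and is togglable, and the role-count tables say which closure
produced them. A mention may count toward several target roles, so role
fractions need not sum to 1.

**MeSH↔ChEBI comparison.** Each MeSH id under comparison receives exactly
one category: `matched` (derived ∩ reference ≠ ∅; any overlap wins over the
other reference targets of a one-to-many mapping), `derived_more_specific`
(a derived id is a strict `is_a` descendant of a reference id — the typical
pattern when context-based linking picks a stereo-specific child),
`derived_new`, `reference_only`, `both_unlinked` (ids supplied in the
universe that neither map covers), and `mismatched` (both present, disjoint,
no descendant path). `mismatched` is needed for the categories to partition
the universe.

**Evaluation.** Overall accuracy counts exact id agreement (unlinked
predictions match "no entity" gold rows); disambiguated accuracy restricts
to mentions whose candidate sets needed disambiguation. Existence detection
treats "produces an unflagged link" as the positive prediction and "a ChEBI
entity exists" as truth, reporting precision/recall/F1 at each τ. Every
gold mention must have a prediction record; missing ones are an error, not
a silent skip.

## Synthetic fixtures

The generator emulates the *shape* of the real inputs at 30–300× reduced
scale: an acyclic `is_a` forest of invented chemical names under a chemical
root, a small role subtree (pharmaceutical/drug/prodrug, nutrient,
metabolite, inhibitor) with `has_role` edges, statuses and star ratings
that exercise the filters, a CID synonym table with shared-CID fan-out, and
a PubTator corpus whose titles embed planted mentions of every category
(exact, synonym, plural/hyphenation variants, PubChem-only names,
single-edit misspellings, context-dependent ambiguity, abbreviations
defined in the abstract, `water`, ≤2-character strings, and verified
unmatchable strings). Everything is a pure function of the seed; hashing is
FNV-1a 64, never the process hash.

Two plants are constructed by verified rejection sampling, which is what
makes their guarantees honest rather than probabilistic: *unmatchable*
strings are re-drawn until no dictionary level yields a candidate, and
*ambiguous* sibling groups (two entities sharing a synonym or a CID,
distinguished by an equal-length token such as alpha/gamma that also
appears twice in the title) are re-drawn until both siblings are separable
under the bundled trigram embedder — hash collisions at dimension 256 can
otherwise swamp the few-trigram context signal. Default conditions: 80
entities, depth 3, 2 synonyms per entity, 10% ambiguous, 15% variant, 10%
misspelled, 5% abbreviated mentions over 40 documents; the corpus-level
checks and the acceptance script use 200 entities and 300 mentions, sizes
chosen so every category is populated while a full run stays in seconds.

**What passing on fixtures shows — and does not.** Fixture recovery rates
are near 1.0 *by construction*: they verify the machinery (level order,
short-circuiting, relaxation, candidate fan-out, argmax selection,
closures), not real-world accuracy. Real corpora differ in every hard way:
surface forms not generated by simple plural/punctuation/edit rules, genuine
sense ambiguity that a character-trigram embedder cannot resolve, systematic
names whose nearest dictionary surface is a different compound, and
annotation noise. Accuracy on real data depends on the ontology release,
the synonym table, and the trained embedding backend, and must be measured
against a human-curated gold standard.

## Numerical and degenerate-input conventions

* Cosine of a zero vector is an error (degenerate embedding), not 0.
* Cosine values are clamped to [−1, 1] against floating-point drift.
* `ratio("", "") = 100`; a single empty side scores 0.
* Empty relax keys are never indexed (a punctuation-only synonym cannot
  match everything).
* Thresholds: fuzzy keeps ratio strictly > threshold; flagging uses
  score < τ (links at exactly τ are kept unflagged).
* All orderings (candidates, surface lists, corpus sentences, file rows)
  are explicit total orders; no dict/set iteration order leaks into output.

## Known limitations

* The trigram embedder is a test-scale stand-in for a trained sentence
  encoder; its disambiguation power on real ambiguity is limited to surface
  overlap with context.
* The noun de-pluralizer is rule-based and English-only; irregular plurals
  (`indices`, `spectra`) are not handled.
* Schwartz–Hearst finds only parenthetical definitions; unparenthesized or
  document-external abbreviations are missed, and its Greek-letter
  expansion covers the common biomedical letters only.
* PubChem "inconsistent structure" name cleaning is approximated by a
  pipe/control-character/length filter; the predicate is injectable.
* One mention maps to one entity; composite mentions ("galantamine
  hydrobromide" tagged as "galantamine") link to the tagged span only.
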