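"""Hierarchical dictionary candidate generation.

A mention is probed against five dictionary levels in a fixed order and the
search stops at the first level that yields at least one candidate:

1. exact match to a ChEBI preferred name,
2. exact match to a ChEBI synonym,
3. relaxed match (see :func:`chemnorm.textnorm.relax`) to ChEBI names/synonyms,
4. exact match to the PubChem synonym list, routed to ChEBI through the
   CID cross-references,
5. relaxed match to the PubChem synonym list,

with fuzzy string matching (Levenshtein ratio with substitution cost 2,
0-100 scale) as the final fallback over all surface forms.  Fuzzy hits are
pooled across the three surface sources, ranked by ratio (source order and
numeric accession break ties), and truncated to a configurable cap.

"Exact" matching folds case by default: mention surface casing in title text
is inconsistent (sentence case, ALL CAPS headers), and chemical names are not
case-normalized across sources.  A strict-case flag restores literal
exactness.
"""

from __future__ import annotations

import gzip
import json
import logging
import os
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

from .errors import ValidationError
from .ontology_io import CidXref, Mention, Ontology, SynonymTable, chebi_num
from .textnorm import relax

logger = logging.getLogger(__name__)


class MatchLevel(IntEnum):
    """Hierarchy levels in probe order; lower value = probed first."""

    EXACT_NAME = 0
    EXACT_SYNONYM = 1
    RELAXED_CHEBI = 2
    EXACT_PUBCHEM = 3
    RELAXED_PUBCHEM = 4
    FUZZY = 5
    UNMATCHED = 6


#: surface-source order used for fuzzy tie-breaking: name < synonym < PubChem
SOURCE_NAME, SOURCE_SYNONYM, SOURCE_PUBCHEM = 0, 1, 2

#: levels whose results always require contextual disambiguation
_AMBIGUOUS_LEVELS = {
    MatchLevel.RELAXED_CHEBI,
    MatchLevel.EXACT_PUBCHEM,
    MatchLevel.RELAXED_PUBCHEM,
    MatchLevel.FUZZY,
}


@dataclass(frozen=True)
class Candidate:
    chebi_id: str
    surface: str
    ratio: Optional[int] = None  # set for FUZZY hits only
    source: int = SOURCE_NAME


@dataclass
class CandidateSet:
    """Ordered candidates for one mention plus the level that produced them."""

    mention: Mention
    level: MatchLevel
    candidates: list[Candidate] = field(default_factory=list)

    @property
    def needs_disambiguation(self) -> bool:
        return len(self.candidates) > 1 or self.level in _AMBIGUOUS_LEVELS


@dataclass
class MatchConfig:
    """Knobs of the hierarchy.

    ``fuzzy_ratio_threshold`` keeps fuzzy candidates whose ratio strictly
    exceeds it (default 50).  ``max_candidates`` caps the fuzzy list (default
    500, balancing recall against downstream embedding cost).
    """

    fuzzy_ratio_threshold: int = 50
    max_candidates: int = 500
    use_relaxed: bool = True
    use_pubchem: bool = True
    use_fuzzy: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fuzzy_ratio_threshold:
            raise ValidationError("fuzzy_ratio_threshold must be positive")
        if self.max_candidates < 1:
            raise ValidationError("max_candidates must be >= 1")


# ---------------------------------------------------------------------------
# edit-distance ratio
# ---------------------------------------------------------------------------


def levenshtein_ratio(a: str, b: str) -> int:
    """Normalized similarity on a 0-100 scale.

    Defined as ``round(100 * (|a|+|b| - D2) / (|a|+|b|))`` where ``D2`` is
    the minimum edit distance with insertion/deletion cost 1 and substitution
    cost 2.  Under those costs ``D2 = |a|+|b| - 2*LCS(a, b)``, so the ratio is
    computed from the longest-common-subsequence length with a two-row DP.
    Symmetric; ``ratio(x, x) == 100``; two empty strings score 100.
    """
    la, lb = len(a), len(b)
    if la + lb == 0:
        return 100
    if la == 0 or lb == 0:
        return 0
    if la > lb:  # keep the inner loop over the longer string
        a, b, la, lb = b, a, lb, la
    prev = [0] * (la + 1)
    cur = [0] * (la + 1)
    for ch_b in b:
        for i, ch_a in enumerate(a):
            if ch_a == ch_b:
                cur[i + 1] = prev[i] + 1
            else:
                cur[i + 1] = cur[i] if cur[i] >= prev[i + 1] else prev[i + 1]
        prev, cur = cur, prev
    lcs = prev[la]
    # round half up for determinism across platforms
    return int((200 * lcs) / (la + lb) + 0.5)


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------


@dataclass
class Lexicon:
    """The five dictionary indexes plus the flat surface list for fuzzy scans.

    Multi-candidate indexes map a key to ``{chebi_id: original surface}`` so
    that match metadata can report the surface that produced each hit.
    """

    case_insensitive: bool = True
    exact_name: dict[str, tuple[str, str]] = field(default_factory=dict)
    exact_synonym: dict[str, dict[str, str]] = field(default_factory=dict)
    relaxed_name_syn: dict[str, dict[str, str]] = field(default_factory=dict)
    pubchem_exact: dict[str, dict[str, str]] = field(default_factory=dict)
    pubchem_relaxed: dict[str, dict[str, str]] = field(default_factory=dict)
    all_surface_forms: list[tuple[str, int, str]] = field(default_factory=list)

    def fold(self, text: str) -> str:
        return text.lower() if self.case_insensitive else text

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "case_insensitive": self.case_insensitive,
            "exact_name": {k: list(v) for k, v in self.exact_name.items()},
            "exact_synonym": self.exact_synonym,
            "relaxed_name_syn": self.relaxed_name_syn,
            "pubchem_exact": self.pubchem_exact,
            "pubchem_relaxed": self.pubchem_relaxed,
            "all_surface_forms": [list(t) for t in self.all_surface_forms],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Lexicon":
        return cls(
            case_insensitive=data["case_insensitive"],
            exact_name={k: (v[0], v[1]) for k, v in data["exact_name"].items()},
            exact_synonym=data["exact_synonym"],
            relaxed_name_syn=data["relaxed_name_syn"],
            pubchem_exact=data["pubchem_exact"],
            pubchem_relaxed=data["pubchem_relaxed"],
            all_surface_forms=[(s, int(src), cid) for s, src, cid in data["all_surface_forms"]],
        )

    def save(self, path: str | os.PathLike) -> None:
        path = os.fspath(path)
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "wt", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, ensure_ascii=False)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "Lexicon":
        path = os.fspath(path)
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "rt", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def build_lexicon(
    ontology: Ontology,
    synonyms: Optional[SynonymTable] = None,
    xref: Optional[CidXref] = None,
    case_insensitive: bool = True,
) -> Lexicon:
    """Populate all five indexes from the filtered inputs.

    PubChem names are attached to *every* ChEBI id sharing the CID, which is
    how one surface form can legitimately fan out to several candidates.
    Preferred names colliding after case folding keep the lowest accession
    (logged); synonym-level collisions are genuine ambiguity and are kept.
    """
    if not ontology.entities:
        raise ValidationError("cannot build a lexicon from an empty ontology")
    lex = Lexicon(case_insensitive=case_insensitive)
    surfaces: set[tuple[str, int, str]] = set()

    for ent in ontology.entities.values():
        key = lex.fold(ent.name)
        prev = lex.exact_name.get(key)
        if prev is None or chebi_num(ent.id) < chebi_num(prev[0]):
            if prev is not None:
                logger.warning("name collision on %r: %s vs %s", key, prev[0], ent.id)
            lex.exact_name[key] = (ent.id, ent.name)
        elif prev is not None:
            logger.warning("name collision on %r: %s vs %s", key, prev[0], ent.id)
        surfaces.add((key, SOURCE_NAME, ent.id))
        rkey = relax(ent.name)
        if rkey:
            lex.relaxed_name_syn.setdefault(rkey, {}).setdefault(ent.id, ent.name)
        for text, _syn_type in ent.synonyms:
            skey = lex.fold(text)
            lex.exact_synonym.setdefault(skey, {}).setdefault(ent.id, text)
            surfaces.add((skey, SOURCE_SYNONYM, ent.id))
            rkey = relax(text)
            if rkey:
                lex.relaxed_name_syn.setdefault(rkey, {}).setdefault(ent.id, text)

    if synonyms is not None and xref is not None:
        for cid, names in synonyms.cid_to_names.items():
            for chebi_id in xref.cid_to_chebis.get(cid, ()):
                if chebi_id not in ontology.entities:
                    continue
                for name in names:
                    key = lex.fold(name)
                    lex.pubchem_exact.setdefault(key, {}).setdefault(chebi_id, name)
                    surfaces.add((key, SOURCE_PUBCHEM, chebi_id))
                    rkey = relax(name)
                    if rkey:
                        lex.pubchem_relaxed.setdefault(rkey, {}).setdefault(chebi_id, name)

    lex.all_surface_forms = sorted(surfaces, key=lambda t: (t[1], chebi_num(t[2]), t[0]))
    return lex


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def _sorted_candidates(hits: dict[str, str], source: int) -> list[Candidate]:
    return [
        Candidate(chebi_id=cid, surface=hits[cid], source=source)
        for cid in sorted(hits, key=chebi_num)
    ]


def fuzzy_candidates(text: str, lexicon: Lexicon, cfg: MatchConfig) -> list[Candidate]:
    """All surfaces with ratio strictly above the threshold, best hit per entity.

    Deterministic ordering: ratio descending, then surface source (name,
    synonym, PubChem), then ascending numeric accession; truncated to
    ``cfg.max_candidates``.
    """
    if cfg.fuzzy_ratio_threshold >= 100:
        return []
    q = lexicon.fold(text)
    best: dict[str, tuple[int, int, str]] = {}  # chebi -> (ratio, source, surface)
    for surface, source, chebi_id in lexicon.all_surface_forms:
        r = levenshtein_ratio(q, surface)
        if r <= cfg.fuzzy_ratio_threshold:
            continue
        prev = best.get(chebi_id)
        if prev is None or (-r, source) < (-prev[0], prev[1]):
            best[chebi_id] = (r, source, surface)
    ranked = sorted(
        best.items(), key=lambda kv: (-kv[1][0], kv[1][1], chebi_num(kv[0]))
    )[: cfg.max_candidates]
    return [
        Candidate(chebi_id=cid, surface=surface, ratio=r, source=source)
        for cid, (r, source, surface) in ranked
    ]


def match(mention: Mention, lexicon: Lexicon, cfg: Optional[MatchConfig] = None) -> CandidateSet:
    """Probe the hierarchy for one mention; the first non-empty level wins."""
    cfg = cfg or MatchConfig()
    text = mention.lookup_text or mention.text
    q = lexicon.fold(text)

    hit = lexicon.exact_name.get(q)
    if hit is not None:
        cid, surface = hit
        return CandidateSet(mention, MatchLevel.EXACT_NAME, [Candidate(cid, surface)])

    hits = lexicon.exact_synonym.get(q)
    if hits:
        return CandidateSet(
            mention, MatchLevel.EXACT_SYNONYM, _sorted_candidates(hits, SOURCE_SYNONYM)
        )

    if cfg.use_relaxed:
        rkey = relax(text)
        hits = lexicon.relaxed_name_syn.get(rkey) if rkey else None
        if hits:
            return CandidateSet(
                mention, MatchLevel.RELAXED_CHEBI, _sorted_candidates(hits, SOURCE_SYNONYM)
            )

    if cfg.use_pubchem:
        hits = lexicon.pubchem_exact.get(q)
        if hits:
            return CandidateSet(
                mention, MatchLevel.EXACT_PUBCHEM, _sorted_candidates(hits, SOURCE_PUBCHEM)
            )
        rkey = relax(text)
        hits = lexicon.pubchem_relaxed.get(rkey) if rkey else None
        if hits:
            return CandidateSet(
                mention, MatchLevel.RELAXED_PUBCHEM, _sorted_candidates(hits, SOURCE_PUBCHEM)
            )

    if cfg.use_fuzzy:
        cands = fuzzy_candidates(text, lexicon, cfg)
        if cands:
            return CandidateSet(mention, MatchLevel.FUZZY, cands)

    return CandidateSet(mention, MatchLevel.UNMATCHED, [])
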