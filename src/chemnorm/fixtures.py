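"""Deterministic miniature fixtures: ontology, synonym tables, mention corpus.

The generator emulates the shape of the real inputs at desk scale so every
pipeline stage is testable without downloads: a filtered ChEBI-like ontology
(acyclic ``is_a`` forest over invented chemical names, a role subtree with
``has_role`` edges, statuses and star ratings that exercise the filters), a
PubChem-style CID synonym table, and a PubTator corpus whose titles embed
planted mentions with known gold links.

Planted mention categories:

* ``exact_name`` / ``exact_synonym`` — recoverable at the exact levels;
* ``relaxed`` — plural or hyphenation variants solvable only after relaxation;
* ``pubchem`` — names present only in the CID synonym table;
* ``fuzzy`` — misspellings within the edit budget, verified to miss every
  exact and relaxed index so only the fuzzy level can find them;
* ``ambiguous`` — a synonym (or shared-CID PubChem name) pointing at two
  sibling entities whose names differ in one discriminating token that also
  appears in the title context;
* ``abbreviation`` — a short form defined Schwartz-Hearst-style in the
  abstract and mentioned in the title;
* ``water`` / ``short`` — generic and <=2-character mentions that the reader
  must filter;
* ``unmatched`` — strings verified to produce no candidate at any level
  (gold "no entity").

Everything is a pure function of the seed: names come from one seeded RNG,
iteration orders are explicit, and the toy embedder hashes character
trigrams with FNV-1a 64 (a fixed published hash) so runs reproduce
bit-for-bit across platforms.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np

from .disambig import cosine
from .errors import ValidationError
from .matcher import MatchConfig, build_lexicon, fuzzy_candidates
from .ontology_io import (
    ChebiEntity,
    CidXref,
    Ontology,
    SynonymTable,
    write_chebi_obo,
    write_chebi_tsv,
)
from .textnorm import relax

# fixed role subtree reusing well-known ChEBI role accessions for readability
ROLE_ROOT = "CHEBI:50906"
BIOLOGICAL_ROLE = "CHEBI:24432"
PHARMACEUTICAL = "CHEBI:52217"
DRUG = "CHEBI:23888"
PRODRUG = "CHEBI:50266"
NUTRIENT = "CHEBI:33284"
METABOLITE = "CHEBI:25212"
INHIBITOR = "CHEBI:35222"
CHEMICAL_ROOT = "CHEBI:24431"

TARGET_ROLES = (PHARMACEUTICAL, NUTRIENT, METABOLITE, INHIBITOR)

_SYLLABLES = [
    "bar", "cin", "dex", "fen", "gli", "lor", "mep", "nor", "pra", "quin",
    "rex", "sta", "tol", "vab", "zol", "ket", "mir", "dol", "pam", "ser",
]
_SUFFIXES = ["ol", "ine", "ate", "ide", "in", "one"]
#: equal-length discriminating token pairs for ambiguous sibling entities;
#: equal lengths keep the candidate titles the same length so only the
#: shared-context signal separates the siblings
_DISC_PAIRS = [("alpha", "gamma"), ("delta", "sigma"), ("kappa", "theta")]

_TITLE_PREFIX = "Effects of "


def _title_for(mention_texts: list[str], ctx_tokens: list[str]) -> tuple[str, list[tuple[int, int]]]:
    """The shared title template: mentions chained after the prefix, context doubled."""
    title = _TITLE_PREFIX
    spans = []
    for k, text in enumerate(mention_texts):
        if k:
            title += " combined with "
        spans.append((len(title), len(title) + len(text)))
        title += text
    ctx = " ".join(ctx_tokens)
    title += f" on {ctx} outcomes in {ctx} cohort models of dementia"
    return title, spans


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one fixture; the seed fully determines the output."""

    seed: int = 0
    n_entities: int = 80
    hierarchy_depth: int = 3
    synonyms_per_entity: int = 2
    frac_ambiguous: float = 0.10
    frac_variants: float = 0.15
    frac_misspelled: float = 0.10
    misspelling_edit_budget: int = 1
    abbreviation_fraction: float = 0.05
    n_documents: int = 40
    mentions_per_title: int = 1

    def __post_init__(self) -> None:
        if self.n_entities < 30:
            raise ValidationError("n_entities must be >= 30")
        if self.hierarchy_depth < 1 or self.n_documents < 10 or self.mentions_per_title < 1:
            raise ValidationError("invalid fixture dimensions")
        for frac in (self.frac_ambiguous, self.frac_variants, self.frac_misspelled,
                     self.abbreviation_fraction):
            if not 0 <= frac <= 1:
                raise ValidationError("fractions must lie in [0, 1]")


@dataclass
class Plant:
    """One planted mention and where it ended up."""

    category: str
    text: str
    gold_id: Optional[str]
    mesh_id: Optional[str] = None
    disc: Optional[str] = None  # discriminating context token (ambiguous plants)
    abbrev_def: Optional[str] = None  # "long (SF)" definition for the abstract
    doc_id: str = ""
    span: tuple[int, int] = (0, 0)


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    all_entities: list[ChebiEntity]
    ontology: Ontology  # status/star-filtered view
    pubchem_rows: list[tuple[int, str]]
    plants: list[Plant]
    docs: dict[str, tuple[str, str]]  # doc_id -> (title, abstract)
    reference_rows: list[tuple[str, str]]

    @property
    def synonym_table(self) -> SynonymTable:
        table = SynonymTable()
        for cid, name in self.pubchem_rows:
            table.add(cid, name)
        return table

    @property
    def cid_xref(self) -> CidXref:
        xref = CidXref()
        for ent in self.ontology.entities.values():
            for ns, acc in ent.xrefs:
                if ns == "PubChem":
                    xref.add(ent.id, int(acc))
        return xref

    def gold(self) -> dict[tuple[str, str], Optional[str]]:
        out: dict[tuple[str, str], Optional[str]] = {}
        for p in self.plants:
            if p.category in ("water", "short"):
                continue
            out.setdefault((p.doc_id, p.text), p.gold_id)
        return out


# ---------------------------------------------------------------------------
# name generation
# ---------------------------------------------------------------------------


class _Namer:
    """Unique invented chemical names with collision-free relaxed keys."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.used: set[str] = set()

    def fresh(self, two_word: bool = False) -> str:
        for _ in range(1000):
            word = "".join(self.rng.choice(_SYLLABLES) for _ in range(self.rng.randint(2, 3)))
            name = word + self.rng.choice(_SUFFIXES)
            if two_word:
                second = "".join(self.rng.choice(_SYLLABLES) for _ in range(2))
                name = f"{name} {second}{self.rng.choice(_SUFFIXES)}"
            key = relax(name)
            # reserve the plural/singular neighborhood too so planted variants
            # cannot collide with an unrelated entity
            neighborhood = {key, key + "s", key[:-1]}
            if neighborhood & self.used:
                continue
            self.used |= neighborhood
            return name
        raise ValidationError("name space exhausted; increase syllable pool")


# ---------------------------------------------------------------------------
# core builder
# ---------------------------------------------------------------------------


def _role_entities() -> list[ChebiEntity]:
    def ent(cid: str, name: str, parent: Optional[str]) -> ChebiEntity:
        rels = [("is_a", parent)] if parent else []
        return ChebiEntity(id=cid, name=name, status="C", stars=3, relations=rels)

    return [
        ent(ROLE_ROOT, "role", None),
        ent(BIOLOGICAL_ROLE, "biological role", ROLE_ROOT),
        ent(PHARMACEUTICAL, "pharmaceutical", ROLE_ROOT),
        ent(DRUG, "drug", PHARMACEUTICAL),
        ent(PRODRUG, "prodrug", DRUG),
        ent(NUTRIENT, "nutrient", BIOLOGICAL_ROLE),
        ent(METABOLITE, "metabolite", BIOLOGICAL_ROLE),
        ent(INHIBITOR, "inhibitor", BIOLOGICAL_ROLE),
        ent(CHEMICAL_ROOT, "chemical entity", None),
    ]


@lru_cache(maxsize=8)
def _build(spec: FixtureSpec) -> FixtureBundle:
    rng = random.Random(spec.seed)
    namer = _Namer(rng)
    role_leaves = [PRODRUG, DRUG, NUTRIENT, METABOLITE, INHIBITOR, PHARMACEUTICAL]

    entities: list[ChebiEntity] = _role_entities()
    levels: dict[int, list[str]] = {0: [CHEMICAL_ROOT]}
    single_word: list[ChebiEntity] = []
    two_word: list[ChebiEntity] = []
    next_id = 1000

    def add_entity(name: str, parent: str, status: str = "C", stars: int = 3,
                   roles: Optional[list[str]] = None) -> ChebiEntity:
        nonlocal next_id
        rels = [("is_a", parent)] + [("has_role", r) for r in roles or []]
        ent = ChebiEntity(id=f"CHEBI:{next_id}", name=name, status=status, stars=stars,
                          relations=rels,
                          definition=f"A fixture compound named {name}.")
        next_id += 1
        entities.append(ent)
        return ent

    # --- chemical entities -------------------------------------------------
    for i in range(spec.n_entities):
        lvl = (i % spec.hierarchy_depth) + 1
        parents = levels.get(lvl - 1) or [CHEMICAL_ROOT]
        parent = rng.choice(parents)
        excluded = i % 13 == 12
        status = "D" if excluded and i % 2 == 0 else ("E" if i % 7 == 3 else "C")
        stars = 1 if excluded and i % 2 == 1 else (2 if i % 6 == 5 else 3)
        roles: list[str] = []
        if i == 0:
            roles = [PRODRUG]  # a statin-like prodrug anchor used in role tests
        elif rng.random() < 0.6:
            roles.append(rng.choice(role_leaves))
            if rng.random() < 0.2:
                roles.append(rng.choice(role_leaves))
        is_two = i % 5 == 2
        ent = add_entity(namer.fresh(two_word=is_two), parent, status, stars, roles)
        levels.setdefault(lvl, []).append(ent.id)
        if not excluded:
            (two_word if is_two else single_word).append(ent)

    retained = [e for e in entities if e.status in ("C", "E") and e.stars in (2, 3)]
    if len(single_word) < 10 or len(two_word) < 3:
        raise ValidationError("fixture too small to host all plant categories")

    # --- synonyms ------------------------------------------------------------
    for ent in retained:
        if ent.id == CHEMICAL_ROOT or ent.id in {e.id for e in _role_entities()}:
            continue
        for _ in range(spec.synonyms_per_entity):
            ent.synonyms.append((namer.fresh(), "SYNONYM"))
        ent.synonyms.append((f"2-{ent.name.replace(' ', '-')}yl-propan-1-ol", "IUPAC NAME"))

    # --- ambiguous sibling groups (shared ChEBI synonym) ---------------------
    # Each group is verified against the bundled trigram embedder at build
    # time: the planted context must actually separate the siblings, so the
    # generator redraws a base name whose hashed trigrams happen to drown the
    # discriminating signal.
    emb = toy_embedder(seed=spec.seed)
    n_groups = max(2, int(spec.n_entities * spec.frac_ambiguous) // 2)
    syn_groups: list[tuple[str, list[tuple[str, str]]]] = []  # (shared syn, [(id, disc)])
    for g in range(n_groups):
        base, discs = _draw_discriminable_group(namer, rng, emb, g)
        if spec.hierarchy_depth == 1:
            parent = CHEMICAL_ROOT
        else:
            parent = rng.choice([e.id for e in single_word[: max(4, len(single_word) // 2)]])
        members = []
        for disc in discs:
            ent = add_entity(f"{base} {disc}", parent)
            ent.synonyms.append((base, "SYNONYM"))
            members.append((ent.id, disc))
        syn_groups.append((base, members))

    # --- PubChem synonym table and cross-references ---------------------------
    pubchem_rows: list[tuple[int, str]] = []
    pubchem_only: list[tuple[str, str]] = []  # (name, chebi_id)
    cid = 90000
    plantable = [e for e in single_word + two_word]
    for j, ent in enumerate(plantable):
        if j % 3 == 1:
            continue  # some entities have no CID at all
        ent.xrefs.append(("PubChem", str(cid)))
        pubchem_rows.append((cid, ent.name))
        if j % 4 == 0:
            extra = namer.fresh()
            pubchem_rows.append((cid, extra))
            pubchem_only.append((extra, ent.id))
        cid += 1

    # one shared-CID group: a PubChem surface naming two sibling entities
    pub_base, pub_discs = _draw_discriminable_group(namer, rng, emb, n_groups)
    pub_parent = CHEMICAL_ROOT if spec.hierarchy_depth == 1 else rng.choice(
        [e.id for e in single_word]
    )
    pub_members = []
    for disc in pub_discs:
        ent = add_entity(f"{pub_base} {disc}", pub_parent)
        ent.xrefs.append(("PubChem", str(cid)))
        pub_members.append((ent.id, disc))
    pubchem_rows.append((cid, pub_base))
    cid += 1
    pub_groups = [(pub_base, pub_members)]

    ontology = Ontology(entities={
        e.id: e for e in entities if e.status in ("C", "E") and e.stars in (2, 3)
    })
    ontology.validate()

    # surface key sets used to verify that fuzzy plants cannot short-circuit
    folded: set[str] = set()
    relaxed: set[str] = set()
    for ent in ontology.entities.values():
        for surface in [ent.name] + [t for t, _ in ent.synonyms]:
            folded.add(surface.lower())
            relaxed.add(relax(surface))
    for _, name in pubchem_rows:
        folded.add(name.lower())
        relaxed.add(relax(name))

    # --- mention plan --------------------------------------------------------
    n_m = spec.n_documents * spec.mentions_per_title
    n_amb = round(spec.frac_ambiguous * n_m)
    n_rel = round(spec.frac_variants * n_m)
    n_fuz = round(spec.frac_misspelled * n_m)
    n_abb = round(spec.abbreviation_fraction * n_m)
    n_unm = max(1, round(0.03 * n_m))
    fixed = n_amb + n_rel + n_fuz + n_abb + n_unm + 2  # + water + short
    if fixed + 4 > n_m:
        raise ValidationError("n_documents too small for the planted category mix")
    rest = n_m - fixed
    n_syn = rest // 4
    n_pub = min(rest // 4, max(1, len(pubchem_only)))
    n_exa = rest - n_syn - n_pub

    plants: list[Plant] = []
    mesh_serial = 0

    def next_mesh() -> str:
        nonlocal mesh_serial
        mesh_serial += 1
        return f"D{610000 + mesh_serial}"

    for j in range(n_exa):
        ent = rng.choice(plantable)
        text = ent.name[0].upper() + ent.name[1:] if j % 2 == 0 else ent.name
        plants.append(Plant("exact_name", text, ent.id, mesh_id=next_mesh()))
    for j in range(n_syn):
        ent = rng.choice([e for e in plantable if e.synonyms])
        plain = [t for t, k in ent.synonyms if k == "SYNONYM"]
        plants.append(Plant("exact_synonym", plain[j % len(plain)], ent.id))
    for j in range(n_rel):
        if j % 2 == 0 or not two_word:
            ent = rng.choice(single_word)
            text = ent.name + "s"  # plural, solvable only after lemmatization
            if j % 4 == 0:
                text = text[0].upper() + text[1:]
        else:
            ent = rng.choice(two_word)
            text = ent.name.replace(" ", "-")  # hyphenation variant
        if text.lower() in folded:
            text = ent.name + "s"  # fall back to the guaranteed-free plural key
        plants.append(Plant("relaxed", text, ent.id))
    for j in range(n_pub):
        name, chebi_id = pubchem_only[j % len(pubchem_only)]
        plants.append(Plant("pubchem", name, chebi_id))
    for j in range(n_fuz):
        ent = rng.choice(single_word)
        text = _misspell(ent.name, folded, relaxed, spec.misspelling_edit_budget)
        plants.append(Plant("fuzzy", text, ent.id))
    groups = syn_groups + pub_groups
    for j in range(n_amb):
        base, members = groups[j % len(groups)]
        member_id, disc = members[j % len(members)]
        plants.append(Plant("ambiguous", base, member_id, disc=disc))
    for j in range(n_abb):
        ent = rng.choice([e for e in single_word if len(e.name) >= 5])
        sf = (ent.name[0] + ent.name[len(ent.name) // 2] + ent.name[-1]).upper()
        plants.append(
            Plant("abbreviation", sf, ent.id, abbrev_def=f"{ent.name} ({sf})")
        )
    plants.append(Plant("water", "water", None))
    plants.append(Plant("short", "qa", None))
    lexicon = build_lexicon(ontology, _rows_to_table(pubchem_rows), _bundle_xref(ontology))
    probe_cfg = MatchConfig()
    for j in range(n_unm):
        text = _unmatchable(rng, lexicon, probe_cfg)
        plants.append(Plant("unmatched", text, None, mesh_id=f"C{700000 + j}"))

    rng.shuffle(plants)

    # --- documents ------------------------------------------------------------
    docs: dict[str, tuple[str, str]] = {}
    for d in range(0, len(plants), spec.mentions_per_title):
        chunk = plants[d : d + spec.mentions_per_title]
        doc_id = str(200001 + d // spec.mentions_per_title)
        ctx_tokens = [p.disc for p in chunk if p.disc] or ["cognitive"]
        title, spans = _title_for([p.text for p in chunk], ctx_tokens)
        for plant, span in zip(chunk, spans):
            plant.doc_id = doc_id
            plant.span = span
        defs = [p.abbrev_def for p in chunk if p.abbrev_def]
        abstract = " ".join(defs) + (" " if defs else "") + "A controlled study in aged cohorts."
        docs[doc_id] = (title, abstract)

    # --- reference MeSH mapping ------------------------------------------------
    reference_rows: list[tuple[str, str]] = []
    exact_plants = [p for p in plants if p.category == "exact_name"]
    for j, plant in enumerate(exact_plants):
        if j % 3 == 0:
            reference_rows.append((plant.mesh_id, plant.gold_id))  # matched
        elif j % 3 == 1:
            parent = next(
                (t for r, t in ontology.entities[plant.gold_id].relations
                 if r == "is_a" and t in ontology.entities),
                None,
            )
            if parent is not None:
                reference_rows.append((plant.mesh_id, parent))  # derived_more_specific
        # j % 3 == 2 -> absent from the reference: derived_new
    for j in range(2):
        reference_rows.append((f"D{777770 + j}", rng.choice(plantable).id))  # reference_only

    return FixtureBundle(
        spec=spec,
        all_entities=entities,
        ontology=ontology,
        pubchem_rows=pubchem_rows,
        plants=plants,
        docs=docs,
        reference_rows=reference_rows,
    )


def _rows_to_table(rows: list[tuple[int, str]]) -> SynonymTable:
    table = SynonymTable()
    for cid, name in rows:
        table.add(cid, name)
    return table


def _bundle_xref(ontology: Ontology) -> CidXref:
    xref = CidXref()
    for ent_id in sorted(ontology.entities):
        for ns, acc in ontology.entities[ent_id].xrefs:
            if ns == "PubChem":
                xref.add(ent_id, int(acc))
    return xref


def _misspell(name: str, folded: set[str], relaxed: set[str], budget: int) -> str:
    """Single-substitution misspelling that no exact or relaxed index can see."""
    del budget  # one substitution; the budget hook is kept for larger fixtures
    letters = "xqzwv"
    for pos in list(range(len(name) // 2, len(name))) + list(range(len(name) // 2)):
        orig = name[pos]
        if not orig.isalpha():
            continue
        for sub in letters:
            if sub == orig:
                continue
            cand = name[:pos] + sub + name[pos + 1 :]
            if cand.lower() not in folded and relax(cand) not in relaxed:
                return cand
    raise ValidationError(f"could not construct a misspelling for {name!r}")


def _group_separable(base: str, discs: tuple[str, str], emb: "TrigramEmbedder") -> bool:
    """True when the doubled context token makes each sibling win its own title."""
    for true_disc in discs:
        title, (span,) = _title_for([base], [true_disc])
        v0 = emb.embed(title)
        scores = {}
        for d in discs:
            cand_title = title[: span[0]] + f"{base} {d}" + title[span[1] :]
            scores[d] = cosine(v0, emb.embed(cand_title))
        if any(scores[true_disc] <= scores[d] for d in discs if d != true_disc):
            return False
    return True


def _draw_discriminable_group(
    namer: _Namer, rng: random.Random, emb: "TrigramEmbedder", group_index: int
) -> tuple[str, tuple[str, str]]:
    """Draw a base name + discriminator pair whose context signal survives hashing.

    Hash collisions in the trigram embedder can swamp the few-trigram margin
    between sibling candidate titles, so the group is only accepted once both
    siblings are separable under the bundled embedder; otherwise a fresh base
    name (and, cyclically, another discriminator pair) is drawn.
    """
    del rng  # freshness comes from the namer's own seeded stream
    for attempt in range(60):
        discs = _DISC_PAIRS[(group_index + attempt) % len(_DISC_PAIRS)]
        base = namer.fresh()
        if _group_separable(base, discs, emb):
            return base, discs
    raise ValidationError("could not draw a context-separable ambiguous group")


def _unmatchable(rng: random.Random, lexicon, cfg: MatchConfig) -> str:
    """A surface verified to yield no candidate at any dictionary level."""
    consonants = "qxzjwkv"
    for _ in range(50):
        text = "".join(rng.choice(consonants) for _ in range(10))
        q = lexicon.fold(text)
        rkey = relax(text)
        if (
            q in lexicon.exact_name
            or q in lexicon.exact_synonym
            or q in lexicon.pubchem_exact
            or rkey in lexicon.relaxed_name_syn
            or rkey in lexicon.pubchem_relaxed
        ):
            continue
        if not fuzzy_candidates(text, lexicon, cfg):
            return text
    raise ValidationError("could not construct an unmatchable mention")


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def generate_ontology(spec: FixtureSpec, out_dir: Optional[str | os.PathLike] = None) -> Ontology:
    """Build the fixture ontology; optionally emit both OBO and TSV dialects."""
    bundle = _build(spec)
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        write_chebi_obo(bundle.all_entities, os.path.join(out_dir, "chebi.obo"))
        write_chebi_tsv(bundle.all_entities, os.path.join(out_dir, "chebi_tsv"))
    return bundle.ontology


def generate_corpus(spec: FixtureSpec, out_dir: Optional[str | os.PathLike] = None) -> FixtureBundle:
    """Build the planted mention corpus (and optionally write all corpus files)."""
    bundle = _build(spec)
    if out_dir is not None:
        write_corpus_files(bundle, out_dir)
    return bundle


def write_corpus_files(bundle: FixtureBundle, out_dir: str | os.PathLike) -> dict[str, str]:
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "pubtator": os.path.join(out_dir, "corpus.pubtator.txt"),
        "gold": os.path.join(out_dir, "gold.tsv"),
        "pubchem": os.path.join(out_dir, "pubchem_synonyms.tsv"),
        "reference": os.path.join(out_dir, "reference_mapping.tsv"),
    }
    by_doc: dict[str, list[Plant]] = {}
    for p in bundle.plants:
        by_doc.setdefault(p.doc_id, []).append(p)
    with open(paths["pubtator"], "w", encoding="utf-8") as fh:
        for doc_id in sorted(by_doc):
            title, abstract = bundle.docs[doc_id]
            fh.write(f"{doc_id}|t|{title}\n{doc_id}|a|{abstract}\n")
            for p in by_doc[doc_id]:
                mesh = f"MESH:{p.mesh_id}" if p.mesh_id else "-"
                fh.write(f"{doc_id}\t{p.span[0]}\t{p.span[1]}\t{p.text}\tChemical\t{mesh}\n")
            fh.write("\n")
    with open(paths["gold"], "w", encoding="utf-8") as fh:
        fh.write("doc_id\tmention\tchebi_id\n")
        for (doc_id, text), gold_id in bundle.gold().items():
            fh.write(f"{doc_id}\t{text}\t{gold_id or 'NONE'}\n")
    with open(paths["pubchem"], "w", encoding="utf-8") as fh:
        for cid, name in bundle.pubchem_rows:
            fh.write(f"{cid}\t{name}\n")
    with open(paths["reference"], "w", encoding="utf-8") as fh:
        for mesh_id, chebi_id in bundle.reference_rows:
            fh.write(f"{mesh_id}\t{chebi_id}\n")
    return paths


def make_fixtures(spec: FixtureSpec, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the complete fixture file set; returns the path map."""
    out_dir = os.fspath(out_dir)
    generate_ontology(spec, out_dir)
    bundle = generate_corpus(spec)
    paths = write_corpus_files(bundle, out_dir)
    paths["obo"] = os.path.join(out_dir, "chebi.obo")
    paths["tsv_dir"] = os.path.join(out_dir, "chebi_tsv")
    return paths


# ---------------------------------------------------------------------------
# toy embedder
# ---------------------------------------------------------------------------

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = (1 << 64) - 1


def _fnv1a64(data: bytes, basis: int) -> int:
    h = basis
    for byte in data:
        h ^= byte
        h = (h * _FNV_PRIME) & _MASK64
    return h


class TrigramEmbedder:
    """Hashed character-trigram bag, L2-normalized.

    Trigrams are taken over the lower-cased text padded with one space on
    each side; each trigram is bucketed with FNV-1a 64 (seed folded into the
    offset basis) modulo the dimension.  Deterministic across platforms and
    processes; identical texts embed identically, and texts sharing no
    trigram hash buckets are orthogonal.
    """

    def __init__(self, dim: int = 256, seed: int = 0):
        if dim < 16:
            raise ValidationError("dim must be >= 16")
        self.dimension = dim
        self.identifier = f"trigram-fnv1a64-d{dim}-s{seed}"
        self._basis = (_FNV_OFFSET ^ (seed * 0x9E3779B97F4A7C15)) & _MASK64

    def embed(self, text: str) -> np.ndarray:
        padded = f" {text.lower()} "
        vec = np.zeros(self.dimension)
        for i in range(len(padded) - 2):
            tri = padded[i : i + 3].encode("utf-8")
            vec[_fnv1a64(tri, self._basis) % self.dimension] += 1.0
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        return vec


def toy_embedder(dim: int = 256, seed: int = 0) -> TrigramEmbedder:
    return TrigramEmbedder(dim=dim, seed=seed)
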