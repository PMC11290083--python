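"""Readers and writers for the ontology, synonym, mention and mapping inputs.

The pipeline consumes five kinds of files:

* a ChEBI ontology dump, either OBO (parsed with :mod:`obonet`) or the
  ChEBI-style flat-file TSV trio (``compounds.tsv``, ``names.tsv``,
  ``relation.tsv`` plus ``database_accession.tsv``),
* a PubChem-style CID -> synonym TSV,
* PubTator-format annotation files carrying chemical mentions,
* a reference MeSH -> ChEBI mapping TSV,
* a gold-standard TSV (read by :mod:`chemnorm.downstream`).

ChEBI entity records carry a curation *status* (single letter; ``C`` curated,
``E`` exists-but-uncurated, others are submitted/deleted/obsolete) and a
*star* rating (3 = curated by the ChEBI team, 2 = curated by a third party).
Only status ``C``/``E`` and 2-3 star entities are retained by default.

Dialect notes: a released OBO file cannot express the status column of the
ChEBI database, so the OBO dialect written by this package carries status as
``property_value: has_status "<S>" xsd:string`` and the star rating as a
``subset: N_STAR`` tag (the convention used by the real ChEBI OBO export).
The TSV dialect carries explicit ``STATUS`` and ``STAR`` columns.

All readers transparently accept gzip-compressed files.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional

import networkx as nx
import obonet

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

CHEBI_ID_RE = re.compile(r"^CHEBI:\d+$")

#: statuses retained by default: curated (C) and exists-uncurated (E)
DEFAULT_STATUS = frozenset({"C", "E"})
#: star ratings retained by default: manual third-party (2) and team (3)
DEFAULT_STARS = frozenset({2, 3})

MENTION_ACTIVE = "active"
MENTION_FILTERED_GENERIC = "filtered_generic"
MENTION_UNMATCHABLE_SHORT = "unmatchable_short"

#: surface forms dropped as uninformative generic mentions
GENERIC_MENTIONS = frozenset({"water"})


def chebi_num(chebi_id: str) -> int:
    """Numeric part of a ``CHEBI:<n>`` accession (used for deterministic tie-breaks)."""
    return int(chebi_id.split(":", 1)[1])


def _open_text(path: str | os.PathLike) -> io.TextIOWrapper:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class ChebiEntity:
    """One ontology record after parsing.

    ``synonyms`` are ``(text, type)`` pairs where *type* is ``"SYNONYM"`` for
    plain synonyms or a named synonym type such as ``"IUPAC NAME"``.
    ``relations`` are ``(relation_type, target_id)`` pairs, including
    ``is_a``.  ``xrefs`` are ``(namespace, accession)`` pairs.
    """

    id: str
    name: str
    synonyms: list[tuple[str, str]] = field(default_factory=list)
    definition: Optional[str] = None
    status: str = "C"
    stars: int = 3
    relations: list[tuple[str, str]] = field(default_factory=list)
    xrefs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not CHEBI_ID_RE.match(self.id):
            raise ParseError(f"malformed ChEBI accession: {self.id!r}")


@dataclass
class Ontology:
    """Filtered entity set plus adjacency indexes over ``is_a`` and ``has_role``.

    Relation edges whose target fell outside the retained entity set are kept
    on the entities and additionally reported in ``dangling`` as
    ``(source_id, relation, target_id)`` triples.
    """

    entities: dict[str, ChebiEntity]
    is_a_index: dict[str, list[str]] = field(default_factory=dict)
    role_index: dict[str, list[str]] = field(default_factory=dict)
    dangling: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.is_a_index and not self.role_index:
            self.rebuild_indexes()

    def rebuild_indexes(self) -> None:
        self.is_a_index = {}
        self.role_index = {}
        self.dangling = []
        for ent in self.entities.values():
            for rel, target in ent.relations:
                if target not in self.entities:
                    self.dangling.append((ent.id, rel, target))
                if rel == "is_a":
                    self.is_a_index.setdefault(ent.id, []).append(target)
                elif rel == "has_role":
                    self.role_index.setdefault(ent.id, []).append(target)

    def name_of(self, chebi_id: str) -> Optional[str]:
        ent = self.entities.get(chebi_id)
        return ent.name if ent is not None else None

    def is_a_ancestors(self, chebi_id: str, include_self: bool = True) -> set[str]:
        """Reflexive-transitive closure over ``is_a`` (unknown targets are kept as ids)."""
        seen: set[str] = set()
        stack = [chebi_id]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(p for p in self.is_a_index.get(cur, ()) if p not in seen)
        if not include_self:
            seen.discard(chebi_id)
        return seen

    def validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.entities)
        for child, parents in self.is_a_index.items():
            for p in parents:
                if p in self.entities:
                    g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(f"is_a graph contains a cycle: {cycle}")

    def __len__(self) -> int:
        return len(self.entities)


@dataclass
class SynonymTable:
    """PubChem CID -> names with its exact transpose."""

    cid_to_names: dict[int, list[str]] = field(default_factory=dict)
    name_to_cids: dict[str, set[int]] = field(default_factory=dict)

    def add(self, cid: int, name: str) -> None:
        names = self.cid_to_names.setdefault(cid, [])
        if name not in names:
            names.append(name)
        self.name_to_cids.setdefault(name, set()).add(cid)

    def __len__(self) -> int:
        return sum(len(v) for v in self.cid_to_names.values())


@dataclass
class CidXref:
    """Bidirectional ChEBI accession <-> PubChem CID lookup."""

    chebi_to_cids: dict[str, list[int]] = field(default_factory=dict)
    cid_to_chebis: dict[int, set[str]] = field(default_factory=dict)

    def add(self, chebi_id: str, cid: int) -> None:
        cids = self.chebi_to_cids.setdefault(chebi_id, [])
        if cid not in cids:
            cids.append(cid)
        self.cid_to_chebis.setdefault(cid, set()).add(chebi_id)


@dataclass
class Mention:
    """One extracted chemical mention anchored in its context text.

    ``span`` is a 0-based half-open character interval into ``context``.
    ``lookup_text`` is the string used for dictionary lookup; it starts equal
    to ``text`` and is rewritten by abbreviation expansion.
    """

    doc_id: str
    text: str
    span: tuple[int, int]
    context: str
    mesh_id: Optional[str] = None
    status: str = MENTION_ACTIVE
    lookup_text: str = ""

    def __post_init__(self) -> None:
        if not self.lookup_text:
            self.lookup_text = self.text
        s, e = self.span
        if self.status == MENTION_ACTIVE and self.context[s:e] != self.text:
            raise ParseError(
                f"doc {self.doc_id}: span {self.span} reads "
                f"{self.context[s:e]!r}, annotation says {self.text!r}"
            )


@dataclass
class MeshChebiMap:
    """MeSH id -> set of ChEBI ids with per-pair support counts.

    ``provenance`` is ``"reference"`` for loaded mappings (e.g. a BioPortal
    export) and ``"derived"`` for mappings induced by normalization results.
    """

    provenance: str
    pairs: dict[str, dict[str, int]] = field(default_factory=dict)

    def add(self, mesh_id: str, chebi_id: str, count: int = 1) -> None:
        if count <= 0:
            raise ValidationError("support counts must be positive")
        row = self.pairs.setdefault(mesh_id, {})
        row[chebi_id] = row.get(chebi_id, 0) + count

    def targets(self, mesh_id: str) -> set[str]:
        return set(self.pairs.get(mesh_id, ()))

    def __len__(self) -> int:
        return sum(len(v) for v in self.pairs.values())


# ---------------------------------------------------------------------------
# ChEBI loading
# ---------------------------------------------------------------------------

_SYN_RE = re.compile(r'^"(?P<text>.*)"\s+(?P<scope>EXACT|RELATED|NARROW|BROAD)'
                     r"(?:\s+(?P<type>[A-Za-z_]+))?\s*(?:\[.*\])?\s*$")
_STATUS_PV_RE = re.compile(r'has_status\s+"(?P<status>[A-Z])"')
_STAR_SUBSET_RE = re.compile(r"^(\d)_STAR$")


def load_chebi(
    path: str | os.PathLike,
    allowed_status: Iterable[str] = DEFAULT_STATUS,
    allowed_stars: Iterable[int] = DEFAULT_STARS,
) -> Ontology:
    """Load and filter a ChEBI dump from OBO or the flat-file TSV directory.

    ``path`` may be an ``.obo``/``.obo.gz`` file or a directory holding the
    TSV trio.  Entities whose status or star rating falls outside the allowed
    sets are dropped; relation edges that end up pointing outside the retained
    set are reported via :attr:`Ontology.dangling`.
    """
    allowed_status = set(allowed_status)
    allowed_stars = set(allowed_stars)
    if not allowed_status or not allowed_stars:
        raise ValidationError("allowed_status and allowed_stars must be non-empty")
    if os.path.isdir(path):
        entities = list(_read_chebi_tsv(os.fspath(path)))
    else:
        entities = list(_read_chebi_obo(path))
    kept = {
        e.id: e
        for e in entities
        if e.status in allowed_status and e.stars in allowed_stars
    }
    onto = Ontology(entities=kept)
    if onto.dangling:
        logger.info("%d relation edges point outside the retained entity set", len(onto.dangling))
    onto.validate()
    return onto


def _read_chebi_obo(path: str | os.PathLike) -> Iterator[ChebiEntity]:
    try:
        with _open_text(path) as fh:
            graph = obonet.read_obo(fh, ignore_obsolete=False)
    except OSError:
        raise
    except Exception as exc:  # obonet raises bare ValueError on bad stanzas
        raise ParseError(f"cannot parse OBO file {path}: {exc}") from exc
    for node, data in graph.nodes(data=True):
        if not data:  # referenced target with no stanza of its own
            continue
        if not CHEBI_ID_RE.match(node):
            continue
        status = "C"
        for pv in data.get("property_value", []):
            m = _STATUS_PV_RE.search(pv)
            if m:
                status = m.group("status")
        if data.get("is_obsolete") == "true" and status in DEFAULT_STATUS:
            status = "O"
        stars = 3
        for subset in data.get("subset", []):
            m = _STAR_SUBSET_RE.match(subset)
            if m:
                stars = int(m.group(1))
        synonyms = []
        for raw in data.get("synonym", []):
            m = _SYN_RE.match(raw)
            if not m:
                raise ParseError(f"stanza {node}: malformed synonym line {raw!r}")
            syn_type = (m.group("type") or "SYNONYM").replace("_", " ")
            synonyms.append((m.group("text"), syn_type))
        definition = None
        if data.get("def"):
            dm = re.match(r'^"(?P<d>.*)"', data["def"], re.S)
            definition = dm.group("d") if dm else data["def"]
        relations = [("is_a", t) for t in data.get("is_a", [])]
        for raw in data.get("relationship", []):
            parts = raw.split()
            if len(parts) < 2:
                raise ParseError(f"stanza {node}: malformed relationship line {raw!r}")
            relations.append((parts[0], parts[1]))
        xrefs = []
        for raw in data.get("xref", []):
            ns, _, acc = raw.partition(":")
            xrefs.append((ns, acc))
        yield ChebiEntity(
            id=node,
            name=data.get("name", node),
            synonyms=synonyms,
            definition=definition,
            status=status,
            stars=stars,
            relations=relations,
            xrefs=xrefs,
        )


def _tsv_rows(path: str, n_cols: int) -> Iterator[list[str]]:
    with _open_text(path) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise ParseError(
                    f"{os.path.basename(path)}:{lineno}: expected {n_cols} columns, got {len(parts)}"
                )
            yield parts
        del header


def _read_chebi_tsv(dirpath: str) -> Iterator[ChebiEntity]:
    compounds = os.path.join(dirpath, "compounds.tsv")
    if not os.path.exists(compounds):
        raise ParseError(f"{dirpath}: missing compounds.tsv")
    entities: dict[str, ChebiEntity] = {}
    for cid_, name, status, star, definition in _tsv_rows(compounds, 5):
        try:
            stars = int(star)
        except ValueError as exc:
            raise ParseError(f"compounds.tsv: non-integer star rating {star!r} for {cid_}") from exc
        entities[cid_] = ChebiEntity(
            id=cid_,
            name=name,
            status=status,
            stars=stars,
            definition=definition or None,
        )
    names_path = os.path.join(dirpath, "names.tsv")
    if os.path.exists(names_path):
        for cid_, name, syn_type in _tsv_rows(names_path, 3):
            if cid_ in entities:
                entities[cid_].synonyms.append((name, syn_type))
    rel_path = os.path.join(dirpath, "relation.tsv")
    if os.path.exists(rel_path):
        for rel_type, subject, obj in _tsv_rows(rel_path, 3):
            if subject in entities:
                entities[subject].relations.append((rel_type, obj))
    acc_path = os.path.join(dirpath, "database_accession.tsv")
    if os.path.exists(acc_path):
        for cid_, source, acc in _tsv_rows(acc_path, 3):
            if cid_ in entities:
                entities[cid_].xrefs.append((source, acc))
    yield from entities.values()


# ---------------------------------------------------------------------------
# ChEBI writing (fixture emission and the round-trip property)
# ---------------------------------------------------------------------------


def write_chebi_tsv(entities: Iterable[ChebiEntity], dirpath: str | os.PathLike) -> None:
    """Emit the flat-file TSV trio (plus accessions) for the given entities."""
    dirpath = os.fspath(dirpath)
    os.makedirs(dirpath, exist_ok=True)
    ents = sorted(entities, key=lambda e: chebi_num(e.id))
    with open(os.path.join(dirpath, "compounds.tsv"), "w", encoding="utf-8") as fh:
        fh.write("ID\tNAME\tSTATUS\tSTAR\tDEFINITION\n")
        for e in ents:
            fh.write(f"{e.id}\t{e.name}\t{e.status}\t{e.stars}\t{e.definition or ''}\n")
    with open(os.path.join(dirpath, "names.tsv"), "w", encoding="utf-8") as fh:
        fh.write("COMPOUND_ID\tNAME\tTYPE\n")
        for e in ents:
            for text, syn_type in e.synonyms:
                fh.write(f"{e.id}\t{text}\t{syn_type}\n")
    with open(os.path.join(dirpath, "relation.tsv"), "w", encoding="utf-8") as fh:
        fh.write("TYPE\tSUBJECT_ID\tOBJECT_ID\n")
        for e in ents:
            for rel, target in e.relations:
                fh.write(f"{rel}\t{e.id}\t{target}\n")
    with open(os.path.join(dirpath, "database_accession.tsv"), "w", encoding="utf-8") as fh:
        fh.write("COMPOUND_ID\tSOURCE\tACCESSION\n")
        for e in ents:
            for ns, acc in e.xrefs:
                fh.write(f"{e.id}\t{ns}\t{acc}\n")


def write_chebi_obo(entities: Iterable[ChebiEntity], path: str | os.PathLike) -> None:
    """Emit the OBO dialect (status as a property_value, stars as N_STAR subsets)."""
    ents = sorted(entities, key=lambda e: chebi_num(e.id))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: chebi-fixture\n")
        for e in ents:
            fh.write(f"\n[Term]\nid: {e.id}\nname: {e.name}\n")
            fh.write(f"subset: {e.stars}_STAR\n")
            fh.write(f'property_value: has_status "{e.status}" xsd:string\n')
            if e.definition:
                fh.write(f'def: "{e.definition}" []\n')
            for text, syn_type in e.synonyms:
                if syn_type == "SYNONYM":
                    fh.write(f'synonym: "{text}" RELATED []\n')
                else:
                    fh.write(f'synonym: "{text}" RELATED {syn_type.replace(" ", "_")} []\n')
            for ns, acc in e.xrefs:
                fh.write(f"xref: {ns}:{acc}\n")
            for rel, target in e.relations:
                if rel == "is_a":
                    fh.write(f"is_a: {target}\n")
                else:
                    fh.write(f"relationship: {rel} {target}\n")
            if e.status == "O":
                fh.write("is_obsolete: true\n")


# ---------------------------------------------------------------------------
# PubChem synonyms and cross-references
# ---------------------------------------------------------------------------


def default_name_filter(name: str) -> bool:
    """Reject structurally inconsistent PubChem names.

    Approximation of the aggregated-substance name cleanup: names containing
    pipes or control characters, empty names, and names longer than 500
    characters are dropped.
    """
    if not name or len(name) > 500:
        return False
    if "|" in name:
        return False
    return not any(ord(c) < 32 for c in name)


def load_pubchem_synonyms(
    path: str | os.PathLike,
    name_filter: Callable[[str], bool] = default_name_filter,
) -> SynonymTable:
    """Read a two-column ``CID<TAB>name`` table, applying the consistency filter."""
    table = SynonymTable()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            raw_cid, name = parts
            try:
                cid = int(raw_cid)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer CID {raw_cid!r}") from exc
            if name_filter(name):
                table.add(cid, name)
    return table


def load_chebi_cid_xref(ontology: Ontology, namespace: str = "PubChem") -> CidXref:
    """Collect PubChem CID cross-references from the retained entities."""
    xref = CidXref()
    for ent in ontology.entities.values():
        cids = [int(acc) for ns, acc in ent.xrefs if ns == namespace and acc.isdigit()]
        if len(cids) > 1:
            logger.warning("%s carries %d PubChem CIDs: %s", ent.id, len(cids), cids)
        for cid in cids:
            xref.add(ent.id, cid)
    return xref


# ---------------------------------------------------------------------------
# PubTator mentions
# ---------------------------------------------------------------------------

_PUBTATOR_TITLE_RE = re.compile(r"^(?P<pmid>\S+)\|t\|(?P<text>.*)$")
_PUBTATOR_ABSTRACT_RE = re.compile(r"^(?P<pmid>\S+)\|a\|(?P<text>.*)$")


def _classify_mention(text: str) -> str:
    if text.lower() in GENERIC_MENTIONS:
        return MENTION_FILTERED_GENERIC
    if len(text) <= 2:
        return MENTION_UNMATCHABLE_SHORT
    return MENTION_ACTIVE


def load_pubtator(
    path: str | os.PathLike,
    keep_types: Iterable[str] = ("Chemical",),
    scope: str = "title",
) -> list[Mention]:
    """Parse a PubTator-format file into :class:`Mention` records.

    With the default ``scope="title"`` only annotations whose span lies inside
    the title line are returned, each carrying the title as context.  With
    ``scope="abstract"`` annotations anywhere in title+abstract are returned
    with the concatenated document text as context (PubTator offsets treat the
    abstract as starting one character after the title).
    """
    keep_types = set(keep_types)
    if scope not in ("title", "abstract"):
        raise ValidationError(f"unknown scope {scope!r}")
    mentions: list[Mention] = []
    titles: dict[str, str] = {}
    abstracts: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            m = _PUBTATOR_TITLE_RE.match(line)
            if m:
                titles[m.group("pmid")] = m.group("text")
                continue
            m = _PUBTATOR_ABSTRACT_RE.match(line)
            if m:
                abstracts[m.group("pmid")] = m.group("text")
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: malformed annotation line")
            pmid, start_s, end_s, text, mtype = parts[:5]
            ann_id = parts[5] if len(parts) > 5 and parts[5] else None
            if mtype not in keep_types:
                continue
            if pmid not in titles:
                raise ParseError(f"{path}:{lineno}: annotation for {pmid} precedes its title line")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer span") from exc
            title = titles[pmid]
            in_title = end <= len(title)
            if scope == "title" and not in_title:
                continue
            context = title if in_title else title + " " + abstracts.get(pmid, "")
            if context[start:end] != text:
                raise ParseError(
                    f"doc {pmid}: span [{start},{end}) reads {context[start:end]!r}, "
                    f"annotation says {text!r}"
                )
            mesh_id = None
            if ann_id and ann_id != "-":
                mesh_id = ann_id[5:] if ann_id.startswith("MESH:") else ann_id
            mentions.append(
                Mention(
                    doc_id=pmid,
                    text=text,
                    span=(start, end),
                    context=context,
                    mesh_id=mesh_id,
                    status=_classify_mention(text),
                )
            )
    return mentions


def document_texts(path: str | os.PathLike) -> dict[str, str]:
    """Full title+abstract text per document (the abbreviation-detection input)."""
    texts: dict[str, str] = {}
    abstracts: dict[str, str] = defaultdict(str)
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            m = _PUBTATOR_TITLE_RE.match(line)
            if m:
                texts[m.group("pmid")] = m.group("text")
                continue
            m = _PUBTATOR_ABSTRACT_RE.match(line)
            if m:
                abstracts[m.group("pmid")] = m.group("text")
    return {pmid: (t + " " + abstracts[pmid]).strip() for pmid, t in texts.items()}


# ---------------------------------------------------------------------------
# reference mappings
# ---------------------------------------------------------------------------


def load_reference_mapping(path: str | os.PathLike) -> MeshChebiMap:
    """Read a two-column ``mesh_id<TAB>chebi_id`` table as a reference mapping."""
    mapping = MeshChebiMap(provenance="reference")
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            mesh_id, chebi_id = parts[0], parts[1]
            if not CHEBI_ID_RE.match(chebi_id):
                raise ParseError(f"{path}:{lineno}: malformed ChEBI id {chebi_id!r}")
            mapping.add(mesh_id, chebi_id)
    return mapping
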