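"""Ontology verbalization: axioms rendered as natural-language sentences.

Every triple, synonym and definition of a retained entity is turned into at
least one human-readable sentence; the resulting corpus is the continued
pretraining input for a domain language model.  ``is_a`` triples are merged
with one plain synonym each into the pattern

    "<name>, otherwise known as <synonym>, is a <parent name>"

and all remaining axioms are rendered standalone through a phrase table
(``has_part`` -> "is partially made up of", ``IUPAC NAME`` -> "has preferred
name", ...) with a generic fallback that replaces underscores with spaces.
At most one synonym is inlined per ``is_a`` sentence to keep sentence length
within typical transformer token limits.
"""

from __future__ import annotations

import logging
import os
import random
from dataclasses import dataclass, field
from typing import Optional

from .errors import ValidationError
from .ontology_io import ChebiEntity, Ontology, chebi_num

logger = logging.getLogger(__name__)

#: default natural-language equivalents for relation and synonym types;
#: injectable — any missing relation falls back to underscores -> spaces
DEFAULT_PHRASES: dict[str, str] = {
    "is_a": "is a",
    "has_part": "is partially made up of",
    "has_role": "has role",
    "SYNONYM": "otherwise known as",
    "IUPAC NAME": "has preferred name",
}

KIND_IS_A = "is_a"
KIND_IS_A_SYNONYM = "is_a+synonym"
KIND_SYNONYM = "synonym"
KIND_RELATION = "relation"
KIND_DEFINITION = "definition"


@dataclass(frozen=True)
class Sentence:
    text: str
    entity_id: str
    kind: str


@dataclass
class VerbalizedCorpus:
    sentences: list[Sentence]
    split: list[str] = field(default_factory=list)  # "train" | "validation", parallel

    @property
    def train(self) -> list[Sentence]:
        return [s for s, sp in zip(self.sentences, self.split) if sp == "train"]

    @property
    def validation(self) -> list[Sentence]:
        return [s for s, sp in zip(self.sentences, self.split) if sp == "validation"]


def _target_name(target: str, ontology: Optional[Ontology], entity_id: str) -> str:
    name = ontology.name_of(target) if ontology is not None else None
    if name is None:
        logger.warning("%s: relation target %s not in ontology; using raw id", entity_id, target)
        return target
    return name


def verbalize_entity(
    entity: ChebiEntity,
    phrases: Optional[dict[str, str]] = None,
    ontology: Optional[Ontology] = None,
) -> list[Sentence]:
    """Render every axiom of one entity; an axiom-free entity yields nothing."""
    table = dict(DEFAULT_PHRASES)
    if phrases:
        table.update(phrases)
    out: list[Sentence] = []
    name = entity.name

    plain_syns = [text for text, syn_type in entity.synonyms if syn_type == "SYNONYM"]
    typed_syns = [(text, t) for text, t in entity.synonyms if t != "SYNONYM"]
    is_a_targets = [t for rel, t in entity.relations if rel == "is_a"]
    other_rels = [(rel, t) for rel, t in entity.relations if rel != "is_a"]

    syn_iter = iter(plain_syns)
    used_syns = 0
    for target in is_a_targets:
        parent = _target_name(target, ontology, entity.id)
        syn = next(syn_iter, None)
        if syn is not None:
            used_syns += 1
            text = f"{name}, {table['SYNONYM']} {syn}, {table['is_a']} {parent}"
            out.append(Sentence(text, entity.id, KIND_IS_A_SYNONYM))
        else:
            out.append(Sentence(f"{name} {table['is_a']} {parent}", entity.id, KIND_IS_A))
    for syn in plain_syns[used_syns:]:
        out.append(Sentence(f"{name} is {table['SYNONYM']} {syn}", entity.id, KIND_SYNONYM))
    for text, syn_type in typed_syns:
        phrase = table.get(syn_type, syn_type.lower())
        out.append(Sentence(f"{name} {phrase} {text}", entity.id, KIND_SYNONYM))
    for rel, target in other_rels:
        phrase = table.get(rel, rel.replace("_", " "))
        obj = _target_name(target, ontology, entity.id)
        out.append(Sentence(f"{name} {phrase} {obj}", entity.id, KIND_RELATION))
    if entity.definition:
        out.append(
            Sentence(f"{name} is defined as: {entity.definition}", entity.id, KIND_DEFINITION)
        )
    return out


def build_corpus(
    ontology: Ontology,
    phrases: Optional[dict[str, str]] = None,
    split_fraction: float = 0.9,
    seed: int = 0,
) -> VerbalizedCorpus:
    """Verbalize the whole ontology and split sentences into train/validation.

    Entities are visited in accession order and the split is a seeded
    permutation of sentence indexes, so the corpus is byte-reproducible.
    """
    if not ontology.entities:
        raise ValidationError("cannot verbalize an empty ontology")
    if not 0.0 < split_fraction < 1.0:
        raise ValidationError("split_fraction must lie strictly between 0 and 1")
    sentences: list[Sentence] = []
    for ent_id in sorted(ontology.entities, key=chebi_num):
        sentences.extend(verbalize_entity(ontology.entities[ent_id], phrases, ontology))
    n_train = int(round(split_fraction * len(sentences)))
    idx = list(range(len(sentences)))
    random.Random(seed).shuffle(idx)
    train_idx = set(idx[:n_train])
    split = ["train" if i in train_idx else "validation" for i in range(len(sentences))]
    return VerbalizedCorpus(sentences=sentences, split=split)


def write_corpus(
    corpus: VerbalizedCorpus,
    path: str | os.PathLike,
    sidecar_path: Optional[str | os.PathLike] = None,
) -> None:
    """One sentence per line; the optional sidecar records provenance and split."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in corpus.sentences:
            fh.write(s.text + "\n")
    if sidecar_path is not None:
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            fh.write("index\tentity_id\tkind\tsplit\n")
            for i, (s, sp) in enumerate(zip(corpus.sentences, corpus.split)):
                fh.write(f"{i}\t{s.entity_id}\t{s.kind}\t{sp}\n")
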