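"""Downstream use of the links: role classification, MeSH mapping, evaluation.

Role classification walks the ontology: the roles of an entity are every
``has_role`` target asserted on the entity or any of its ``is_a`` ancestors,
closed upward over ``is_a`` on the role side (a prodrug is thereby also a
drug and a pharmaceutical).  Entity-side inheritance can be disabled.

The MeSH comparison contrasts the mapping *derived* from normalization
results (mention MeSH id -> linked ChEBI id) with a reference mapping such
as a BioPortal export, assigning each MeSH id to exactly one category.

The evaluation harness scores predictions against a gold table of
``(doc_id, mention, ChEBI id or NONE)`` rows: overall accuracy, accuracy on
the disambiguated subset, and existence-detection precision/recall/F1 swept
over cosine thresholds (a flagged link counts as predicting "no entity").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .disambig import METHOD_EMBEDDER, NormalizationResult
from .errors import ValidationError
from .matcher import MatchLevel
from .ontology_io import MeshChebiMap, Ontology

CAT_MATCHED = "matched"
CAT_MORE_SPECIFIC = "derived_more_specific"
CAT_DERIVED_NEW = "derived_new"
CAT_REFERENCE_ONLY = "reference_only"
CAT_BOTH_UNLINKED = "both_unlinked"
CAT_MISMATCHED = "mismatched"

GOLD_NONE = "NONE"


# ---------------------------------------------------------------------------
# roles
# ---------------------------------------------------------------------------


@dataclass
class RoleAssignment:
    chebi_id: str
    roles: set[str]
    groups: set[str]  # intersection with the configured target role list


def classify_roles(
    chebi_id: str,
    ontology: Ontology,
    target_roles: Optional[Iterable[str]] = None,
    inherit_entity_roles: bool = True,
) -> RoleAssignment:
    """Role closure for one entity.

    ``roles`` = upward ``is_a`` closure of every ``has_role`` target found on
    the entity (and, by default, on its ``is_a`` ancestors).  ``groups`` is
    the intersection with ``target_roles`` when given.
    """
    if chebi_id not in ontology.entities:
        raise ValidationError(f"unknown entity {chebi_id}")
    if inherit_entity_roles:
        entity_closure = ontology.is_a_ancestors(chebi_id)
    else:
        entity_closure = {chebi_id}
    roles: set[str] = set()
    for ent in entity_closure:
        for role in ontology.role_index.get(ent, ()):
            roles |= ontology.is_a_ancestors(role)
    targets = set(target_roles) if target_roles is not None else set()
    return RoleAssignment(chebi_id=chebi_id, roles=roles, groups=roles & targets)


def role_counts(
    results: Sequence[NormalizationResult],
    ontology: Ontology,
    target_roles: Iterable[str],
) -> dict[str, tuple[int, float]]:
    """Per-role mention count and fraction over linked mentions.

    A mention reaching several target roles increments each of them, so
    fractions need not sum to one.
    """
    targets = set(target_roles)
    linked = [r for r in results if r.chebi_id is not None and r.chebi_id in ontology.entities]
    if not linked:
        return {}
    counts: dict[str, int] = {}
    for res in linked:
        assignment = classify_roles(res.chebi_id, ontology, targets)
        for role in assignment.groups:
            counts[role] = counts.get(role, 0) + 1
    n = len(linked)
    return {role: (c, c / n) for role, c in sorted(counts.items())}


# ---------------------------------------------------------------------------
# MeSH <-> ChEBI mapping
# ---------------------------------------------------------------------------


def build_derived_mapping(results: Sequence[NormalizationResult]) -> MeshChebiMap:
    """MeSH id -> linked ChEBI ids induced by the normalization results."""
    mapping = MeshChebiMap(provenance="derived")
    for res in results:
        if res.chebi_id is None or res.mention.mesh_id is None:
            continue
        mapping.add(res.mention.mesh_id, res.chebi_id)
    return mapping


@dataclass
class MappingComparison:
    """Category per MeSH id (a partition) plus aggregate counts."""

    categories: dict[str, str]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            for cat in self.categories.values():
                self.counts[cat] = self.counts.get(cat, 0) + 1


def compare_mappings(
    derived: MeshChebiMap,
    reference: MeshChebiMap,
    ontology: Ontology,
    all_mesh_ids: Optional[Iterable[str]] = None,
) -> MappingComparison:
    """Assign each MeSH id under comparison to exactly one category.

    Duplicate (one-to-many) reference mappings are resolved by prioritizing
    matched pairs: any overlap between derived and reference targets makes
    the id ``matched`` and the remaining reference targets are ignored.
    Otherwise a derived target lying strictly below a reference target in the
    ``is_a`` hierarchy makes the id ``derived_more_specific``; disjoint
    non-ancestral targets are ``mismatched``.  Ids present in one map only
    are ``derived_new`` / ``reference_only``; ids in neither (possible when
    an explicit universe is supplied) are ``both_unlinked``.
    """
    universe: set[str] = set(derived.pairs) | set(reference.pairs)
    if all_mesh_ids is not None:
        universe |= set(all_mesh_ids)
    categories: dict[str, str] = {}
    for mesh_id in universe:
        d = derived.targets(mesh_id)
        r = reference.targets(mesh_id)
        if not d and not r:
            categories[mesh_id] = CAT_BOTH_UNLINKED
        elif d and not r:
            categories[mesh_id] = CAT_DERIVED_NEW
        elif r and not d:
            categories[mesh_id] = CAT_REFERENCE_ONLY
        elif d & r:
            categories[mesh_id] = CAT_MATCHED
        else:
            more_specific = any(
                ref_id in ontology.is_a_ancestors(d_id, include_self=False)
                for d_id in d
                if d_id in ontology.entities
                for ref_id in r
            )
            categories[mesh_id] = CAT_MORE_SPECIFIC if more_specific else CAT_MISMATCHED
    return MappingComparison(categories=categories)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class ThresholdPoint:
    tau: float
    accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass
class EvalReport:
    n: int
    overall_accuracy: float
    disambiguated_n: int
    disambiguated_accuracy: float
    level_counts: dict[str, int]
    thresholds: list[ThresholdPoint] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "overall_accuracy": self.overall_accuracy,
            "disambiguated_n": self.disambiguated_n,
            "disambiguated_accuracy": self.disambiguated_accuracy,
            "level_counts": self.level_counts,
            "thresholds": [
                {
                    "tau": t.tau,
                    "accuracy": t.accuracy,
                    "precision": t.precision,
                    "recall": t.recall,
                    "f1": t.f1,
                }
                for t in self.thresholds
            ],
        }


def _gold_key(doc_id: str, mention_text: str) -> tuple[str, str]:
    return (doc_id, mention_text)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def evaluate(
    predictions: Sequence[NormalizationResult],
    gold: dict[tuple[str, str], Optional[str]],
    taus: Optional[Sequence[float]] = None,
) -> EvalReport:
    """Score predictions against the gold table.

    ``gold`` maps ``(doc_id, mention text)`` to a ChEBI id or ``None`` (no
    entity exists).  Every gold mention must have a prediction.  At each
    threshold, an embedder link scoring below tau counts as predicting "no
    entity" for both the accuracy and the existence-detection P/R/F1
    (positive = an unflagged link is produced; truth = an entity exists).
    """
    by_key: dict[tuple[str, str], NormalizationResult] = {}
    for res in predictions:
        by_key.setdefault(_gold_key(res.mention.doc_id, res.mention.text), res)
    missing = [k for k in gold if k not in by_key]
    if missing:
        raise ValidationError(f"gold mentions without predictions: {missing[:5]} ...")
    pairs = [(by_key[k], gold_id) for k, gold_id in gold.items()]
    n = len(pairs)

    def correct(res: NormalizationResult, gold_id: Optional[str], tau: Optional[float]) -> bool:
        pred = res.chebi_id
        if tau is not None and res.method == METHOD_EMBEDDER and (res.score or 0.0) < tau:
            pred = None
        return pred == gold_id

    overall = sum(correct(r, g, None) for r, g in pairs) / n if n else 0.0
    disamb = [(r, g) for r, g in pairs if r.needs_disambiguation]
    disamb_acc = (
        sum(correct(r, g, None) for r, g in disamb) / len(disamb) if disamb else 0.0
    )
    level_counts: dict[str, int] = {}
    for r, _ in pairs:
        level_counts[r.level.name] = level_counts.get(r.level.name, 0) + 1

    points: list[ThresholdPoint] = []
    for tau in taus or []:
        tp = fp = fn = 0
        for res, gold_id in pairs:
            pred_pos = res.chebi_id is not None and not (
                res.method == METHOD_EMBEDDER and (res.score or 0.0) < tau
            )
            gold_pos = gold_id is not None
            if pred_pos and gold_pos:
                tp += 1
            elif pred_pos and not gold_pos:
                fp += 1
            elif gold_pos and not pred_pos:
                fn += 1
        precision, recall, f1 = _prf(tp, fp, fn)
        acc = sum(correct(r, g, tau) for r, g in pairs) / n if n else 0.0
        points.append(ThresholdPoint(tau, acc, precision, recall, f1))

    return EvalReport(
        n=n,
        overall_accuracy=overall,
        disambiguated_n=len(disamb),
        disambiguated_accuracy=disamb_acc,
        level_counts=level_counts,
        thresholds=points,
    )


def load_gold(path: str) -> dict[tuple[str, str], Optional[str]]:
    """Read the gold TSV ``doc_id<TAB>mention<TAB>chebi_id-or-NONE``."""
    gold: dict[tuple[str, str], Optional[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        del header
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            doc_id, mention_text, chebi_id = line.split("\t")[:3]
            gold[(doc_id, mention_text)] = None if chebi_id == GOLD_NONE else chebi_id
    return gold


def unmatched_report(results: Sequence[NormalizationResult]) -> dict[str, int]:
    """Frequency table of unlinked surface forms (candidate new ontology terms)."""
    freq: dict[str, int] = {}
    for res in results:
        if res.chebi_id is None and res.level is MatchLevel.UNMATCHED:
            key = res.mention.text
            freq[key] = freq.get(key, 0) + 1
    return dict(sorted(freq.items(), key=lambda kv: (-kv[1], kv[0])))
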