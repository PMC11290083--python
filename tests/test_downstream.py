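"""Role closure, MeSH mapping comparison, and the evaluation harness."""

import random

import pytest

from chemnorm.disambig import NormalizationResult
from chemnorm.downstream import (
    CAT_BOTH_UNLINKED,
    CAT_DERIVED_NEW,
    CAT_MATCHED,
    CAT_MORE_SPECIFIC,
    CAT_REFERENCE_ONLY,
    build_derived_mapping,
    classify_roles,
    compare_mappings,
    evaluate,
    role_counts,
)
from chemnorm.errors import ValidationError
from chemnorm.matcher import MatchLevel
from chemnorm.ontology_io import ChebiEntity, Mention, MeshChebiMap, Ontology


def brute_force_roles(ontology, chebi_id):
    """Independent BFS over raw relation lists: is_a* then has_role then is_a*."""

    def ancestors(start):
        seen, queue = set(), [start]
        while queue:
            cur = queue.pop(0)
            if cur in seen:
                continue
            seen.add(cur)
            ent = ontology.entities.get(cur)
            if ent:
                queue.extend(t for r, t in ent.relations if r == "is_a")
        return seen

    roles = set()
    for anc in ancestors(chebi_id):
        ent = ontology.entities.get(anc)
        if not ent:
            continue
        for rel, target in ent.relations:
            if rel == "has_role":
                roles |= ancestors(target)
    return roles


def random_ontology(seed, n=30):
    rng = random.Random(seed)
    ents = {}
    for i in range(n):
        cid = f"CHEBI:{i + 1}"
        relations = []
        if i > 0:
            relations.append(("is_a", f"CHEBI:{rng.randint(1, i)}"))  # earlier id: acyclic
        if rng.random() < 0.4:
            relations.append(("has_role", f"CHEBI:{rng.randint(1, n)}"))
        ents[cid] = ChebiEntity(id=cid, name=f"ent{i}", relations=relations)
    return Ontology(entities=ents)


def _result(doc_id, text, chebi_id, mesh_id=None, method="exact",
            level=MatchLevel.EXACT_NAME, needs_disambiguation=False, score=None):
    mention = Mention(doc_id=doc_id, text=text, span=(0, len(text)), context=text,
                      mesh_id=mesh_id)
    return NormalizationResult(
        mention=mention, chebi_id=chebi_id, method=method, score=score,
        level=level, needs_disambiguation=needs_disambiguation,
    )


class TestClassifyRoles:
    def test_matches_bruteforce_on_random_ontologies(self):
        for seed in range(20):
            onto = random_ontology(seed)
            for cid in onto.entities:
                assert classify_roles(cid, onto).roles == brute_force_roles(onto, cid)

    def test_prodrug_anchor_reports_role_ancestors(self, paper_ontology):
        roles = classify_roles("CHEBI:9150", paper_ontology).roles
        assert {"CHEBI:50266", "CHEBI:23888", "CHEBI:52217"} <= roles

    def test_no_role_anywhere_yields_empty(self, paper_ontology):
        assert classify_roles("CHEBI:63584", paper_ontology).roles == set()

    def test_entity_side_inheritance_togglable(self, paper_ontology):
        # a role asserted only on the is_a parent (lovastatin)
        ent = paper_ontology.entities["CHEBI:40303"]
        ent.relations.append(("has_role", "CHEBI:77777"))
        paper_ontology.rebuild_indexes()
        with_inherit = classify_roles("CHEBI:9150", paper_ontology, inherit_entity_roles=True)
        without = classify_roles("CHEBI:9150", paper_ontology, inherit_entity_roles=False)
        assert "CHEBI:77777" in with_inherit.roles
        assert "CHEBI:77777" not in without.roles
        assert {"CHEBI:50266", "CHEBI:23888", "CHEBI:52217"} <= without.roles
        ent.relations.pop()
        paper_ontology.rebuild_indexes()

    def test_unknown_id_rejected(self, paper_ontology):
        with pytest.raises(ValidationError):
            classify_roles("CHEBI:424242", paper_ontology)


class TestRoleCounts:
    def test_fraction_arithmetic(self, paper_ontology):
        results = [_result(str(i), "simvastatin", "CHEBI:9150") for i in range(4)]
        results += [_result(str(i + 10), "cabazitaxel", "CHEBI:63584") for i in range(6)]
        table = role_counts(results, paper_ontology, ["CHEBI:52217"])
        count, fraction = table["CHEBI:52217"]
        assert (count, fraction) == (4, 0.4)

    def test_multiple_target_roles_both_counted(self, paper_ontology):
        results = [_result("1", "simvastatin", "CHEBI:9150")]
        table = role_counts(results, paper_ontology, ["CHEBI:52217", "CHEBI:23888"])
        assert table["CHEBI:52217"] == (1, 1.0)
        assert table["CHEBI:23888"] == (1, 1.0)

    def test_no_linked_mentions_empty(self, paper_ontology):
        assert role_counts([_result("1", "x", None)], paper_ontology, ["CHEBI:52217"]) == {}


class TestMeshMapping:
    def test_derived_mapping_collects_linked_mesh_pairs(self):
        results = [
            _result("1", "Ladostigil", "CHEBI:177484", mesh_id="C423264"),
            _result("2", "Ladostigil", "CHEBI:177484", mesh_id="C423264"),
            _result("3", "nothing", None, mesh_id="C999999"),
        ]
        derived = build_derived_mapping(results)
        assert derived.targets("C423264") == {"CHEBI:177484"}
        assert derived.pairs["C423264"]["CHEBI:177484"] == 2
        assert derived.targets("C999999") == set()

    def test_comparison_categories(self, paper_ontology):
        derived = MeshChebiMap(provenance="derived")
        derived.add("D1", "CHEBI:9150")   # matched
        derived.add("D2", "CHEBI:9150")   # child of reference CHEBI:40303
        derived.add("D3", "CHEBI:63584")  # absent from reference
        reference = MeshChebiMap(provenance="reference")
        reference.add("D1", "CHEBI:9150")
        reference.add("D1", "CHEBI:40303")  # one-to-many: matched wins
        reference.add("D2", "CHEBI:40303")
        reference.add("D4", "CHEBI:6117")
        comparison = compare_mappings(derived, reference, paper_ontology,
                                      all_mesh_ids={"D5"})
        assert comparison.categories == {
            "D1": CAT_MATCHED,
            "D2": CAT_MORE_SPECIFIC,
            "D3": CAT_DERIVED_NEW,
            "D4": CAT_REFERENCE_ONLY,
            "D5": CAT_BOTH_UNLINKED,
        }

    def test_categories_partition_universe(self, bundle, paper_ontology):
        derived = MeshChebiMap(provenance="derived")
        reference = MeshChebiMap(provenance="reference")
        rng = random.Random(1)
        ids = sorted(bundle.ontology.entities)
        for i in range(30):
            if rng.random() < 0.7:
                derived.add(f"D{i}", rng.choice(ids))
            if rng.random() < 0.7:
                reference.add(f"D{i}", rng.choice(ids))
        comparison = compare_mappings(derived, reference, bundle.ontology,
                                      all_mesh_ids={f"D{i}" for i in range(35)})
        assert set(comparison.categories) == {f"D{i}" for i in range(35)}
        assert sum(comparison.counts.values()) == 35


class TestEvaluate:
    def _pairs(self):
        preds = [
            _result("1", "a", "CHEBI:1"),
            _result("2", "b", "CHEBI:2", needs_disambiguation=True,
                    method="embedder", level=MatchLevel.FUZZY, score=0.9),
            _result("3", "c", "CHEBI:3", needs_disambiguation=True,
                    method="embedder", level=MatchLevel.FUZZY, score=0.4),
            _result("4", "d", None, level=MatchLevel.UNMATCHED),
        ]
        gold = {("1", "a"): "CHEBI:1", ("2", "b"): "CHEBI:2",
                ("3", "c"): "CHEBI:9", ("4", "d"): None}
        return preds, gold

    def test_accuracy_all_correct(self):
        preds = [_result(str(i), "m", "CHEBI:1") for i in range(4)]
        gold = {(str(i), "m"): "CHEBI:1" for i in range(4)}
        assert evaluate(preds, gold).overall_accuracy == 1.0

    def test_accuracy_three_of_four(self):
        preds, gold = self._pairs()
        report = evaluate(preds, gold)
        assert report.overall_accuracy == 0.75
        assert report.disambiguated_n == 2
        assert report.disambiguated_accuracy == 0.5

    def test_precision_recall_f1_arithmetic(self):
        preds = [_result(str(i), "m", "CHEBI:1", method="embedder", score=0.9)
                 for i in range(10)]
        gold = {(str(i), "m"): "CHEBI:1" for i in range(9)}
        gold[("9", "m")] = None  # one false positive
        report = evaluate(preds, gold, taus=[0.0])
        point = report.thresholds[0]
        assert point.precision == pytest.approx(0.9)
        assert point.recall == pytest.approx(1.0)
        assert point.f1 == pytest.approx(18 / 19)

    def test_threshold_flags_convert_links_to_negatives(self):
        preds, gold = self._pairs()
        report = evaluate(preds, gold, taus=[0.0, 0.5])
        loose, tight = report.thresholds
        assert tight.precision >= loose.precision

    def test_missing_prediction_rejected(self):
        preds, gold = self._pairs()
        gold[("99", "zz")] = "CHEBI:7"
        with pytest.raises(ValidationError):
            evaluate(preds, gold)

    def test_accuracy_order_invariant(self):
        preds, gold = self._pairs()
        forward = evaluate(preds, gold).overall_accuracy
        backward = evaluate(list(reversed(preds)), gold).overall_accuracy
        assert forward == backward
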