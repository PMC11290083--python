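"""Readers, writers, filtering rules and mention classification."""

import gzip

import pytest

from chemnorm.errors import ParseError
from chemnorm.ontology_io import (
    ChebiEntity,
    load_chebi,
    load_chebi_cid_xref,
    load_pubchem_synonyms,
    load_pubtator,
    load_reference_mapping,
    write_chebi_obo,
    write_chebi_tsv,
)

OBO_SMALL = """format-version: 1.2
ontology: chebi-test

[Term]
id: CHEBI:9150
name: simvastatin
subset: 3_STAR
property_value: has_status "C" xsd:string
synonym: "MK-733" RELATED []
is_a: CHEBI:40303
relationship: has_role CHEBI:50266

[Term]
id: CHEBI:40303
name: lovastatin
subset: 3_STAR
property_value: has_status "C" xsd:string

[Term]
id: CHEBI:11111
name: deletedol
subset: 3_STAR
property_value: has_status "D" xsd:string

[Term]
id: CHEBI:22222
name: onestarol
subset: 1_STAR
property_value: has_status "C" xsd:string
"""


@pytest.fixture()
def obo_path(tmp_path):
    p = tmp_path / "mini.obo"
    p.write_text(OBO_SMALL, encoding="utf-8")
    return p


class TestLoadChebi:
    def test_status_filter_excludes_deleted(self, obo_path):
        onto = load_chebi(obo_path)
        assert "CHEBI:11111" not in onto.entities
        assert len(onto) == 2

    def test_star_filter_excludes_one_star(self, obo_path):
        onto = load_chebi(obo_path)
        assert "CHEBI:22222" not in onto.entities

    def test_is_a_edge_parsed(self, obo_path):
        onto = load_chebi(obo_path)
        assert ("is_a", "CHEBI:40303") in onto.entities["CHEBI:9150"].relations
        assert onto.is_a_index["CHEBI:9150"] == ["CHEBI:40303"]

    def test_dangling_targets_reported_not_dropped(self, obo_path):
        onto = load_chebi(obo_path)
        # has_role target CHEBI:50266 has no stanza: edge kept, reported
        assert ("has_role", "CHEBI:50266") in onto.entities["CHEBI:9150"].relations
        assert ("CHEBI:9150", "has_role", "CHEBI:50266") in onto.dangling

    def test_gzip_input(self, tmp_path):
        p = tmp_path / "mini.obo.gz"
        with gzip.open(p, "wt", encoding="utf-8") as fh:
            fh.write(OBO_SMALL)
        assert len(load_chebi(p)) == 2

    def test_filter_monotonicity(self, obo_path):
        wide = load_chebi(obo_path, allowed_status={"C", "E", "D"}, allowed_stars={1, 2, 3})
        narrow = load_chebi(obo_path)
        assert set(narrow.entities) <= set(wide.entities)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(OSError):
            load_chebi(tmp_path / "nope.obo")


class TestRoundTrip:
    def test_tsv_round_trip_preserves_entities(self, bundle, tmp_path):
        write_chebi_tsv(bundle.all_entities, tmp_path / "tsv")
        reloaded = load_chebi(tmp_path / "tsv")
        assert set(reloaded.entities) == set(bundle.ontology.entities)
        for cid, ent in bundle.ontology.entities.items():
            got = reloaded.entities[cid]
            assert (got.name, got.synonyms, got.relations) == (
                ent.name,
                ent.synonyms,
                ent.relations,
            )

    def test_obo_and_tsv_dialects_agree(self, bundle, tmp_path):
        write_chebi_obo(bundle.all_entities, tmp_path / "f.obo")
        write_chebi_tsv(bundle.all_entities, tmp_path / "tsv")
        from_obo = load_chebi(tmp_path / "f.obo")
        from_tsv = load_chebi(tmp_path / "tsv")
        assert set(from_obo.entities) == set(from_tsv.entities)
        for cid in from_obo.entities:
            a, b = from_obo.entities[cid], from_tsv.entities[cid]
            assert (a.name, sorted(a.synonyms), sorted(a.relations), a.status, a.stars) == (
                b.name, sorted(b.synonyms), sorted(b.relations), b.status, b.stars
            )

    def test_is_a_index_matches_bruteforce_scan(self, bundle):
        onto = bundle.ontology
        brute = {}
        for ent in onto.entities.values():
            for rel, target in ent.relations:
                if rel == "is_a":
                    brute.setdefault(ent.id, []).append(target)
        assert onto.is_a_index == brute


class TestPubchem:
    def test_name_shared_by_two_cids(self, tmp_path):
        p = tmp_path / "syn.tsv"
        p.write_text("1\tkawain\n2\tkawain\n", encoding="utf-8")
        table = load_pubchem_synonyms(p)
        assert table.name_to_cids["kawain"] == {1, 2}

    def test_empty_file(self, tmp_path):
        p = tmp_path / "syn.tsv"
        p.write_text("", encoding="utf-8")
        assert len(load_pubchem_synonyms(p)) == 0

    def test_filtered_name_absent_from_both_maps(self, tmp_path):
        p = tmp_path / "syn.tsv"
        p.write_text("1\tgood name\n1\tbad|name\n", encoding="utf-8")
        table = load_pubchem_synonyms(p)
        assert table.cid_to_names[1] == ["good name"]
        assert "bad|name" not in table.name_to_cids

    def test_non_integer_cid_raises(self, tmp_path):
        p = tmp_path / "syn.tsv"
        p.write_text("x\tname\n", encoding="utf-8")
        with pytest.raises(ParseError):
            load_pubchem_synonyms(p)

    def test_cid_xref_bidirectional_and_shared(self, paper_ontology):
        xref = load_chebi_cid_xref(paper_ontology)
        assert xref.chebi_to_cids["CHEBI:6117"] == [5281565]
        assert xref.cid_to_chebis[5281565] == {"CHEBI:6117", "CHEBI:91863", "CHEBI:92164"}
        assert "CHEBI:9150" not in xref.chebi_to_cids


PUBTATOR = """123|t|Investigation of Cabazitaxel in a model of disease
123|a|Background text mentioning water and more.
123\t17\t28\tCabazitaxel\tChemical\tMESH:C552428
123\t0\t13\tInvestigation\tDisease\t-

456|t|Role of water and qa in models
456|a|Some abstract.
456\t8\t13\twater\tChemical\t-
456\t18\t20\tqa\tChemical\t-
"""


class TestPubtator:
    @pytest.fixture()
    def pubtator_path(self, tmp_path):
        p = tmp_path / "corpus.txt"
        p.write_text(PUBTATOR, encoding="utf-8")
        return p

    def test_chemical_mentions_in_titles(self, pubtator_path):
        mentions = load_pubtator(pubtator_path)
        assert [m.text for m in mentions] == ["Cabazitaxel", "water", "qa"]
        first = mentions[0]
        assert first.status == "active"
        assert first.mesh_id == "C552428"
        assert first.context[first.span[0] : first.span[1]] == "Cabazitaxel"

    def test_water_flagged_generic(self, pubtator_path):
        mentions = load_pubtator(pubtator_path)
        assert mentions[1].status == "filtered_generic"

    def test_two_char_mention_unmatchable(self, pubtator_path):
        mentions = load_pubtator(pubtator_path)
        assert mentions[2].status == "unmatchable_short"

    def test_span_mismatch_raises(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("9|t|Some title\n9\t0\t4\tWRONG\tChemical\t-\n", encoding="utf-8")
        with pytest.raises(ParseError):
            load_pubtator(p)

    def test_annotation_before_title_raises(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("9\t0\t4\tSome\tChemical\t-\n", encoding="utf-8")
        with pytest.raises(ParseError):
            load_pubtator(p)


class TestReferenceMapping:
    def test_one_to_many_preserved(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text(
            "D008610\tCHEBI:15409\nD008610\tCHEBI:76306\nD008610\tCHEBI:76310\n",
            encoding="utf-8",
        )
        mapping = load_reference_mapping(p)
        assert mapping.targets("D008610") == {"CHEBI:15409", "CHEBI:76306", "CHEBI:76310"}

    def test_duplicate_row_counts_support(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text("D1\tCHEBI:5\nD1\tCHEBI:5\n", encoding="utf-8")
        mapping = load_reference_mapping(p)
        assert mapping.targets("D1") == {"CHEBI:5"}
        assert mapping.pairs["D1"]["CHEBI:5"] == 2

    def test_malformed_chebi_id_raises(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text("D1\tnot-an-id\n", encoding="utf-8")
        with pytest.raises(ParseError):
            load_reference_mapping(p)

    def test_malformed_entity_id_rejected(self):
        with pytest.raises(ParseError):
            ChebiEntity(id="CHX:12", name="x")
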