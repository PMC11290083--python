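import pytest
from hypothesis import settings as hypothesis_settings

from chemnorm.fixtures import FixtureSpec, _build, write_corpus_files

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")
from chemnorm.matcher import build_lexicon
from chemnorm.ontology_io import ChebiEntity, Ontology


@pytest.fixture(scope="session")
def bundle():
    """Default-scale fixture bundle shared across tests (seed 11)."""
    return _build(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def fixture_dir(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_files")
    paths = write_corpus_files(bundle, out)
    from chemnorm.ontology_io import write_chebi_obo, write_chebi_tsv

    obo = out / "chebi.obo"
    write_chebi_obo(bundle.all_entities, obo)
    write_chebi_tsv(bundle.all_entities, out / "chebi_tsv")
    paths["obo"] = str(obo)
    paths["tsv_dir"] = str(out / "chebi_tsv")
    return paths


@pytest.fixture(scope="session")
def lexicon(bundle):
    return build_lexicon(bundle.ontology, bundle.synonym_table, bundle.cid_xref)


def make_entity(chebi_id, name, synonyms=(), relations=(), xrefs=(), **kw):
    return ChebiEntity(
        id=chebi_id,
        name=name,
        synonyms=list(synonyms),
        relations=list(relations),
        xrefs=list(xrefs),
        **kw,
    )


@pytest.fixture()
def paper_ontology():
    """Tiny ontology mirroring the worked examples: statin-like drugs, kawain trio."""
    ents = [
        make_entity("CHEBI:40303", "lovastatin"),
        make_entity(
            "CHEBI:9150",
            "simvastatin",
            relations=[("is_a", "CHEBI:40303"), ("has_role", "CHEBI:50266")],
        ),
        make_entity("CHEBI:50266", "prodrug", relations=[("is_a", "CHEBI:23888")]),
        make_entity("CHEBI:23888", "drug", relations=[("is_a", "CHEBI:52217")]),
        make_entity("CHEBI:52217", "pharmaceutical"),
        make_entity("CHEBI:63584", "cabazitaxel"),
        make_entity(
            "CHEBI:92875",
            "5-(2-chloroethyl)-4-methylthiazole",
            synonyms=[("chlormethiazole", "SYNONYM")],
        ),
        make_entity("CHEBI:6117", "kawain", xrefs=[("PubChem", "5281565")]),
        make_entity(
            "CHEBI:91863",
            "4-methoxy-2-(2-phenylethenyl)-2,3-dihydropyran-6-one",
            xrefs=[("PubChem", "5281565")],
        ),
        make_entity(
            "CHEBI:92164",
            "(2R)-4-methoxy-2-(2-phenylethenyl)-2,3-dihydropyran-6-one",
            xrefs=[("PubChem", "5281565")],
        ),
    ]
    return Ontology(entities={e.id: e for e in ents})
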