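"""Source adapters: dialect parsing, filter rules, identifier mapping."""

import json

import pandas as pd
import pytest

from screendeconv import adapters, chem
from conftest import toy_dir

TOY = toy_dir()


def _toy_library():
    return chem.standardize_library(chem.load_library(TOY / "library.csv"))


@pytest.fixture(scope="module")
def library():
    return _toy_library()


@pytest.fixture(scope="module")
def id_map(library):
    return adapters.map_identifiers(library, TOY / "id_map.tsv")


@pytest.fixture(scope="module")
def gene_map():
    return adapters.load_gene_map(TOY / "gene_map.tsv")


class TestIdentifierMapping:
    def test_salt_compound_resolves_via_parent_key(self, id_map):
        # T004 is the hydrochloride; only its parent key is registered
        assert id_map.sample_ids_for("pubchem", "6341") == ["T004"]

    def test_unmapped_compound_unresolved(self, id_map):
        assert "T007" not in id_map.resolved_sample_ids()
        assert "T006" not in id_map.resolved_sample_ids()  # invalid structure

    def test_empty_mapping_table(self, library, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("inchikey\tsource\tsource_id\n")
        empty = adapters.map_identifiers(library, path)
        assert empty.resolved_sample_ids() == set()

    def test_malformed_rows_skipped_and_counted(self, library, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("inchikey\tsource\tsource_id\n"
                        "LFQSCWFLJHTTHZ-UHFFFAOYSA-N\tdrugbank\tDB00001\n"
                        "bogus-key\tdrugbank\tDB9\n"
                        "LFQSCWFLJHTTHZ-UHFFFAOYSA-N\tnot_a_source\tX\n")
        stats = {}
        m = adapters.map_identifiers(library, path, stats)
        assert stats["malformed_mapping_rows"] == 2
        assert m.sample_ids_for("drugbank", "DB00001") == ["T001"]


class TestDrugbank:
    def test_known_action_and_organism_filters(self, id_map):
        records = adapters.parse_drugbank(TOY / "drugbank.xml", id_map)
        assert [(r.sample_id, r.uniprot_acc) for r in records] == [("T001", "P10001")]
        assert records[0].activity_value_molar is None  # curated: no activity

    def test_nonhuman_target_dropped(self, id_map, tmp_path):
        xml = (TOY / "drugbank.xml").read_text().replace("Humans", "Rat")
        path = tmp_path / "db.xml"
        path.write_text(xml)
        assert adapters.parse_drugbank(path, id_map) == []

    def test_target_without_uniprot_skipped(self, id_map, tmp_path):
        xml = """<drugbank><drug><drugbank-id>DB00001</drugbank-id><targets>
          <target><known-action>yes</known-action><organism>Humans</organism>
          <polypeptide><gene-name>G</gene-name><external-identifiers/></polypeptide>
          </target></targets></drug></drugbank>"""
        path = tmp_path / "db.xml"
        path.write_text(xml)
        stats = {}
        assert adapters.parse_drugbank(path, id_map, stats) == []
        assert stats["drugbank_targets_without_uniprot"] == 1


class TestPharmgkb:
    def test_resolved_and_unresolved_symbols(self, id_map, gene_map):
        stats = {}
        records = adapters.parse_pharmgkb(TOY / "pharmgkb.tsv", id_map, gene_map, stats)
        assert [(r.sample_id, r.uniprot_acc) for r in records] == [("T005", "P10005")]
        assert stats["pharmgkb_unresolved_symbols"] == 1

    def test_unmapped_chemical_ignored(self, library, gene_map, tmp_path):
        path = tmp_path / "empty_map.tsv"
        path.write_text("inchikey\tsource\tsource_id\n")
        empty = adapters.map_identifiers(library, path)
        assert adapters.parse_pharmgkb(TOY / "pharmgkb.tsv", empty, gene_map) == []


class TestIuphar:
    def test_affinity_and_species_filters(self, id_map):
        records = adapters.parse_iuphar(TOY / "iuphar.json", id_map)
        assert len(records) == 1  # the Mouse row is removed
        rec = records[0]
        assert rec.sample_id == "T003" and rec.uniprot_acc == "P10003"
        assert rec.activity_value_molar == pytest.approx(1e-8)
        assert rec.action_field == "Antagonist"

    def test_weak_affinity_removed(self, id_map, tmp_path):
        rows = [{"ligandId": "407", "targetSpecies": "Human",
                 "affinityParameter": "pKi", "affinity": 4.0,
                 "action": "", "targetGeneSymbol": "GENC",
                 "targetUniprot": "P10003"}]
        path = tmp_path / "iuphar.json"
        path.write_text(json.dumps(rows))
        assert adapters.parse_iuphar(path, id_map) == []

    def test_boundary_affinity_is_inclusive(self, id_map, tmp_path):
        rows = [{"ligandId": "407", "targetSpecies": "Human",
                 "affinityParameter": "pKi", "affinity": 5.0,
                 "action": "", "targetGeneSymbol": "GENC",
                 "targetUniprot": "P10003"}]
        path = tmp_path / "iuphar.json"
        path.write_text(json.dumps(rows))
        assert len(adapters.parse_iuphar(path, id_map)) == 1

    def test_unparseable_affinity_counted(self, id_map, tmp_path):
        rows = [{"ligandId": "407", "targetSpecies": "Human",
                 "affinityParameter": "pKi", "affinity": "n/a",
                 "targetUniprot": "P10003"}]
        path = tmp_path / "iuphar.json"
        path.write_text(json.dumps(rows))
        stats = {}
        assert adapters.parse_iuphar(path, id_map, stats) == []
        assert stats["iuphar_unparseable_affinity"] == 1


class TestPubchem:
    def test_unit_conversion_and_cutoff(self, id_map):
        records = adapters.parse_pubchem(TOY / "pubchem.csv", id_map)
        assert len(records) == 1  # the 50 uM row is removed
        assert records[0].activity_value_molar == pytest.approx(5.0e-7)

    def test_boundary_10um_is_inclusive(self, id_map, tmp_path):
        path = tmp_path / "pc.csv"
        path.write_text("cid,target_accession,target_taxonomy,activity_type,"
                        "activity_value,activity_unit\n"
                        "6341,P10004,Homo sapiens,IC50,10,uM\n")
        records = adapters.parse_pubchem(path, id_map)
        assert len(records) == 1

    def test_unknown_unit_dropped_with_count(self, id_map, tmp_path):
        path = tmp_path / "pc.csv"
        path.write_text("cid,target_accession,target_taxonomy,activity_type,"
                        "activity_value,activity_unit\n"
                        "6341,P10004,Homo sapiens,IC50,5,ugmL\n")
        stats = {}
        assert adapters.parse_pubchem(path, id_map, stats) == []
        assert stats["pubchem_unknown_units"] == 1

    def test_qualitative_outcomes_excluded(self, id_map, tmp_path):
        path = tmp_path / "pc.csv"
        path.write_text("cid,target_accession,target_taxonomy,activity_type,"
                        "activity_value,activity_unit\n"
                        "6341,P10004,Homo sapiens,Active,1,nM\n")
        stats = {}
        assert adapters.parse_pubchem(path, id_map, stats) == []
        assert stats["pubchem_nonconcentration_rows"] == 1


class TestChembl:
    def test_pchembl_target_type_and_assay_filters(self, id_map):
        records = adapters.parse_chembl(TOY / "chembl.csv", id_map)
        # pChEMBL 4.9 row and PROTEIN COMPLEX row are removed
        assert [(r.sample_id, r.uniprot_acc) for r in records] == [("T002", "P10002")]
        assert records[0].pchembl == pytest.approx(6.2)
        assert records[0].action_field == "INHIBITOR"
        assert records[0].assay_class == "binding"

    def test_pchembl_5_boundary_is_inclusive(self, id_map, tmp_path):
        path = tmp_path / "ch.csv"
        path.write_text("molecule_chembl_id,target_accession,target_organism,"
                        "target_type,assay_type,standard_type,pchembl_value,action_type\n"
                        "CHEMBL25,P10002,Homo sapiens,SINGLE PROTEIN,B,IC50,5.0,\n")
        assert len(adapters.parse_chembl(path, id_map)) == 1


class TestUserAnnotations:
    def test_direct_join(self, library, gene_map):
        records = adapters.attach_user_annotations(library, gene_map)
        assert [(r.sample_id, r.uniprot_acc) for r in records] == [("T008", "P10001")]
        assert records[0].source == "user"

    def test_blank_column_yields_nothing(self, gene_map, tmp_path):
        path = tmp_path / "lib.csv"
        path.write_text("SMILES,Sample ID,Gene Symbol\nCCO,A1,\n")
        lib = chem.standardize_library(chem.load_library(path))
        assert adapters.attach_user_annotations(lib, gene_map) == []

    def test_unresolvable_symbol_counted(self, gene_map, tmp_path):
        path = tmp_path / "lib.csv"
        path.write_text("SMILES,Sample ID,Gene Symbol\nCCO,A1,NOT_A_GENE\n")
        lib = chem.standardize_library(chem.load_library(path))
        stats = {}
        assert adapters.attach_user_annotations(lib, gene_map, stats) == []
        assert stats["user_unresolved_symbols"] == 1


class TestFilterInvariants:
    def test_emitted_records_satisfy_source_invariants(self, small_bundle, library):
        lib = chem.standardize_library(chem.load_library(small_bundle.paths["library"]))
        id_map = adapters.map_identifiers(lib, small_bundle.paths["id_map"])
        gmap = adapters.load_gene_map(small_bundle.paths["gene_map"])
        records = adapters.parse_all_sources(
            {s: small_bundle.paths[s] for s in
             ("drugbank", "pharmgkb", "iuphar", "pubchem", "chembl")},
            id_map, lib, gmap)
        assert records
        for r in records:
            assert r.organism == "human"
            if r.source in ("iuphar", "pubchem"):
                assert r.activity_value_molar <= 1.0e-5
            if r.source == "chembl":
                assert r.pchembl >= 5.0
            if r.source in adapters.CURATED_SOURCES:
                assert r.activity_type is None and r.activity_value_molar is None

    def test_tightening_cutoff_never_adds_records(self, small_bundle):
        lib = chem.standardize_library(chem.load_library(small_bundle.paths["library"]))
        id_map = adapters.map_identifiers(lib, small_bundle.paths["id_map"])
        for parse, path, kwargs in [
                (adapters.parse_iuphar, small_bundle.paths["iuphar"],
                 "activity_cutoff_molar"),
                (adapters.parse_pubchem, small_bundle.paths["pubchem"],
                 "activity_cutoff_molar")]:
            loose = parse(path, id_map, **{kwargs: 1e-5})
            tight = parse(path, id_map, **{kwargs: 1e-6})
            assert len(tight) <= len(loose)
            tight_keys = {(r.sample_id, r.uniprot_acc, r.activity_value_molar)
                          for r in tight}
            loose_keys = {(r.sample_id, r.uniprot_acc, r.activity_value_molar)
                          for r in loose}
            assert tight_keys <= loose_keys
        loose = adapters.parse_chembl(small_bundle.paths["chembl"], id_map,
                                      pchembl_min=5.0)
        tight = adapters.parse_chembl(small_bundle.paths["chembl"], id_map,
                                      pchembl_min=6.0)
        assert len(tight) <= len(loose)

    def test_row_order_does_not_matter(self, small_bundle, tmp_path):
        lib = chem.standardize_library(chem.load_library(small_bundle.paths["library"]))
        id_map = adapters.map_identifiers(lib, small_bundle.paths["id_map"])
        df = pd.read_csv(small_bundle.paths["chembl"], dtype=str, keep_default_na=False)
        shuffled = df.sample(frac=1, random_state=0)
        path = tmp_path / "shuffled.csv"
        shuffled.to_csv(path, index=False)
        original = adapters.parse_chembl(small_bundle.paths["chembl"], id_map)
        reordered = adapters.parse_chembl(path, id_map)
        key = lambda r: (r.sample_id, r.uniprot_acc, r.pchembl, r.activity_type)
        assert sorted(map(key, original)) == sorted(map(key, reordered))
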