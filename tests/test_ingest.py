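import pandas as pd
import pytest

from slctools import ingest
from slctools.ingest import (
    CHEMBL_COLUMNS,
    GTOPDB_COLUMNS,
    PUBCHEM_COLUMNS,
    FormatError,
    load_chembl_activities,
    load_gtopdb_interactions,
    load_pubchem_bioactivities,
    resolve_parent_compound,
)


def chembl_row(**overrides):
    row = {
        "molecule_chembl_id": "CHEMBL1",
        "parent_chembl_id": "CHEMBL1",
        "canonical_smiles": "CCO",
        "uniprot_accession": "Q91001",
        "organism": "Homo sapiens",
        "confidence_score": "9",
        "data_validity_comment": "",
        "potential_duplicate": "0",
        "src_id": "1",
        "standard_type": "IC50",
        "standard_value": "100",
        "standard_units": "nM",
        "assay_description": "inhibition assay",
    }
    row.update(overrides)
    return row


def write_csv(path, rows, columns):
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path


class TestChemblLoader:
    @pytest.mark.parametrize(
        "overrides, reason",
        [
            ({"confidence_score": "6"}, "confidence<7"),
            ({"src_id": "7"}, "source-excluded"),
            ({"src_id": "58"}, "source-excluded"),
            ({"organism": "Rattus norvegicus"}, "not-human"),
            ({"data_validity_comment": "outside range"}, "data-validity-comment"),
            ({"potential_duplicate": "1"}, "potential-duplicate"),
            ({"standard_type": "Inhibition"}, "activity-type"),
            ({"standard_units": "ug.mL-1"}, "units"),
            ({"standard_value": ""}, "missing-value"),
            ({"standard_value": "-1"}, "nonpositive-value"),
        ],
    )
    def test_each_exclusion_rule_logs_its_reason(
        self, tmp_path, slc_ref, id_map, overrides, reason
    ):
        path = write_csv(
            tmp_path / "c.csv", [chembl_row(**overrides)], CHEMBL_COLUMNS
        )
        records, report = load_chembl_activities(path, slc_ref, id_map)
        assert len(records) == 0
        assert report[reason] == 1

    def test_micromolar_values_convert_to_nanomolar(
        self, tmp_path, slc_ref, id_map
    ):
        path = write_csv(
            tmp_path / "c.csv",
            [chembl_row(standard_value="1", standard_units="uM")],
            CHEMBL_COLUMNS,
        )
        records, _ = load_chembl_activities(path, slc_ref, id_map)
        assert records.loc[0, "value_nM"] == 1000.0
        assert records.loc[0, "p_activity"] == pytest.approx(6.0)

    def test_gene_joined_by_accession_and_output_passes_all_filters(
        self, tmp_path, slc_ref, id_map
    ):
        rows = [
            chembl_row(),
            chembl_row(uniprot_accession="P00000"),  # not an SLC: kept, flagged
            chembl_row(organism="Human", standard_type="Ki"),
        ]
        path = write_csv(tmp_path / "c.csv", rows, CHEMBL_COLUMNS)
        records, report = load_chembl_activities(path, slc_ref, id_map)
        assert len(records) + sum(report.values()) == len(rows)
        assert records.loc[0, "gene_name"] == "SLC91A1"
        assert records.loc[0, "is_slc"]
        assert not records.loc[1, "is_slc"]
        assert set(records["activity_type"]) <= {"pIC50", "pKi", "pEC50", "pKd"}
        assert (records["value_nM"] > 0).all()

    def test_empty_file_yields_empty_records_and_report(
        self, tmp_path, slc_ref, id_map
    ):
        path = write_csv(tmp_path / "c.csv", [], CHEMBL_COLUMNS)
        records, report = load_chembl_activities(path, slc_ref, id_map)
        assert len(records) == 0 and sum(report.values()) == 0

    def test_unparseable_file_raises_format_error(self, tmp_path, slc_ref, id_map):
        path = tmp_path / "bad.csv"
        path.write_text("just,two,columns\n1,2,3\n")
        with pytest.raises(FormatError):
            load_chembl_activities(path, slc_ref, id_map)


def gtopdb_row(**overrides):
    row = {
        "ligand_id": "L1",
        "ligand_pubchem_sid": "S1",
        "target_gene_symbol": "SLC91A1",
        "target_species": "Human",
        "type": "IC50",
        "affinity_low": "10",
        "affinity_high": "",
        "affinity_units": "nM",
    }
    row.update(overrides)
    return row


class TestGtopdbLoader:
    def test_range_rows_average_their_endpoints(self, tmp_path, slc_ref, id_map):
        path = write_csv(
            tmp_path / "g.csv",
            [gtopdb_row(affinity_low="10", affinity_high="100")],
            GTOPDB_COLUMNS,
        )
        records, _ = load_gtopdb_interactions(path, slc_ref, id_map)
        assert records.loc[0, "value_nM"] == 55.0

    @pytest.mark.parametrize(
        "overrides, reason",
        [
            ({"target_species": "Rat"}, "not-human"),
            ({"target_gene_symbol": "GPR55"}, "not-slc"),
            ({"affinity_low": ""}, "missing-value"),
            ({"affinity_units": ">"}, "units"),
            ({"ligand_pubchem_sid": "S999"}, "unresolved-compound"),
        ],
    )
    def test_exclusions(self, tmp_path, slc_ref, id_map, overrides, reason):
        path = write_csv(tmp_path / "g.csv", [gtopdb_row(**overrides)], GTOPDB_COLUMNS)
        records, report = load_gtopdb_interactions(path, slc_ref, id_map)
        assert len(records) == 0 and report[reason] == 1

    def test_compound_resolution_chain_and_cid_fallback(
        self, tmp_path, slc_ref, id_map
    ):
        rows = [
            gtopdb_row(ligand_pubchem_sid="S1"),  # S1->C1->K1->K0
            gtopdb_row(ligand_pubchem_sid="S2"),  # S2->C2, no canonical: CID key
        ]
        path = write_csv(tmp_path / "g.csv", rows, GTOPDB_COLUMNS)
        records, _ = load_gtopdb_interactions(path, slc_ref, id_map)
        assert list(records["compound_id"]) == ["K0", "C2"]


def pubchem_row(**overrides):
    row = {
        "aid": "100",
        "source_name": "Screening Center",
        "target_entrez": "990001",
        "cid": "C1",
        "activity_type": "IC50",
        "activity_value": "50",
        "activity_units": "nM",
    }
    row.update(overrides)
    return row


class TestPubchemLoader:
    @pytest.mark.parametrize(
        "overrides, reason",
        [
            ({"source_name": "ChEMBL"}, "source-excluded"),
            ({"source_name": "IUPHAR-DB"}, "source-excluded"),
            ({"activity_value": ""}, "missing-value"),
            ({"target_entrez": "123"}, "not-slc"),
        ],
    )
    def test_exclusions(self, tmp_path, slc_ref, id_map, overrides, reason):
        path = write_csv(
            tmp_path / "p.csv", [pubchem_row(**overrides)], PUBCHEM_COLUMNS
        )
        records, report = load_pubchem_bioactivities(path, slc_ref, id_map)
        assert len(records) == 0 and report[reason] == 1

    def test_counts_balance_and_parent_resolution(self, tmp_path, slc_ref, id_map):
        rows = [
            pubchem_row(),
            pubchem_row(cid="C2"),
            pubchem_row(source_name="ChEMBL"),
        ]
        path = write_csv(tmp_path / "p.csv", rows, PUBCHEM_COLUMNS)
        records, report = load_pubchem_bioactivities(path, slc_ref, id_map)
        assert len(records) + sum(report.values()) == len(rows)
        assert list(records["compound_id"]) == ["K0", "C2"]
        assert records["is_slc"].all()


class TestResolveParent:
    def test_full_chain(self, id_map):
        res = resolve_parent_compound("S1", id_map)
        assert (res.compound_id, res.tag) == ("K0", "parent")

    def test_cid_fallback(self, id_map):
        res = resolve_parent_compound("C2", id_map)
        assert (res.compound_id, res.tag) == ("C2", "cid-fallback")

    def test_unknown_accession_is_unresolved(self, id_map):
        assert resolve_parent_compound("NOPE", id_map).tag == "unresolved"

    def test_idempotent_on_parents(self, id_map):
        parent = resolve_parent_compound("S1", id_map).compound_id
        again = resolve_parent_compound(parent, id_map)
        assert (again.compound_id, again.tag) == (parent, "parent")

    def test_empty_raises(self, id_map):
        with pytest.raises(ValueError):
            resolve_parent_compound("", id_map)
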