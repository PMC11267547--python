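import numpy as np
import pandas as pd
import pytest

from slctools.ingest import IdentifierMap, SlcReference
from slctools.pipeline import RunConfig, run_pipeline
from slctools.synthetic import GeneratorConfig, generate_source_bundle

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def slc_ref() -> SlcReference:
    return SlcReference(
        pd.DataFrame(
            {
                "gene_symbol": ["SLC91A1", "SLC91A2", "SLC92A1"],
                "uniprot_accession": ["Q91001", "Q91002", "Q92001"],
                "entrez_id": ["990001", "990002", "990003"],
                "family_name": ["SLC91", "SLC91", "SLC92"],
            }
        )
    )


@pytest.fixture(scope="session")
def id_map() -> IdentifierMap:
    return IdentifierMap(
        substance_to_cid={"S1": "C1", "S2": "C2"},
        cid_to_canonical={"C1": "K1"},
        child_to_parent={"K1": "K0"},
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return generate_source_bundle(outdir, GeneratorConfig(), seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def pipeline_result(bundle, tmp_path_factory):
    b, _ = bundle
    config = RunConfig(
        chembl=b.chembl,
        gtopdb=b.gtopdb,
        pubchem=b.pubchem,
        slc_table=b.slc_table,
        substance_to_cid=b.substance_to_cid,
        cid_to_chembl=b.cid_to_chembl,
        child_to_parent=b.child_to_parent,
        pains=b.pains,
        curated=b.curated,
        outdir=tmp_path_factory.mktemp("out"),
    )
    return run_pipeline(config)


def summaries_frame(rows):
    """Build a per-(compound, target) summary frame from compact tuples:
    (compound_id, accession, gene, is_slc, median_p)."""
    return pd.DataFrame(
        [
            {
                "compound_id": c,
                "target_accession": acc,
                "gene_name": gene,
                "is_slc": slc,
                "median_p_activity": p,
                "n_records": 1,
                "activity_types_pooled": "pIC50",
                "per_type_medians": "{}",
            }
            for c, acc, gene, slc, p in rows
        ]
    )
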