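import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from slctools import harmonize


def records_frame(rows):
    """(compound, target, type, p, smiles, description) tuples -> records."""
    return pd.DataFrame(
        [
            {
                "compound_id": c,
                "smiles": smi,
                "target_accession": acc,
                "gene_name": acc,
                "is_slc": True,
                "source": "chembl",
                "activity_type": t,
                "p_activity": p,
                "value_nM": 10 ** (9 - p),
                "assay_description": desc,
                "reference": "ref",
            }
            for c, acc, t, p, smi, desc in rows
        ]
    )


@pytest.mark.parametrize(
    "value_nM, expected",
    [(1000.0, 6.0), (1.0, 9.0), (200.0, 6.698970004336019)],
)
def test_pactivity_of_known_potencies(value_nM, expected):
    assert harmonize.to_pactivity(value_nM) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("bad", [0.0, -1.0, float("nan")])
def test_pactivity_rejects_nonpositive_potencies(bad):
    with pytest.raises(ValueError):
        harmonize.to_pactivity(bad)


@given(st.floats(min_value=0.0, max_value=12.0))
@settings(deadline=None, derandomize=True)
def test_pactivity_round_trip(p):
    assert harmonize.to_pactivity(harmonize.from_pactivity(p)) == pytest.approx(
        p, abs=1e-9
    )


def test_activity_type_whitelist_drops_other_types():
    recs = records_frame(
        [
            ("A", "Q1", "pIC50", 6.0, "CCO", ""),
            ("A", "Q1", "pKB", 6.0, "CCO", ""),
            ("A", "Q1", "pKi", 7.0, "CCO", ""),
            ("A", "Q1", "pEC50", np.nan, "CCO", ""),
        ]
    )
    out = harmonize.filter_activity_types(recs)
    assert list(out["activity_type"]) == ["pIC50", "pKi"]


def test_mutant_filter_is_case_insensitive_substring():
    recs = records_frame(
        [
            ("A", "Q1", "pIC50", 6.0, "", "Inhibition of the T199A mutant transporter"),
            ("A", "Q1", "pIC50", 6.5, "", "wild-type uptake assay"),
            ("A", "Q1", "pIC50", 7.0, "", "MUTANT channel block"),
        ]
    )
    out = harmonize.filter_mutant(recs)
    assert list(out["p_activity"]) == [6.5]


def test_deduplicate_unique_on_six_field_key_and_idempotent():
    rows = [
        ("A", "Q1", "pIC50", 6.0, "CCO", ""),
        ("A", "Q1", "pIC50", 6.0, "CCO", ""),  # exact duplicate
        ("A", "Q1", "pIC50", 7.0, "CCO", ""),  # differs in value: kept
        ("A", "Q1", "pKi", 6.0, "CCO", ""),    # differs in type: kept
        ("A", "Q1", "pIC50", 6.0, None, ""),   # missing SMILES == empty key
        ("A", "Q1", "pIC50", 6.0, "", ""),     # duplicate of the above
    ]
    recs = records_frame(rows)
    out = harmonize.deduplicate(recs)
    assert len(out) == 4
    again = harmonize.deduplicate(out)
    pd.testing.assert_frame_equal(out, again)


def test_median_aggregation_pools_types_and_orders_are_irrelevant():
    rows = [
        ("A", "Q1", "pIC50", 6.0, "CCO", ""),
        ("A", "Q1", "pKi", 7.0, "CCO", ""),
        ("A", "Q1", "pEC50", 8.0, "CCO", ""),
        ("A", "Q2", "pIC50", 6.0, "CCO", ""),
        ("A", "Q2", "pIC50", 8.0, "CCO", ""),
        ("B", "Q1", "pKd", 5.5, "CC", ""),
    ]
    recs = records_frame(rows)
    out = harmonize.aggregate_median(recs)
    by_key = out.set_index(["compound_id", "target_accession"])
    assert by_key.loc[("A", "Q1"), "median_p_activity"] == 7.0  # odd count
    assert by_key.loc[("A", "Q2"), "median_p_activity"] == 7.0  # even midpoint
    assert by_key.loc[("B", "Q1"), "median_p_activity"] == 5.5  # single record
    assert by_key.loc[("A", "Q1"), "n_records"] == 3
    # permutation invariance
    shuffled = recs.sample(frac=1.0, random_state=3).reset_index(drop=True)
    pd.testing.assert_frame_equal(out, harmonize.aggregate_median(shuffled))


def test_median_lies_between_min_and_max_of_contributions():
    rng = np.random.default_rng(0)
    rows = []
    for c in "ABC":
        for acc in ("Q1", "Q2"):
            for p in rng.uniform(4, 9, size=rng.integers(1, 6)):
                rows.append((c, acc, "pIC50", float(p), "CCO", ""))
    recs = records_frame(rows)
    out = harmonize.aggregate_median(recs)
    for r in out.itertuples():
        grp = recs.loc[
            (recs.compound_id == r.compound_id)
            & (recs.target_accession == r.target_accession),
            "p_activity",
        ]
        assert grp.min() <= r.median_p_activity <= grp.max()


def test_compounds_never_tested_on_an_slc_are_discarded_entirely():
    rows = [
        ("A", "QK", "pIC50", 9.0, "", ""),  # kinase only: dropped
        ("B", "QS", "pIC50", 6.0, "", ""),
        ("B", "QK", "pIC50", 7.0, "", ""),  # kept: B tested on an SLC
    ]
    recs = records_frame(rows)
    recs.loc[recs.target_accession == "QK", "is_slc"] = False
    out = harmonize.restrict_to_slc_testers(harmonize.aggregate_median(recs))
    assert set(out["compound_id"]) == {"B"}
    assert len(out) == 2
    empty = harmonize.restrict_to_slc_testers(out.iloc[0:0])
    assert len(empty) == 0


def test_each_filter_output_is_subset_of_input():
    rng = np.random.default_rng(5)
    rows = [
        (
            f"C{i % 7}",
            f"Q{i % 4}",
            rng.choice(["pIC50", "pKi", "pKB"]),
            float(rng.uniform(4, 9)),
            "CCO",
            rng.choice(["assay", "mutant assay"]),
        )
        for i in range(60)
    ]
    recs = records_frame(rows)
    for fn in (
        harmonize.filter_activity_types,
        harmonize.filter_mutant,
        harmonize.deduplicate,
    ):
        out = fn(recs)
        assert len(out) <= len(recs)
        merged = out.merge(recs.drop_duplicates(), how="left", indicator=True)
        assert (merged["_merge"] == "both").all()
        recs = out
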