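"""Post-concatenation harmonisation of activity records.

After the per-source loaders, the records from all sources are concatenated
and pushed through a fixed sequence of filters: activity-type whitelist,
mutant-assay exclusion, exact deduplication, then aggregation to one median
pActivity per (compound, target) pair.  Compounds never tested on at least
one SLC are discarded entirely.
"""

from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVITY_TYPE_WHITELIST",
    "to_pactivity",
    "from_pactivity",
    "concat_sources",
    "filter_activity_types",
    "filter_mutant",
    "deduplicate",
    "aggregate_median",
    "restrict_to_slc_testers",
    "SUMMARY_COLUMNS",
]

#: Negative-log activity types retained after concatenation.
ACTIVITY_TYPE_WHITELIST = frozenset({"pIC50", "pKi", "pEC50", "pKd"})

#: Column schema of the per-(compound, target) summary table.
SUMMARY_COLUMNS = [
    "compound_id",
    "target_accession",
    "gene_name",
    "is_slc",
    "median_p_activity",
    "n_records",
    "activity_types_pooled",
    "per_type_medians",
]

#: 1 nM corresponds to pActivity 9 (1e-9 M).
_P_NM_OFFSET = 9.0


def to_pactivity(value_nM):
    """Negative base-10 logarithm of a molar potency given in nM.

    ``to_pactivity(1000) == 6.0`` (1 uM), ``to_pactivity(1) == 9.0``.
    Accepts scalars or arrays; values must be strictly positive.
    """
    arr = np.asarray(value_nM, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("potency values must be positive and finite")
    out = _P_NM_OFFSET - np.log10(arr)
    return float(out) if np.isscalar(value_nM) or arr.ndim == 0 else out


def from_pactivity(p):
    """Inverse of :func:`to_pactivity`: pActivity back to nM."""
    arr = np.asarray(p, dtype=float)
    out = np.power(10.0, _P_NM_OFFSET - arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def concat_sources(frames) -> pd.DataFrame:
    """Concatenate per-source record tables into one frame."""
    frames = [f for f in frames if len(f)]
    if not frames:
        from .ingest import _empty_records

        return _empty_records()
    return pd.concat(frames, ignore_index=True)


def filter_activity_types(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only whitelist activity types with non-empty pActivity values."""
    keep = records["activity_type"].isin(ACTIVITY_TYPE_WHITELIST) & records[
        "p_activity"
    ].notna()
    return records.loc[keep].reset_index(drop=True)


def filter_mutant(records: pd.DataFrame) -> pd.DataFrame:
    """Drop records whose assay description mentions a mutant protein.

    Matching is a case-insensitive plain substring test for "mutant", the
    glob-with-wildcards rule expressed directly.
    """
    desc = records["assay_description"].fillna("").astype(str)
    keep = ~desc.str.contains("mutant", case=False, regex=False)
    return records.loc[keep].reset_index(drop=True)


#: Fields identifying a duplicate measurement across sources.
DEDUP_KEY = [
    "activity_type",
    "p_activity",
    "compound_id",
    "smiles",
    "gene_name",
    "target_accession",
]


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per duplicate key, first occurrence wins.

    The key is (activity type, activity value, parent compound accession,
    SMILES, gene name, protein accession); records lacking a structure
    participate with an empty-string SMILES.  Idempotent.
    """
    work = records.copy()
    work["smiles"] = work["smiles"].fillna("")
    return work.drop_duplicates(subset=DEDUP_KEY, keep="first").reset_index(drop=True)


def aggregate_median(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate deduplicated records to one median pActivity per
    (compound, target) pair.

    The median pools all whitelist activity types together; per-type medians
    are retained as JSON metadata for transparency.  Output order is sorted
    by (compound_id, target_accession) for determinism.
    """
    if not len(records):
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    rows = []
    grouped = records.groupby(["compound_id", "target_accession"], sort=True)
    for (compound, accession), grp in grouped:
        p = grp["p_activity"].to_numpy(dtype=float)
        types = sorted(set(grp["activity_type"]))
        per_type = {
            t: float(np.median(grp.loc[grp["activity_type"] == t, "p_activity"]))
            for t in types
        }
        rows.append(
            {
                "compound_id": compound,
                "target_accession": accession,
                "gene_name": grp["gene_name"].iloc[0],
                "is_slc": bool(grp["is_slc"].iloc[0]),
                "median_p_activity": float(np.median(p)),
                "n_records": int(len(grp)),
                "activity_types_pooled": ";".join(types),
                "per_type_medians": json.dumps(per_type, sort_keys=True),
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def restrict_to_slc_testers(summaries: pd.DataFrame) -> pd.DataFrame:
    """Discard compounds that were not tested on at least one SLC.

    All rows of such compounds are removed, including their non-SLC target
    rows.
    """
    if not len(summaries):
        return summaries.reset_index(drop=True)
    testers = set(summaries.loc[summaries["is_slc"], "compound_id"])
    return summaries.loc[summaries["compound_id"].isin(testers)].reset_index(drop=True)
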