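"""Merging manually curated compound-SLC lists and probe cross-checks.

Curated lists (consortium collections, external probe portals) carry
compound-SLC associations with provenance but usually no dose-response
value.  Pairs already present in the mined database rows are flagged with a
provenance column; pairs absent from the databases are appended as
curated-only rows with empty activity, counted in the merge report.  They
are excluded from entropy and Pareto computation upstream (nothing to
score) but appear in the full table.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = [
    "read_curated",
    "merge_curated",
    "crosscheck_probes",
    "CURATED_COLUMNS",
]

CURATED_COLUMNS = ["compound_id", "slc_gene", "list_name", "reference"]


def read_curated(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CURATED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: curated list missing columns {missing}")
    return df[CURATED_COLUMNS]


def _pair_key(compound_id, gene):
    return compound_id.astype(str) + "\t" + gene.astype(str).str.upper()


def merge_curated(full_list: pd.DataFrame, curated: pd.DataFrame, slc_genes=None):
    """Annotate the full inhibitor list with curated-list provenance.

    Joins on (compound accession, SLC gene symbol), case-insensitive on the
    symbol.  Returns ``(annotated, report)`` where ``report`` maps each list
    name to ``{"overlapping": ..., "curated_only": ...}`` with
    ``overlapping + curated_only == number of distinct curated pairs`` for
    that list.  Curated pairs with a gene symbol outside ``slc_genes`` (when
    given) are kept but flagged unmatched, with a warning.  Idempotent:
    merging the same list twice changes nothing after the first merge.
    """
    out = full_list.copy()
    report: dict = {}
    for list_name, grp in curated.groupby("list_name", sort=True):
        col = f"in_{list_name}"
        if col not in out.columns:
            out[col] = False
        pairs = grp.drop_duplicates(subset=["compound_id", "slc_gene"])
        keys = _pair_key(out["compound_id"], out["gene_name"])
        curated_keys = _pair_key(pairs["compound_id"], pairs["slc_gene"])
        hit = curated_keys.isin(set(keys))
        out.loc[keys.isin(set(curated_keys)), col] = True
        missing = pairs.loc[~hit]
        appended = 0
        new_rows = []
        for r in missing.itertuples(index=False):
            unmatched = slc_genes is not None and r.slc_gene.upper() not in {
                g.upper() for g in slc_genes
            }
            if unmatched:
                warnings.warn(
                    f"curated list {list_name!r}: unknown SLC symbol {r.slc_gene!r}"
                )
            row = {c: pd.NA for c in out.columns}
            row.update(
                {
                    "compound_id": r.compound_id,
                    "gene_name": r.slc_gene,
                    "is_slc": not unmatched,
                    "source": "curated",
                    "reference": r.reference,
                    col: True,
                }
            )
            new_rows.append(row)
            appended += 1
        if new_rows:
            addition = pd.DataFrame(new_rows).dropna(axis=1, how="all")
            out = pd.concat([out, addition], ignore_index=True)
        report[list_name] = {
            "overlapping": int(hit.sum()),
            "curated_only": int(appended),
        }
    return out.reset_index(drop=True), report


def crosscheck_probes(full_list: pd.DataFrame, probes: pd.DataFrame) -> dict:
    """Cross-check an external probe list against the ranked full list.

    ``full_list`` must carry ``pareto_rank`` and ``shortlisted`` columns.
    Returns per-pair results (found, rank, shortlisted) and summary counts:
    how many probe pairs were found, how many rank first, how many pass the
    tool-compound criteria.
    """
    keys = _pair_key(full_list["compound_id"], full_list["gene_name"])
    indexed = full_list.set_index(keys)
    results = []
    for r in probes.drop_duplicates(subset=["compound_id", "slc_gene"]).itertuples(
        index=False
    ):
        key = f"{r.compound_id}\t{r.slc_gene.upper()}"
        if key in indexed.index:
            row = indexed.loc[key]
            if isinstance(row, pd.DataFrame):
                row = row.iloc[0]
            rank = row.get("pareto_rank")
            results.append(
                {
                    "compound_id": r.compound_id,
                    "slc_gene": r.slc_gene,
                    "found": True,
                    "pareto_rank": None if pd.isna(rank) else int(rank),
                    "shortlisted": bool(row.get("shortlisted", False)),
                }
            )
        else:
            results.append(
                {
                    "compound_id": r.compound_id,
                    "slc_gene": r.slc_gene,
                    "found": False,
                    "pareto_rank": None,
                    "shortlisted": False,
                }
            )
    return {
        "pairs": results,
        "n_probes": len(results),
        "n_found": sum(r["found"] for r in results),
        "n_rank1": sum(1 for r in results if r["pareto_rank"] == 1),
        "n_pass": sum(r["shortlisted"] for r in results),
    }
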