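"""End-to-end pipeline: ingest -> harmonize -> score -> flag -> merge -> report.

``run_pipeline`` wires the stage modules together, writes the full
inhibitor list, tool-compound shortlist, flag and score tables, a
marginal-count summary (compounds by number of SLCs tested), the
dashboard-ready JSON payload, and a filter report recording every
exclusion count.  All outputs are deterministic for fixed inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import criteria, curated, harmonize, ingest, selectivity

__all__ = ["RunConfig", "PipelineResult", "StageError", "run_pipeline",
           "write_marginal_counts", "build_dashboard_payload"]

log = logging.getLogger("slctools")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    chembl: Path
    gtopdb: Path
    pubchem: Path
    slc_table: Path
    substance_to_cid: Path
    cid_to_chembl: Path
    child_to_parent: Path
    pains: Path
    outdir: Path
    curated: Path | None = None
    potency_nM: float = criteria.POTENCY_NM_DEFAULT
    fold: float = criteria.FOLD_DEFAULT
    pains_unknown_blocks: bool = True

    def criteria_config(self) -> criteria.CriteriaConfig:
        return criteria.CriteriaConfig(
            potency_nM=self.potency_nM,
            fold=self.fold,
            pains_unknown_blocks=self.pains_unknown_blocks,
        )


@dataclass
class PipelineResult:
    records: pd.DataFrame
    summaries: pd.DataFrame
    scores: pd.DataFrame
    flags: pd.DataFrame
    full_list: pd.DataFrame
    tool_list: pd.DataFrame
    marginals: pd.DataFrame
    dashboard: dict
    filter_report: dict
    merge_report: dict = field(default_factory=dict)
    probe_report: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kw):
            try:
                return fn(*args, **kw)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc

        return wrapper

    return deco


@_stage("ingest")
def ingest_sources(config: RunConfig):
    slc_table = ingest.SlcReference.from_tsv(config.slc_table)
    id_map = ingest.IdentifierMap.from_tsvs(
        config.substance_to_cid, config.cid_to_chembl, config.child_to_parent
    )
    frames, report = [], {}
    loaders = [
        ("chembl", ingest.load_chembl_activities, config.chembl),
        ("gtopdb", ingest.load_gtopdb_interactions, config.gtopdb),
        ("pubchem", ingest.load_pubchem_bioactivities, config.pubchem),
    ]
    for name, loader, path in loaders:
        df, counts = loader(path, slc_table, id_map)
        frames.append(df)
        report[name] = {"loaded": int(len(df)), "excluded": dict(counts)}
        log.info("ingest %s: %d records, %d excluded", name, len(df),
                 sum(counts.values()))
    return harmonize.concat_sources(frames), slc_table, report


@_stage("harmonize")
def harmonize_records(records: pd.DataFrame):
    report = {}
    n0 = len(records)
    records = harmonize.filter_activity_types(records)
    report["activity-type-filter"] = n0 - len(records)
    n0 = len(records)
    records = harmonize.filter_mutant(records)
    report["mutant-filter"] = n0 - len(records)
    n0 = len(records)
    records = harmonize.deduplicate(records)
    report["duplicate-filter"] = n0 - len(records)
    summaries = harmonize.aggregate_median(records)
    n_compounds = summaries["compound_id"].nunique() if len(summaries) else 0
    summaries = harmonize.restrict_to_slc_testers(summaries)
    kept = summaries["compound_id"].nunique() if len(summaries) else 0
    report["non-slc-tester-compounds"] = int(n_compounds - kept)
    for k, v in report.items():
        log.info("harmonize %s: %d removed", k, v)
    return records, summaries, report


def compound_smiles_map(records: pd.DataFrame) -> dict:
    """First non-empty structure string per compound, in record order."""
    out: dict = {}
    for cid, smi in zip(records["compound_id"], records["smiles"]):
        if cid not in out and isinstance(smi, str) and smi.strip():
            out[cid] = smi
    return out


def build_full_list(summaries, scores, flags) -> pd.DataFrame:
    """One row per (compound, SLC target) with scores and flags joined."""
    slc_rows = summaries.loc[summaries["is_slc"]].copy()
    merged = slc_rows.merge(scores, on="compound_id", how="left").merge(
        flags.drop(columns=["primary_is_slc"]), on="compound_id", how="left"
    )
    return merged.sort_values(["compound_id", "gene_name"]).reset_index(drop=True)


def write_marginal_counts(full_list: pd.DataFrame) -> pd.DataFrame:
    """Tabulate unique compounds (and shortlisted compounds) by the number
    of SLCs they were tested on.

    Column sums equal the distinct-compound counts of the full list.
    """
    if not len(full_list):
        return pd.DataFrame(
            columns=["n_slcs_tested", "unique_molecules", "unique_tool_compounds"]
        )
    per_comp = full_list.drop_duplicates("compound_id")
    grouped = per_comp.groupby("n_slcs_tested", sort=True)
    rows = [
        {
            "n_slcs_tested": int(n),
            "unique_molecules": int(len(grp)),
            "unique_tool_compounds": int(grp["shortlisted"].eq(True).sum()),
        }
        for n, grp in grouped
    ]
    return pd.DataFrame(rows)


def build_dashboard_payload(full_list: pd.DataFrame) -> dict:
    """Dashboard JSON: ranked activities plus per-compound and per-target
    panels.

    Every activity row appears in exactly one compound panel and one target
    panel; within a target, compounds are ordered by descending median
    pActivity.
    """
    act = full_list.dropna(subset=["median_p_activity"]).copy()
    act["rank_in_target"] = (
        act.groupby("gene_name")["median_p_activity"]
        .rank(ascending=False, method="first")
        .astype(int)
    )
    act["rank_in_compound"] = (
        act.groupby("compound_id")["median_p_activity"]
        .rank(ascending=False, method="first")
        .astype(int)
    )
    activities = []
    for r in act.sort_values(["gene_name", "rank_in_target"]).itertuples(index=False):
        activities.append(
            {
                "compound_id": r.compound_id,
                "slc": r.gene_name,
                "median_p_activity": float(r.median_p_activity),
                "rank_in_target": int(r.rank_in_target),
                "rank_in_compound": int(r.rank_in_compound),
                "pareto_rank": None if pd.isna(r.pareto_rank) else int(r.pareto_rank),
                "shortlisted": bool(r.shortlisted),
            }
        )
    compound_panel = {
        cid: [
            {"slc": r.gene_name, "median_p_activity": float(r.median_p_activity)}
            for r in grp.sort_values(
                "median_p_activity", ascending=False
            ).itertuples(index=False)
        ]
        for cid, grp in act.groupby("compound_id", sort=True)
    }
    target_panel = {
        gene: [
            {"compound_id": r.compound_id,
             "median_p_activity": float(r.median_p_activity)}
            for r in grp.sort_values(
                "median_p_activity", ascending=False
            ).itertuples(index=False)
        ]
        for gene, grp in act.groupby("gene_name", sort=True)
    }
    return {
        "activities": activities,
        "compound_panel": compound_panel,
        "target_panel": target_panel,
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow and write all outputs under
    ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records, slc_table, ingest_report = ingest_sources(config)
    records, summaries, harmonize_report = harmonize_records(records)

    try:
        scores = selectivity.score_compounds(summaries)
        scores = selectivity.pareto_rank(scores)
    except Exception as exc:
        raise StageError("score", str(exc)) from exc

    try:
        patterns = criteria.parse_smarts_patterns(config.pains)
        flags = criteria.compute_flags(
            scores, compound_smiles_map(records), patterns,
            config.criteria_config(),
        )
    except Exception as exc:
        raise StageError("flag", str(exc)) from exc

    full_list = build_full_list(summaries, scores, flags)
    merge_report, probe_report = {}, {}
    if config.curated is not None:
        try:
            curated_df = curated.read_curated(config.curated)
            merge_lists = curated_df.loc[
                curated_df["list_name"] != "chemicalprobes"
            ]
            full_list, merge_report = curated.merge_curated(
                full_list, merge_lists, slc_genes=slc_table.genes()
            )
            probes = curated_df.loc[curated_df["list_name"] == "chemicalprobes"]
            if len(probes):
                probe_report = curated.crosscheck_probes(full_list, probes)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("merge", str(exc)) from exc

    tool_list = criteria.shortlist(full_list, flags)
    marginals = write_marginal_counts(full_list)
    dashboard = build_dashboard_payload(full_list)
    filter_report = {"ingest": ingest_report, "harmonize": harmonize_report}

    outputs = {
        "full_list": outdir / "full_inhibitor_list.csv",
        "tool_list": outdir / "tool_compounds.csv",
        "scores": outdir / "scores.csv",
        "flags": outdir / "flags.csv",
        "marginals": outdir / "marginal_counts.csv",
        "dashboard": outdir / "dashboard.json",
        "filter_report": outdir / "filter_report.json",
    }
    full_list.to_csv(outputs["full_list"], index=False)
    tool_list.to_csv(outputs["tool_list"], index=False)
    scores.to_csv(outputs["scores"], index=False)
    flags.to_csv(outputs["flags"], index=False)
    marginals.to_csv(outputs["marginals"], index=False)
    outputs["dashboard"].write_text(json.dumps(dashboard, indent=2, sort_keys=True))
    report_doc = {
        "filters": filter_report,
        "curated_merge": merge_report,
        "probe_crosscheck": probe_report,
    }
    outputs["filter_report"].write_text(
        json.dumps(report_doc, indent=2, sort_keys=True)
    )
    return PipelineResult(
        records=records,
        summaries=summaries,
        scores=scores,
        flags=flags,
        full_list=full_list,
        tool_list=tool_list,
        marginals=marginals,
        dashboard=dashboard,
        filter_report=filter_report,
        merge_report=merge_report,
        probe_report=probe_report,
        outputs=outputs,
    )
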