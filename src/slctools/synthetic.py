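"""Synthetic source bundles with planted ground truth.

Generates the complete set of input files the pipeline consumes — the three
source-dialect tables, the SLC reference table, the identifier-mapping
TSVs, a PAINS pattern file, and curated/probe lists — together with a
ground-truth sidecar computed *by construction* at generation time (inline
arithmetic, never by running the pipeline).  Running the pipeline on a
bundle and comparing against the sidecar is the package's end-to-end test.

The generator emulates the logical structure of real exports (schemas,
exclusion reasons, identifier chains, duplicate and mutant rows, boundary
potencies) but not the statistical texture of real databases.  Boundary
cases — a compound at exactly 200 nM, a pair at exactly 30-fold — are
always planted, since inclusive-threshold semantics are the likeliest bug
site.  Potencies are otherwise drawn log-uniformly over 1 nM to 100 uM.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .criteria import default_pains_path
from .ingest import CHEMBL_COLUMNS, GTOPDB_COLUMNS, PUBCHEM_COLUMNS

__all__ = ["GeneratorConfig", "SourceBundle", "generate_source_bundle"]


# Structure library: (smiles, PAINS-positive under the shipped test set).
CLEAN_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",          # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",     # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",     # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",             # paracetamol
    "CC(C)NCC(O)COc1ccccc1",          # propranolol-like aryloxypropanolamine
    "c1ccncc1",                       # pyridine
    "CCO",                            # ethanol
    "c1ccccc1",                       # benzene
]
PAINS_SMILES = [
    "O=C1CSC(=S)N1",                  # rhodanine core
    "Oc1ccccc1O",                     # catechol
    "O=C1C=CC(=O)C=C1",               # p-benzoquinone
    "c1ccc(cc1)N=Nc1ccccc1",          # azobenzene
]
INVALID_SMILES = "not_a_structure"


@dataclass
class GeneratorConfig:
    """Settings for one synthetic bundle.

    Defaults give a bundle of ~50 compounds over 18 SLC and 6 non-SLC
    targets with all boundary cases planted; it generates in well under a
    second and exercises every pipeline stage.
    """

    n_filler_compounds: int = 32
    n_slc_targets: int = 18
    n_other_targets: int = 6
    max_slcs_per_compound: int = 5
    n_duplicates: int = 6
    n_mutant_rows: int = 5
    pains_fraction: float = 0.15
    salt_fraction: float = 0.25
    kinase_fraction: float = 0.2
    n_curated_resolute: int = 10
    curated_overlap_resolute: int = 4
    n_curated_eubopen: int = 5
    curated_overlap_eubopen: int = 2
    log10_nM_range: tuple = (0.0, 5.0)


@dataclass
class SourceBundle:
    """File paths of one generated bundle."""

    root: Path
    chembl: Path
    gtopdb: Path
    pubchem: Path
    slc_table: Path
    substance_to_cid: Path
    cid_to_chembl: Path
    child_to_parent: Path
    pains: Path
    curated: Path
    ground_truth: Path


def _p(value_nM: float) -> float:
    return 9.0 - math.log10(value_nM)


def _entropy(p_values) -> float:
    # Inline ground-truth entropy: K_i = 10^p_i, phi = K/sum, S = -sum phi ln phi.
    ks = [10.0 ** p for p in p_values]
    tot = sum(ks)
    return -sum((k / tot) * math.log(k / tot) for k in ks if k > 0)


@dataclass
class _Target:
    gene: str
    accession: str
    entrez: str
    family: str
    is_slc: bool


@dataclass
class _Compound:
    compound_id: str
    sid: str
    cid: str
    child_id: str | None   # salt form accession, mapped to parent
    smiles: str            # "" = no structure in any source
    pains: bool
    cid_only: bool = False


@dataclass
class _Record:
    compound: _Compound
    target: _Target
    value_nM: float
    act_type: str          # raw source type: IC50/Ki/EC50/Kd
    source: str            # chembl | gtopdb | pubchem
    counts_for_truth: bool = True
    mutant: bool = False
    empty_smiles: bool = False    # chembl row without a structure string
    as_uM: bool = False           # emit value in uM (exactly representable)
    as_range: tuple | None = None  # gtopdb (lo, hi) averaging to value_nM


def _make_targets(config) -> tuple:
    families = ["SLC91", "SLC92", "SLC93", "SLC94", "SLC95", "SLC96"]
    slcs = []
    for i in range(config.n_slc_targets):
        fam = families[i % len(families)]
        member = i // len(families) + 1
        slcs.append(
            _Target(
                gene=f"{fam}A{member}",
                accession=f"Q9{1001 + i}",
                entrez=str(990001 + i),
                family=fam,
                is_slc=True,
            )
        )
    others = [
        _Target(
            gene=f"P8{1001 + i}",
            accession=f"P8{1001 + i}",
            entrez=str(880001 + i),
            family="kinase",
            is_slc=False,
        )
        for i in range(config.n_other_targets)
    ]
    return slcs, others


class _Plan:
    """Accumulates compounds, records and the by-construction truth."""

    def __init__(self):
        self.compounds: list[_Compound] = []
        self.records: list[_Record] = []
        self._n = 0

    def add_compound(self, smiles, pains, salt=False, cid_only=False, label=None):
        self._n += 1
        n = self._n
        if cid_only:
            compound_id = f"CID9{n:04d}"
            child = None
        else:
            compound_id = label or f"CHEMBL9{n:05d}"
            child = f"{compound_id}_SALT" if salt else None
        comp = _Compound(
            compound_id=compound_id,
            sid=f"SID9{n:04d}",
            cid=f"CID9{n:04d}",
            child_id=child,
            smiles=smiles,
            pains=pains,
            cid_only=cid_only,
        )
        self.compounds.append(comp)
        return comp

    def add(self, comp, target, value_nM, act_type="IC50", source="chembl", **kw):
        rec = _Record(comp, target, float(value_nM), act_type, source, **kw)
        self.records.append(rec)
        return rec


def _plant_designed(plan: _Plan, slcs, others):
    """Plant the deterministic boundary/criterion compounds.

    Returns per-compound intent notes used for probe selection.
    """
    a, b, c, d, e, f, g, m1, m2, m3, h = (
        slcs[0], slcs[1], slcs[2], slcs[3], slcs[4], slcs[5], slcs[6],
        slcs[7], slcs[8], slcs[9], slcs[10],
    )
    kin0, kin1 = others[0], others[1]
    planted = {}

    # Exactly at the 200 nM potency boundary, single SLC, clean: shortlisted.
    cp = plan.add_compound(CLEAN_SMILES[0], False, label="CHEMBL800001")
    plan.add(cp, a, 200.0)
    planted[cp.compound_id] = "pass"

    # Just above the potency boundary: fails.
    cp = plan.add_compound(CLEAN_SMILES[1], False, label="CHEMBL800002")
    plan.add(cp, b, 250.0)
    planted[cp.compound_id] = "fail"

    # Exactly 30-fold between two SLCs: passes selectivity.
    cp = plan.add_compound(CLEAN_SMILES[2], False, label="CHEMBL800003")
    plan.add(cp, a, 10.0)
    plan.add(cp, b, 300.0)
    planted[cp.compound_id] = "pass"

    # Only 10-fold: fails selectivity.
    cp = plan.add_compound(CLEAN_SMILES[3], False, label="CHEMBL800004")
    plan.add(cp, c, 10.0)
    plan.add(cp, d, 100.0)
    planted[cp.compound_id] = "fail"

    # Potent but PAINS-positive: fails the substructure criterion.
    cp = plan.add_compound(PAINS_SMILES[0], True, label="CHEMBL800005")
    plan.add(cp, e, 50.0)
    planted[cp.compound_id] = "fail"

    # Potent but unparseable structure: PAINS status unknown, blocked.
    cp = plan.add_compound(INVALID_SMILES, False, label="CHEMBL800006")
    plan.add(cp, f, 50.0)
    planted[cp.compound_id] = "fail"

    # Primary target is a kinase, not the SLC: not shortlisted.
    cp = plan.add_compound(CLEAN_SMILES[4], False, label="CHEMBL800007")
    plan.add(cp, g, 100.0)
    plan.add(cp, kin0, 1.0)
    planted[cp.compound_id] = "fail"

    # Tested on a kinase only: dropped entirely (not an SLC tester).
    cp = plan.add_compound(CLEAN_SMILES[5], False, label="CHEMBL800008")
    plan.add(cp, kin1, 10.0)
    planted[cp.compound_id] = "dropped"

    # Multi-source, multi-target compound exercising uM conversion, range
    # averaging, cross-source deduplication and median pooling.
    cp = plan.add_compound(CLEAN_SMILES[1], False, salt=True, label="CHEMBL800009")
    plan.add(cp, m1, 4.0)
    plan.add(cp, m1, 5.0, act_type="Ki")
    plan.add(cp, m1, 6.0)
    plan.add(cp, m2, 250.0, as_uM=True)              # emitted as 0.25 uM
    plan.add(cp, m2, 200.0, source="gtopdb", as_range=(100.0, 300.0))
    plan.add(cp, m2, 150.0, empty_smiles=True)        # chembl copy ...
    plan.add(cp, m2, 150.0, source="gtopdb", counts_for_truth=False)  # ... dup
    plan.add(cp, m3, 1000.0, source="pubchem")
    plan.add(cp, kin0, 500.0)
    planted[cp.compound_id] = "pass"   # best SLC 5 nM, 40-fold, clean

    # Identifier-only compound (CID fallback, no structure): blocked.
    cp = plan.add_compound("", False, cid_only=True)
    plan.add(cp, h, 20.0, source="gtopdb")
    planted[cp.compound_id] = "fail"

    return planted


def _plant_filler(plan: _Plan, rng, config, slcs, others):
    n_pains = round(config.pains_fraction * config.n_filler_compounds)
    lo, hi = config.log10_nM_range
    weights = np.array([0.55, 0.2, 0.15, 0.06, 0.04])
    weights = weights[: config.max_slcs_per_compound]
    weights = weights / weights.sum()
    for i in range(config.n_filler_compounds):
        pains = i < n_pains
        smiles = (
            PAINS_SMILES[i % len(PAINS_SMILES)]
            if pains
            else CLEAN_SMILES[i % len(CLEAN_SMILES)]
        )
        comp = plan.add_compound(
            smiles, pains, salt=rng.random() < config.salt_fraction
        )
        n_slc = int(rng.choice(np.arange(1, len(weights) + 1), p=weights))
        targets = list(rng.choice(len(slcs), size=n_slc, replace=False))
        pair_targets = [slcs[t] for t in targets]
        if rng.random() < config.kinase_fraction:
            pair_targets.append(others[int(rng.integers(len(others)))])
        for tgt in pair_targets:
            for _ in range(int(rng.integers(1, 4))):
                value = float(10.0 ** rng.uniform(lo, hi))
                act_type = str(rng.choice(["IC50", "Ki", "EC50", "Kd"]))
                if tgt.is_slc:
                    source = str(
                        rng.choice(["chembl", "gtopdb", "pubchem"], p=[0.6, 0.2, 0.2])
                    )
                else:
                    source = "chembl"
                plan.add(comp, tgt, value, act_type=act_type, source=source)


def _plant_noise(plan: _Plan, rng, config):
    """Duplicate and mutant rows on top of the valid records."""
    eligible = [
        r
        for r in plan.records
        if r.source == "chembl"
        and r.counts_for_truth
        and not r.as_uM
        and not r.empty_smiles
        and not r.mutant
    ]
    if config.n_duplicates > len(eligible):
        raise ValueError("config plants more duplicates than eligible rows")
    idx = sorted(rng.choice(len(eligible), size=config.n_duplicates, replace=False))
    for i in idx:
        src = eligible[i]
        plan.add(
            src.compound,
            src.target,
            src.value_nM,
            act_type=src.act_type,
            source="chembl",
            counts_for_truth=False,
        )
    # Mutant rows: valid by every loader rule, flagged only by description.
    slc_recs = [r for r in eligible if r.target.is_slc]
    midx = rng.choice(len(slc_recs), size=config.n_mutant_rows, replace=True)
    for i in midx:
        src = slc_recs[int(i)]
        plan.add(
            src.compound,
            src.target,
            0.001,  # p = 12: would distort medians if wrongly retained
            source="chembl",
            counts_for_truth=False,
            mutant=True,
        )


# --- emission ---------------------------------------------------------------


def _chembl_row(rec: _Record, description=None):
    comp = rec.compound
    molecule = comp.child_id or comp.compound_id
    if rec.as_uM:
        value, units = rec.value_nM / 1000.0, "uM"
    else:
        value, units = rec.value_nM, "nM"
    if description is None:
        description = (
            f"Inhibition of {rec.target.gene} T199A mutant transporter"
            if rec.mutant
            else f"Inhibition assay on {rec.target.gene}"
        )
    return {
        "molecule_chembl_id": molecule,
        "parent_chembl_id": "" if comp.child_id else comp.compound_id,
        "canonical_smiles": "" if rec.empty_smiles else comp.smiles,
        "uniprot_accession": rec.target.accession,
        "organism": "Homo sapiens",
        "confidence_score": "9",
        "data_validity_comment": "",
        "potential_duplicate": "0",
        "src_id": "1",
        "standard_type": rec.act_type,
        "standard_value": value,
        "standard_units": units,
        "assay_description": description,
    }


def _gtopdb_row(rec: _Record):
    if rec.as_range:
        lo, hi = rec.as_range
    else:
        lo, hi = rec.value_nM, ""
    return {
        "ligand_id": f"L{rec.compound.sid[4:]}",
        "ligand_pubchem_sid": rec.compound.sid,
        "target_gene_symbol": rec.target.gene,
        "target_species": "Human",
        "type": rec.act_type,
        "affinity_low": lo,
        "affinity_high": hi,
        "affinity_units": "nM",
    }


def _pubchem_row(rec: _Record, aid):
    return {
        "aid": aid,
        "source_name": "Screening Center",
        "target_entrez": rec.target.entrez,
        "cid": rec.compound.cid,
        "activity_type": rec.act_type,
        "activity_value": rec.value_nM,
        "activity_units": "nM",
    }


def _decoy_rows(slcs, others):
    """One excluded input row per loader exclusion reason."""
    base = dict(_chembl_row(_Record(
        _Compound("CHEMBLDECOY", "SIDX", "CIDX", None, "CCO", False),
        slcs[0], 100.0, "IC50", "chembl",
    ), description="decoy assay"))
    chembl, reasons_c = [], []

    def c(reason, **overrides):
        row = dict(base)
        row.update(overrides)
        chembl.append(row)
        reasons_c.append(reason)

    c("not-human", organism="Rattus norvegicus")
    c("confidence<7", confidence_score="6")
    c("data-validity-comment", data_validity_comment="Outside typical range")
    c("potential-duplicate", potential_duplicate="1")
    c("source-excluded", src_id="7")
    c("source-excluded", src_id="58")
    c("activity-type", standard_type="Inhibition")
    c("units", standard_units="ug.mL-1")
    c("missing-value", standard_value="")
    c("nonpositive-value", standard_value="-5")

    gtopdb = [
        {**_gtopdb_row(_Record(_Compound("X", "SIDX", "CIDX", None, "", False),
                               slcs[0], 100.0, "IC50", "gtopdb")),
         "target_species": "Rat"},
        {**_gtopdb_row(_Record(_Compound("X", "SIDX", "CIDX", None, "", False),
                               others[0], 100.0, "IC50", "gtopdb"))},
        {**_gtopdb_row(_Record(_Compound("X", "SIDX", "CIDX", None, "", False),
                               slcs[0], 100.0, "IC50", "gtopdb")),
         "affinity_low": ""},
        {**_gtopdb_row(_Record(_Compound("X", "SIDX", "CIDX", None, "", False),
                               slcs[0], 100.0, "IC50", "gtopdb")),
         "affinity_units": "%"},
        {**_gtopdb_row(_Record(_Compound("X", "SID_UNKNOWN", "CIDX", None, "", False),
                               slcs[0], 100.0, "IC50", "gtopdb"))},
    ]
    reasons_g = ["not-human", "not-slc", "missing-value", "units",
                 "unresolved-compound"]

    pub_base = _pubchem_row(_Record(
        _Compound("X", "SIDX", "CID_UNKNOWN", None, "", False),
        slcs[0], 100.0, "IC50", "pubchem"), aid=1)
    pubchem = [
        {**pub_base, "source_name": "ChEMBL"},
        {**pub_base, "source_name": "IUPHAR-DB"},
        {**pub_base, "target_entrez": "123"},
        {**pub_base, "activity_value": ""},
        dict(pub_base),  # unknown CID
    ]
    reasons_p = ["source-excluded", "source-excluded", "not-slc",
                 "missing-value", "unresolved-compound"]
    from collections import Counter

    return (
        chembl, gtopdb, pubchem,
        {"chembl": dict(Counter(reasons_c)),
         "gtopdb": dict(Counter(reasons_g)),
         "pubchem": dict(Counter(reasons_p))},
    )


def _compound_truth(plan: _Plan, config):
    """Per-compound expectations from the planted records, by construction."""
    pair_values: dict = {}
    comp_targets: dict = {}
    has_structure: set = set()
    for rec in plan.records:
        # A structure is only visible downstream when some retained source
        # row carries it (the interactions/bioassay dialects do not).
        if (
            rec.source == "chembl"
            and not rec.mutant
            and not rec.empty_smiles
            and rec.compound.smiles
        ):
            has_structure.add(rec.compound.compound_id)
        if not rec.counts_for_truth:
            continue
        key = (rec.compound.compound_id, rec.target.accession)
        pair_values.setdefault(key, []).append(_p(rec.value_nM))
        comp_targets.setdefault(rec.compound.compound_id, {})[
            rec.target.accession
        ] = rec.target
    comp_lookup = {c.compound_id: c for c in plan.compounds}
    per_compound = {}
    n_dropped = 0
    for compound_id in sorted(comp_targets):
        targets = comp_targets[compound_id]
        medians = {
            acc: float(np.median(pair_values[(compound_id, acc)]))
            for acc in sorted(targets)
        }
        slc_accs = [a for a in medians if targets[a].is_slc]
        if not slc_accs:
            n_dropped += 1
            continue
        slc_p = [medians[a] for a in slc_accs]
        all_p = list(medians.values())
        best_slc_acc = max(slc_accs, key=lambda a: (medians[a], a))
        best_slc_p = medians[best_slc_acc]
        primary_acc = max(medians, key=lambda a: (medians[a], a))
        primary_is_slc = targets[primary_acc].is_slc
        if len(slc_accs) > 1:
            second = max(medians[a] for a in slc_accs if a != best_slc_acc)
            fold = 10.0 ** (best_slc_p - second)
        else:
            fold = math.inf
        comp = comp_lookup[compound_id]
        if compound_id not in has_structure or comp.smiles == INVALID_SMILES:
            pains_status = "unknown"
        else:
            pains_status = "fail" if comp.pains else "pass"
        potency_pass = best_slc_p >= _p(200.0) - 1e-9
        selectivity_pass = math.isinf(fold) or fold >= 30.0 * (1 - 1e-9)
        shortlisted = (
            primary_is_slc
            and potency_pass
            and selectivity_pass
            and pains_status == "pass"
        )
        per_compound[compound_id] = {
            "medians": medians,
            "s_slcs": _entropy(slc_p),
            "s_other": _entropy(all_p),
            "n_slcs_tested": len(slc_accs),
            "n_targets_tested": len(medians),
            "best_slc_p_activity": best_slc_p,
            "best_slc_gene": targets[best_slc_acc].gene,
            "primary_is_slc": primary_is_slc,
            "fold_selectivity_other_slcs": fold if math.isfinite(fold) else None,
            "pains_status": pains_status,
            "potency_pass": potency_pass,
            "selectivity_pass": selectivity_pass,
            "shortlisted": shortlisted,
        }
    return per_compound, n_dropped


def _curated_lists(plan, per_compound, config, rng):
    """Curated and probe tables plus their expected merge/crosscheck counts."""
    comp_lookup = {c.compound_id: c for c in plan.compounds}
    db_pairs = []  # (compound_id, gene) present in the database rows
    seen = set()
    for rec in plan.records:
        if not rec.counts_for_truth or not rec.target.is_slc:
            continue
        key = (rec.compound.compound_id, rec.target.gene)
        if key not in seen and rec.compound.compound_id in per_compound:
            seen.add(key)
            db_pairs.append(key)
    db_pairs.sort()
    all_genes = sorted({r.target.gene for r in plan.records if r.target.is_slc})

    rows = []
    truth = {}
    used_new_pairs: set = set()  # curated-only pairs must be globally unique

    def build(list_name, n_total, n_overlap, start):
        overlap = db_pairs[start : start + n_overlap]
        for cid, gene in overlap:
            rows.append(
                {"compound_id": cid, "slc_gene": gene, "list_name": list_name,
                 "reference": f"{list_name} curation"}
            )
        n_new = n_total - n_overlap
        made = 0
        for cid, gene in db_pairs[start + n_overlap :]:
            if made >= n_new:
                break
            tested = {
                r.target.gene for r in plan.records
                if r.compound.compound_id == cid and r.target.is_slc
            }
            untested = [
                g for g in all_genes
                if g not in tested and (cid, g) not in used_new_pairs
            ]
            if not untested:
                continue
            used_new_pairs.add((cid, untested[0]))
            rows.append(
                {"compound_id": cid, "slc_gene": untested[0],
                 "list_name": list_name, "reference": f"{list_name} curation"}
            )
            made += 1
        truth[list_name] = {"overlapping": n_overlap, "curated_only": made}
        return n_overlap + made

    build("resolute", config.n_curated_resolute,
          config.curated_overlap_resolute, start=0)
    build("eubopen", config.n_curated_eubopen - 1,
          config.curated_overlap_eubopen, start=config.curated_overlap_resolute)
    # One eubopen row with an unknown SLC symbol: kept, flagged, curated-only.
    rows.append(
        {"compound_id": db_pairs[0][0], "slc_gene": "SLC999A9",
         "list_name": "eubopen", "reference": "eubopen curation"}
    )
    truth["eubopen"]["curated_only"] += 1

    # Probe list: the planted criterion compounds, all present in the
    # database; their pass count is known by construction.
    probe_ids = [f"CHEMBL8{i:05d}" for i in range(1, 8)] + ["CHEMBL800009"]
    probe_ids = [c for c in probe_ids if c in per_compound]
    n_pass = 0
    for cid in probe_ids:
        gene = per_compound[cid]["best_slc_gene"]
        rows.append(
            {"compound_id": cid, "slc_gene": gene, "list_name": "chemicalprobes",
             "reference": "probe portal"}
        )
        n_pass += bool(per_compound[cid]["shortlisted"])
    truth["chemicalprobes"] = {"overlapping": len(probe_ids), "curated_only": 0}
    probes_truth = {"n_probes": len(probe_ids), "n_found": len(probe_ids),
                    "n_pass": n_pass}
    return pd.DataFrame(rows), truth, probes_truth


def generate_source_bundle(outdir, config: GeneratorConfig | None = None,
                           seed: int = 0):
    """Write a synthetic source bundle under ``outdir``.

    Returns ``(bundle, truth)``; ``truth`` is also written as a JSON
    sidecar.  Deterministic: the same config and seed produce byte-identical
    files.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    slcs, others = _make_targets(config)
    plan = _Plan()
    _plant_designed(plan, slcs, others)
    _plant_filler(plan, rng, config, slcs, others)
    _plant_noise(plan, rng, config)

    chembl_rows = [_chembl_row(r) for r in plan.records if r.source == "chembl"]
    gtopdb_rows = [_gtopdb_row(r) for r in plan.records if r.source == "gtopdb"]
    pubchem_rows = [
        _pubchem_row(r, aid=7000 + i)
        for i, r in enumerate(r for r in plan.records if r.source == "pubchem")
    ]
    n_valid = {
        "chembl": len(chembl_rows),
        "gtopdb": len(gtopdb_rows),
        "pubchem": len(pubchem_rows),
    }
    dec_c, dec_g, dec_p, exclusions = _decoy_rows(slcs, others)
    chembl_rows += dec_c
    gtopdb_rows += dec_g
    pubchem_rows += dec_p

    per_compound, n_dropped = _compound_truth(plan, config)
    curated_df, curated_truth, probes_truth = _curated_lists(
        plan, per_compound, config, rng
    )

    marginals: dict = {}
    for info in per_compound.values():
        n = info["n_slcs_tested"]
        cell = marginals.setdefault(str(n), [0, 0])
        cell[0] += 1
        cell[1] += int(info["shortlisted"])

    n_cross_dups = sum(
        1 for r in plan.records
        if not r.counts_for_truth and not r.mutant and r.source != "chembl"
    )
    truth = {
        "seed": seed,
        "config": asdict(config),
        "expected_records_per_source": n_valid,
        "expected_exclusions_per_source": exclusions,
        "planted_duplicates": config.n_duplicates + n_cross_dups,
        "planted_mutant_rows": config.n_mutant_rows,
        "n_non_slc_tester_compounds": n_dropped,
        "per_compound_expected": per_compound,
        "curated_overlap": curated_truth,
        "probes": probes_truth,
        "marginal_counts": marginals,
    }

    def shuffled(rows, columns):
        df = pd.DataFrame(rows, columns=columns)
        return df.iloc[rng.permutation(len(df))].reset_index(drop=True)

    bundle = SourceBundle(
        root=outdir,
        chembl=outdir / "chembl_activities.csv",
        gtopdb=outdir / "gtopdb_interactions.csv",
        pubchem=outdir / "pubchem_bioactivities.csv",
        slc_table=outdir / "slc_table.tsv",
        substance_to_cid=outdir / "substance_to_cid.tsv",
        cid_to_chembl=outdir / "cid_to_chembl.tsv",
        child_to_parent=outdir / "child_to_parent.tsv",
        pains=outdir / "pains.smarts",
        curated=outdir / "curated.csv",
        ground_truth=outdir / "ground_truth.json",
    )
    shuffled(chembl_rows, CHEMBL_COLUMNS).to_csv(bundle.chembl, index=False)
    shuffled(gtopdb_rows, GTOPDB_COLUMNS).to_csv(bundle.gtopdb, index=False)
    shuffled(pubchem_rows, PUBCHEM_COLUMNS).to_csv(bundle.pubchem, index=False)

    pd.DataFrame(
        [
            {"gene_symbol": t.gene, "uniprot_accession": t.accession,
             "entrez_id": t.entrez, "family_name": t.family}
            for t in slcs
        ]
    ).to_csv(bundle.slc_table, sep="\t", index=False)

    s2c, c2k, k2p = [], [], []
    for comp in plan.compounds:
        s2c.append({"substance": comp.sid, "cid": comp.cid})
        if not comp.cid_only:
            canonical = comp.child_id or comp.compound_id
            c2k.append({"cid": comp.cid, "canonical": canonical})
            if comp.child_id:
                k2p.append({"child": comp.child_id, "parent": comp.compound_id})
    pd.DataFrame(s2c).to_csv(bundle.substance_to_cid, sep="\t", index=False)
    pd.DataFrame(c2k).to_csv(bundle.cid_to_chembl, sep="\t", index=False)
    pd.DataFrame(k2p, columns=["child", "parent"]).to_csv(
        bundle.child_to_parent, sep="\t", index=False
    )

    bundle.pains.write_text(default_pains_path().read_text())
    curated_df.to_csv(bundle.curated, index=False)
    bundle.ground_truth.write_text(json.dumps(truth, indent=2, sort_keys=True))
    return bundle, truth
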