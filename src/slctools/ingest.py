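"""Readers for the three bioactivity source dialects.

Each loader applies the source-specific inclusion rules (human targets only,
assay-quality filters, source exclusions, unit normalisation) and resolves
compound identifiers to a canonical parent accession, yielding a harmonised
activity-record table.  Live database access is replaced by file contracts:
exported CSV tables plus an offline identifier map.

Every loader returns ``(records, report)`` where ``report`` counts excluded
input rows by reason, so that ``len(records) + sum(report.values())`` equals
the number of input rows.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .harmonize import to_pactivity

__all__ = [
    "SlcReference",
    "IdentifierMap",
    "Resolution",
    "load_chembl_activities",
    "load_gtopdb_interactions",
    "load_pubchem_bioactivities",
    "resolve_parent_compound",
    "RECORD_COLUMNS",
]

#: Column schema of the harmonised activity-record table.
RECORD_COLUMNS = [
    "compound_id",
    "smiles",
    "target_accession",
    "gene_name",
    "is_slc",
    "source",
    "activity_type",
    "p_activity",
    "value_nM",
    "assay_description",
    "reference",
]

# Raw activity types accepted from the sources, mapped to the negative-log
# labels used downstream.
_TYPE_MAP = {"IC50": "pIC50", "KI": "pKi", "EC50": "pEC50", "KD": "pKd"}

_HUMAN = {"homo sapiens", "human"}


class FormatError(ValueError):
    """A source file does not parse as its declared dialect."""


def _read_csv(path, required, sep=","):
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


class SlcReference:
    """Reference table of solute-carrier genes.

    Wraps a table of (gene_symbol, uniprot_accession, entrez_id, family_name)
    rows and offers the lookups the loaders need.  Gene symbols and UniProt
    accessions must be unique.
    """

    REQUIRED = ["gene_symbol", "uniprot_accession", "entrez_id", "family_name"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise FormatError(f"SLC reference table missing columns {missing}")
        if table["gene_symbol"].duplicated().any():
            raise FormatError("SLC reference table: duplicate gene symbols")
        if table["uniprot_accession"].duplicated().any():
            raise FormatError("SLC reference table: duplicate UniProt accessions")
        self.table = table.reset_index(drop=True)
        self._by_uniprot = dict(zip(table["uniprot_accession"], table["gene_symbol"]))
        self._by_gene = {
            g.upper(): (g, u)
            for g, u in zip(table["gene_symbol"], table["uniprot_accession"])
        }
        self._by_entrez = {
            str(e): (g, u)
            for e, g, u in zip(
                table["entrez_id"], table["gene_symbol"], table["uniprot_accession"]
            )
        }

    @classmethod
    def from_tsv(cls, path) -> "SlcReference":
        return cls(_read_csv(path, cls.REQUIRED, sep="\t"))

    def __len__(self):
        return len(self.table)

    def gene_for_uniprot(self, accession: str):
        return self._by_uniprot.get(accession)

    def lookup_gene(self, symbol: str):
        """Return (gene_symbol, uniprot) for a symbol, case-insensitive."""
        return self._by_gene.get(str(symbol).upper())

    def lookup_entrez(self, entrez) -> tuple | None:
        return self._by_entrez.get(str(entrez))

    def genes(self) -> set:
        return set(self.table["gene_symbol"])


@dataclass(frozen=True)
class Resolution:
    """Outcome of resolving a raw compound accession."""

    compound_id: str
    tag: str  # "parent" | "cid-fallback" | "unresolved"


@dataclass
class IdentifierMap:
    """Offline substance -> compound -> canonical parent mapping chain.

    Mirrors the cross-reference chain used when integrating sources: a
    substance accession maps to a compound accession (CID), the CID maps to a
    canonical compound accession, and canonical accessions map to their parent
    (salt-stripped) form.  Parents are fixed points: the parent of a parent is
    itself.
    """

    substance_to_cid: dict = field(default_factory=dict)
    cid_to_canonical: dict = field(default_factory=dict)
    child_to_parent: dict = field(default_factory=dict)

    def __post_init__(self):
        self._known_cids = set(self.substance_to_cid.values()) | set(
            self.cid_to_canonical
        )
        self._known_canonical = (
            set(self.child_to_parent)
            | set(self.child_to_parent.values())
            | set(self.cid_to_canonical.values())
        )

    @classmethod
    def from_tsvs(cls, substance_to_cid, cid_to_canonical, child_to_parent):
        def read_map(path):
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
            if df.shape[1] != 2:
                raise FormatError(f"{path}: identifier maps are two-column TSVs")
            pairs = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
            if len(pairs) != len(df):
                raise FormatError(f"{path}: mapping is not functional")
            return pairs

        return cls(
            read_map(substance_to_cid),
            read_map(cid_to_canonical),
            read_map(child_to_parent),
        )

    def resolve(self, raw_id: str) -> Resolution:
        return resolve_parent_compound(raw_id, self)


def resolve_parent_compound(raw_id: str, id_map: IdentifierMap) -> Resolution:
    """Resolve a raw accession through the substance->CID->canonical->parent
    chain.

    Returns the parent canonical accession when the chain resolves; a CID with
    a ``cid-fallback`` tag when the CID is known but has no canonical mapping;
    and an ``unresolved`` result when the accession appears in no map.
    Idempotent: resolving a parent accession returns itself.
    """
    if not raw_id:
        raise ValueError("raw_id must be non-empty")
    cur = id_map.substance_to_cid.get(raw_id, raw_id)
    if cur in id_map.cid_to_canonical:
        canonical = id_map.cid_to_canonical[cur]
        return Resolution(id_map.child_to_parent.get(canonical, canonical), "parent")
    if cur in id_map._known_canonical:
        return Resolution(id_map.child_to_parent.get(cur, cur), "parent")
    if cur in id_map._known_cids:
        return Resolution(cur, "cid-fallback")
    return Resolution("", "unresolved")


def _parse_value_nM(value: str, units: str):
    """Parse a potency and normalise to nM. Returns (value_nM, reason)."""
    if value == "" or value is None:
        return None, "missing-value"
    try:
        v = float(value)
    except ValueError:
        return None, "missing-value"
    if not math.isfinite(v) or v <= 0:
        return None, "nonpositive-value"
    u = str(units).strip()
    if u == "nM":
        return v, None
    if u in ("uM", "µM", "um", "UM"):
        return v * 1000.0, None
    return None, "units"


def _empty_records():
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in RECORD_COLUMNS})
    df["is_slc"] = df["is_slc"].astype(bool)
    df["p_activity"] = df["p_activity"].astype(float)
    df["value_nM"] = df["value_nM"].astype(float)
    return df


def _finish(rows, report):
    if not rows:
        return _empty_records(), report
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df["is_slc"] = df["is_slc"].astype(bool)
    df["p_activity"] = df["p_activity"].astype(float)
    df["value_nM"] = df["value_nM"].astype(float)
    return df, report


CHEMBL_COLUMNS = [
    "molecule_chembl_id",
    "parent_chembl_id",
    "canonical_smiles",
    "uniprot_accession",
    "organism",
    "confidence_score",
    "data_validity_comment",
    "potential_duplicate",
    "src_id",
    "standard_type",
    "standard_value",
    "standard_units",
    "assay_description",
]

#: Deposition source codes excluded to avoid double counting: 7 mirrors
#: PubChem, 58 mirrors the consortium's own deposits.
EXCLUDED_SRC_IDS = {"7", "58"}


def load_chembl_activities(path, slc_table: SlcReference, id_map: IdentifierMap):
    """Load a ChEMBL-dialect activity export.

    Keeps human targets with assay confidence >= 7, no data-validity comment,
    not flagged as potential duplicates, not deposited from excluded sources,
    with activity type IC50/Ki/EC50/Kd and nM units (after exact uM -> nM
    conversion).  Compounds are keyed by their parent accession.
    """
    df = _read_csv(path, CHEMBL_COLUMNS)
    report: Counter = Counter()
    rows = []
    for r in df.itertuples(index=False):
        if str(r.organism).strip().lower() not in _HUMAN:
            report["not-human"] += 1
            continue
        try:
            conf = int(float(r.confidence_score))
        except ValueError:
            conf = -1
        if conf < 7:
            report["confidence<7"] += 1
            continue
        if str(r.data_validity_comment).strip():
            report["data-validity-comment"] += 1
            continue
        if str(r.potential_duplicate).strip().lower() in ("1", "true", "yes"):
            report["potential-duplicate"] += 1
            continue
        if str(r.src_id).strip() in EXCLUDED_SRC_IDS:
            report["source-excluded"] += 1
            continue
        act_type = str(r.standard_type).strip().upper()
        if act_type not in _TYPE_MAP:
            report["activity-type"] += 1
            continue
        value_nM, reason = _parse_value_nM(r.standard_value, r.standard_units)
        if reason:
            report[reason] += 1
            continue
        parent = str(r.parent_chembl_id).strip()
        if not parent:
            res = resolve_parent_compound(str(r.molecule_chembl_id), id_map)
            if res.tag == "unresolved":
                report["unresolved-compound"] += 1
                continue
            parent = res.compound_id
        gene = slc_table.gene_for_uniprot(str(r.uniprot_accession))
        rows.append(
            {
                "compound_id": parent,
                "smiles": str(r.canonical_smiles),
                "target_accession": str(r.uniprot_accession),
                "gene_name": gene if gene is not None else str(r.uniprot_accession),
                "is_slc": gene is not None,
                "source": "chembl",
                "activity_type": _TYPE_MAP[act_type],
                "p_activity": to_pactivity(value_nM),
                "value_nM": value_nM,
                "assay_description": str(r.assay_description),
                "reference": str(r.molecule_chembl_id),
            }
        )
    return _finish(rows, report)


GTOPDB_COLUMNS = [
    "ligand_id",
    "ligand_pubchem_sid",
    "target_gene_symbol",
    "target_species",
    "type",
    "affinity_low",
    "affinity_high",
    "affinity_units",
]


def load_gtopdb_interactions(path, slc_table: SlcReference, id_map: IdentifierMap):
    """Load a pharmacology-database interactions export.

    Keeps human SLC rows only.  Affinity ranges are replaced by the
    arithmetic mean of their endpoints.  Substance accessions are resolved
    substance -> CID -> canonical -> parent; when no canonical accession
    exists the CID itself keys the compound.  Rows with qualifier-style or
    missing units are excluded with a logged reason rather than guessed.
    """
    df = _read_csv(path, GTOPDB_COLUMNS)
    report: Counter = Counter()
    rows = []
    for r in df.itertuples(index=False):
        if str(r.target_species).strip().lower() not in _HUMAN:
            report["not-human"] += 1
            continue
        hit = slc_table.lookup_gene(r.target_gene_symbol)
        if hit is None:
            report["not-slc"] += 1
            continue
        gene, uniprot = hit
        lo, hi = str(r.affinity_low).strip(), str(r.affinity_high).strip()
        if lo == "":
            report["missing-value"] += 1
            continue
        raw = lo if hi == "" else None
        if raw is None:
            v_lo, reason_lo = _parse_value_nM(lo, r.affinity_units)
            v_hi, reason_hi = _parse_value_nM(hi, r.affinity_units)
            if reason_lo or reason_hi:
                report[reason_lo or reason_hi] += 1
                continue
            value_nM = (v_lo + v_hi) / 2.0
        else:
            value_nM, reason = _parse_value_nM(raw, r.affinity_units)
            if reason:
                report[reason] += 1
                continue
        res = resolve_parent_compound(str(r.ligand_pubchem_sid), id_map)
        if res.tag == "unresolved":
            report["unresolved-compound"] += 1
            continue
        act_type = str(r.type).strip().upper()
        rows.append(
            {
                "compound_id": res.compound_id,
                "smiles": "",
                "target_accession": uniprot,
                "gene_name": gene,
                "is_slc": True,
                "source": "gtopdb",
                "activity_type": _TYPE_MAP.get(act_type, f"p{r.type}"),
                "p_activity": to_pactivity(value_nM),
                "value_nM": value_nM,
                "assay_description": "",
                "reference": str(r.ligand_id),
            }
        )
    return _finish(rows, report)


PUBCHEM_COLUMNS = [
    "aid",
    "source_name",
    "target_entrez",
    "cid",
    "activity_type",
    "activity_value",
    "activity_units",
]

#: Assay depositors removed to avoid overlap with the other two sources.
EXCLUDED_PUBCHEM_SOURCES = {"chembl", "iuphar-db"}


def load_pubchem_bioactivities(path, slc_table: SlcReference, id_map: IdentifierMap):
    """Load a PubChem-dialect bioactivity export.

    Restricted to targets whose Entrez ID is in the SLC reference table;
    assays deposited by the other two integrated sources are dropped, as are
    rows with missing activity values.  Parent resolution as for the
    interactions loader.
    """
    df = _read_csv(path, PUBCHEM_COLUMNS)
    report: Counter = Counter()
    rows = []
    for r in df.itertuples(index=False):
        if str(r.source_name).strip().lower() in EXCLUDED_PUBCHEM_SOURCES:
            report["source-excluded"] += 1
            continue
        hit = slc_table.lookup_entrez(r.target_entrez)
        if hit is None:
            report["not-slc"] += 1
            continue
        gene, uniprot = hit
        value_nM, reason = _parse_value_nM(r.activity_value, r.activity_units)
        if reason:
            report[reason] += 1
            continue
        res = resolve_parent_compound(str(r.cid), id_map)
        if res.tag == "unresolved":
            report["unresolved-compound"] += 1
            continue
        act_type = str(r.activity_type).strip().upper()
        rows.append(
            {
                "compound_id": res.compound_id,
                "smiles": "",
                "target_accession": uniprot,
                "gene_name": gene,
                "is_slc": True,
                "source": "pubchem",
                "activity_type": _TYPE_MAP.get(act_type, f"p{r.activity_type}"),
                "p_activity": to_pactivity(value_nM),
                "value_nM": value_nM,
                "assay_description": "",
                "reference": f"AID{r.aid}",
            }
        )
    return _finish(rows, report)
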