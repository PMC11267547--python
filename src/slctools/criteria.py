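"""Tool-compound criteria: PAINS substructure filtering and shortlist flags.

A compound qualifies as a potential tool compound for an SLC when

* the SLC of interest is its primary (most potent) reported target,
* the median potency at that SLC is at most 200 nM,
* it is at least 30-fold selective against the best other tested SLC
  (vacuously selective when no other SLC was tested), and
* its structure matches no PAINS (pan-assay interference) substructure.

Compounds without a parseable structure cannot be certified PAINS-free; by
default their status is "unknown" and blocks shortlisting, which a config
switch can relax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "PainsPattern",
    "CriteriaConfig",
    "parse_smarts_patterns",
    "default_pains_path",
    "match_pains",
    "evaluate_criteria",
    "compute_flags",
    "shortlist",
    "FLAG_COLUMNS",
    "POTENCY_NM_DEFAULT",
    "FOLD_DEFAULT",
]

POTENCY_NM_DEFAULT = 200.0
FOLD_DEFAULT = 30.0

#: Relative slack absorbing float round-trip error at the inclusive
#: thresholds; far below any meaningful potency difference.
_REL_EPS = 1e-9

FLAG_COLUMNS = [
    "compound_id",
    "primary_is_slc",
    "primary_slc_gene",
    "potency_pass",
    "selectivity_pass",
    "pains_status",
    "matched_pains",
    "shortlisted",
]


@dataclass(frozen=True)
class PainsPattern:
    """One named SMARTS substructure filter."""

    pattern_id: str
    smarts: str
    mol: "Chem.Mol" = field(repr=False, compare=False, default=None)


@dataclass
class CriteriaConfig:
    """Thresholds and policies for the tool-compound flags.

    potency_nM: maximal median potency at the primary SLC (inclusive).
    fold: minimal fold selectivity against other tested SLCs (inclusive).
    pains_unknown_blocks: whether an unparseable/missing structure blocks
        shortlisting (default True: PAINS-freedom cannot be certified).
    """

    potency_nM: float = POTENCY_NM_DEFAULT
    fold: float = FOLD_DEFAULT
    pains_unknown_blocks: bool = True

    @property
    def potency_p_threshold(self) -> float:
        return 9.0 - float(np.log10(self.potency_nM))


def parse_smarts_patterns(path) -> list:
    """Parse a PAINS pattern file: ``pattern_id<TAB>SMARTS`` per line,
    ``#`` comments and blank lines ignored.

    Raises ``ValueError`` naming the offending line when a pattern does not
    parse as valid SMARTS.
    """
    patterns = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'pattern_id<TAB>SMARTS'")
        pattern_id, smarts = parts[0].strip(), parts[1].strip()
        mol = Chem.MolFromSmarts(smarts)
        if mol is None:
            raise ValueError(f"{path}:{lineno}: invalid SMARTS for {pattern_id!r}")
        patterns.append(PainsPattern(pattern_id, smarts, mol))
    return patterns


def default_pains_path() -> Path:
    """Path of the small PAINS pattern set shipped for testing.

    The full PAINS catalog is a versioned external artifact supplied by the
    user; this set covers the common alert classes needed by the fixtures.
    """
    return Path(resources.files("slctools").joinpath("data/pains_test.smarts"))


def match_pains(smiles, patterns) -> list | None:
    """Return the ids of every pattern with a substructure match in
    ``smiles``.

    An empty list means the structure is clean; ``None`` signals that the
    structure is missing or unparseable, which is distinct from clean.
    """
    if smiles is None or str(smiles).strip() == "":
        return None
    mol = Chem.MolFromSmiles(str(smiles))
    if mol is None:
        return None
    return [p.pattern_id for p in patterns if mol.HasSubstructMatch(p.mol)]


def evaluate_criteria(
    score_row,
    primary_slc_p_activity: float,
    pains_matches,
    config: CriteriaConfig | None = None,
) -> dict:
    """Evaluate the tool-compound flags for one compound.

    ``score_row`` is a row of the selectivity score table;
    ``primary_slc_p_activity`` the median pActivity at the compound's best
    SLC target; ``pains_matches`` the result of :func:`match_pains`.
    Both thresholds are inclusive: exactly 200 nM passes potency and
    exactly 30-fold passes selectivity.
    """
    config = config or CriteriaConfig()
    potency_pass = bool(
        primary_slc_p_activity >= config.potency_p_threshold - _REL_EPS
    )
    fold = float(score_row["fold_selectivity_other_slcs"])
    selectivity_pass = bool(
        np.isinf(fold) or fold >= config.fold * (1.0 - _REL_EPS)
    )
    if pains_matches is None:
        pains_status = "unknown"
    elif pains_matches:
        pains_status = "fail"
    else:
        pains_status = "pass"
    pains_ok = pains_status == "pass" or (
        pains_status == "unknown" and not config.pains_unknown_blocks
    )
    primary_is_slc = bool(score_row["primary_is_slc"])
    return {
        "compound_id": score_row["compound_id"],
        "primary_is_slc": primary_is_slc,
        "primary_slc_gene": score_row["best_slc_gene"],
        "potency_pass": potency_pass,
        "selectivity_pass": selectivity_pass,
        "pains_status": pains_status,
        "matched_pains": ";".join(pains_matches or []),
        "shortlisted": bool(
            primary_is_slc and potency_pass and selectivity_pass and pains_ok
        ),
    }


def compute_flags(
    scores: pd.DataFrame,
    compound_smiles: dict,
    patterns,
    config: CriteriaConfig | None = None,
) -> pd.DataFrame:
    """Evaluate the criteria for every scored compound.

    ``compound_smiles`` maps compound_id -> structure string (may be empty
    or missing for identifier-only compounds).
    """
    config = config or CriteriaConfig()
    rows = []
    for _, row in scores.iterrows():
        matches = match_pains(compound_smiles.get(row["compound_id"]), patterns)
        rows.append(
            evaluate_criteria(row, float(row["best_slc_p_activity"]), matches, config)
        )
    return pd.DataFrame(rows, columns=FLAG_COLUMNS)


def shortlist(full_list: pd.DataFrame, flags: pd.DataFrame) -> pd.DataFrame:
    """Restrict the full inhibitor table to shortlisted compounds.

    Always a subset of ``full_list``.
    """
    passing = set(flags.loc[flags["shortlisted"], "compound_id"])
    return full_list.loc[full_list["compound_id"].isin(passing)].reset_index(
        drop=True
    )
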