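"""Selectivity entropy scoring and Pareto ranking of compounds.

The selectivity entropy treats a compound's potencies as association
constants ``K_i = 10^{p_i}``, normalises them to fractions
``phi_i = K_i / sum_j K_j`` and reports the Shannon entropy
``S = -sum_i phi_i ln(phi_i)`` in nats.  S is 0 for a single-target compound
(or one overwhelmingly dominant target) and ln(n) for n equipotent targets,
and is invariant under adding a constant to all pActivities, so the choice
of potency unit cancels.

Each compound is scored twice: over its tested SLC targets only (``s_slcs``)
and over all tested targets (``s_other``).  Because most compounds were
tested on very few targets, a low entropy does not by itself establish
selectivity; the Pareto ranking therefore also rewards the breadth of SLC
testing and the best potency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "selectivity_entropy",
    "score_compounds",
    "pareto_rank",
    "SCORE_COLUMNS",
]

SCORE_COLUMNS = [
    "compound_id",
    "s_slcs",
    "s_other",
    "n_slcs_tested",
    "n_targets_tested",
    "best_slc_p_activity",
    "best_slc_gene",
    "primary_target",
    "primary_gene",
    "primary_is_slc",
    "primary_tie",
    "fold_selectivity_other_slcs",
]


def selectivity_entropy(p_activities) -> float:
    """Selectivity entropy (nats) of a vector of pActivities.

    Computed with the largest value shifted to zero before exponentiation,
    which makes the evaluation numerically stable and the shift invariance
    exact by construction.
    """
    p = np.asarray(p_activities, dtype=float)
    if p.size == 0:
        raise ValueError("selectivity entropy requires at least one pActivity")
    if np.any(~np.isfinite(p)):
        raise ValueError("pActivities must be finite")
    w = np.power(10.0, p - p.max())
    phi = w / w.sum()
    nz = phi[phi > 0]
    # entropy is mathematically >= 0; clamp away the -0.0 float artifact
    return max(0.0, float(-(nz * np.log(nz)).sum()))


def _score_one(grp: pd.DataFrame) -> dict:
    slc = grp.loc[grp["is_slc"]]
    p_all = grp["median_p_activity"].to_numpy(dtype=float)
    p_slc = slc["median_p_activity"].to_numpy(dtype=float)
    # Primary target: maximal median over all targets; ties are flagged and
    # broken deterministically (SLC targets first, then accession order).
    best = p_all.max()
    tied = grp.loc[grp["median_p_activity"] == best]
    primary = tied.sort_values(
        ["is_slc", "target_accession"], ascending=[False, True]
    ).iloc[0]
    best_slc_idx = slc["median_p_activity"].idxmax()
    best_slc_p = float(slc.loc[best_slc_idx, "median_p_activity"])
    if len(slc) > 1:
        others = slc.drop(index=best_slc_idx)["median_p_activity"].to_numpy()
        fold = float(np.power(10.0, best_slc_p - others.max()))
    else:
        fold = float("inf")
    return {
        "compound_id": grp["compound_id"].iloc[0],
        "s_slcs": selectivity_entropy(p_slc),
        "s_other": selectivity_entropy(p_all),
        "n_slcs_tested": int(len(slc)),
        "n_targets_tested": int(len(grp)),
        "best_slc_p_activity": best_slc_p,
        "best_slc_gene": slc.loc[best_slc_idx, "gene_name"],
        "primary_target": primary["target_accession"],
        "primary_gene": primary["gene_name"],
        "primary_is_slc": bool(primary["is_slc"]),
        "primary_tie": bool(len(tied) > 1),
        "fold_selectivity_other_slcs": fold,
    }


def score_compounds(summaries: pd.DataFrame) -> pd.DataFrame:
    """Compute per-compound selectivity scores from the summary table.

    Every compound must carry at least one SLC summary (guaranteed by
    :func:`slctools.harmonize.restrict_to_slc_testers` upstream).
    ``fold_selectivity_other_slcs`` is ``10**(best SLC pActivity - best
    other-SLC pActivity)``, infinite when only one SLC was tested.
    """
    if not len(summaries):
        return pd.DataFrame(columns=SCORE_COLUMNS)
    rows = [
        _score_one(grp)
        for _, grp in summaries.groupby("compound_id", sort=True)
    ]
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


# Objective directions for the Pareto ranking: the two entropies are
# minimised, the best SLC potency and the SLC test count are maximised.
_OBJECTIVES = [
    ("s_slcs", -1.0),
    ("s_other", -1.0),
    ("best_slc_p_activity", +1.0),
    ("n_slcs_tested", +1.0),
]


def pareto_rank(scores: pd.DataFrame) -> pd.DataFrame:
    """Assign Pareto front ranks (1 = non-dominated) to the scores table.

    A dominates B iff A is no worse on all four objectives and strictly
    better on at least one.  Fronts are peeled iteratively: rank k+1 is the
    non-dominated set after removing ranks <= k (non-dominated sorting with
    domination counts).  The result is independent of input order; the
    returned frame is sorted by (pareto_rank, compound_id).
    """
    out = scores.copy()
    n = len(out)
    if n == 0:
        out["pareto_rank"] = pd.Series(dtype=int)
        return out
    # Work on a sign-flipped matrix so that "better" is uniformly "greater".
    mat = np.column_stack(
        [sign * out[col].to_numpy(dtype=float) for col, sign in _OBJECTIVES]
    )
    ge = np.ones((n, n), dtype=bool)
    gt = np.zeros((n, n), dtype=bool)
    for k in range(mat.shape[1]):
        col = mat[:, k]
        ge &= col[:, None] >= col[None, :]
        gt |= col[:, None] > col[None, :]
    dominates = ge & gt  # dominates[i, j]: i dominates j
    dom_count = dominates.sum(axis=0)
    dominated_by = [np.flatnonzero(dominates[i]) for i in range(n)]
    ranks = np.zeros(n, dtype=int)
    front = np.flatnonzero(dom_count == 0)
    rank = 1
    remaining = dom_count.copy()
    while front.size:
        ranks[front] = rank
        nxt = []
        for i in front:
            for j in dominated_by[i]:
                remaining[j] -= 1
                if remaining[j] == 0:
                    nxt.append(j)
        front = np.array(sorted(set(nxt)), dtype=int)
        rank += 1
    out["pareto_rank"] = ranks
    return out.sort_values(["pareto_rank", "compound_id"]).reset_index(drop=True)
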