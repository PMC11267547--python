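import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from slctools.selectivity import pareto_rank, score_compounds, selectivity_entropy

from conftest import summaries_frame

p_vectors = st.lists(
    st.floats(min_value=0.0, max_value=12.0), min_size=1, max_size=12
)


@pytest.mark.parametrize(
    "p, expected",
    [
        ([7.2], 0.0),
        ([6.0, 6.0], math.log(2)),
        # phi = (1000/1001, 1/1001); frozen from direct -sum(phi ln phi)
        ([9.0, 6.0], 0.007900354757641078),
    ],
)
def test_entropy_of_known_profiles(p, expected):
    assert selectivity_entropy(p) == pytest.approx(expected, abs=1e-12)


def test_entropy_rejects_empty_input():
    with pytest.raises(ValueError):
        selectivity_entropy([])


@given(p_vectors)
@settings(deadline=None, derandomize=True)
def test_entropy_bounds(p):
    s = selectivity_entropy(p)
    assert -1e-12 <= s <= math.log(len(p)) + 1e-12
    if len(set(p)) == 1:
        assert s == pytest.approx(math.log(len(p)), abs=1e-9)


@given(p_vectors, st.floats(min_value=-5.0, max_value=5.0))
@settings(deadline=None, derandomize=True)
def test_entropy_shift_invariance(p, c):
    shifted = [x + c for x in p]
    assert selectivity_entropy(shifted) == pytest.approx(
        selectivity_entropy(p), abs=1e-9
    )


def test_single_target_compounds_score_zero_entropy():
    """A compound with one tested target is formally perfectly selective."""
    rng = np.random.default_rng(2)
    for p in rng.uniform(4, 9, size=20):
        frame = summaries_frame([("A", "Q1", "SLC91A1", True, float(p))])
        s = score_compounds(frame).iloc[0]
        assert s["s_slcs"] == 0.0 and s["s_other"] == 0.0
        assert math.isinf(s["fold_selectivity_other_slcs"])
        assert s["primary_is_slc"]


def test_score_compound_fold_selectivity_and_primary_target():
    frame = summaries_frame(
        [
            ("A", "Q1", "SLC91A1", True, 8.0),
            ("A", "Q2", "SLC91A2", True, 7.0),
            ("B", "Q1", "SLC91A1", True, 7.0),
            ("B", "QK", "KIN1", False, 9.0),
        ]
    )
    scores = score_compounds(frame).set_index("compound_id")
    a = scores.loc["A"]
    assert a["fold_selectivity_other_slcs"] == pytest.approx(10.0, rel=1e-12)
    assert a["n_slcs_tested"] == 2 and a["n_targets_tested"] == 2
    assert a["primary_target"] == "Q1" and a["primary_is_slc"]
    b = scores.loc["B"]
    assert not b["primary_is_slc"]
    assert b["best_slc_p_activity"] == 7.0
    assert b["s_slcs"] == 0.0 and b["s_other"] > 0.0


def test_primary_target_ties_are_flagged():
    frame = summaries_frame(
        [("A", "Q1", "SLC91A1", True, 7.0), ("A", "Q2", "SLC91A2", True, 7.0)]
    )
    s = score_compounds(frame).iloc[0]
    assert s["primary_tie"]


def _scores_table(mat):
    return pd.DataFrame(
        {
            "compound_id": [f"C{i:03d}" for i in range(len(mat))],
            "s_slcs": mat[:, 0],
            "s_other": mat[:, 1],
            "best_slc_p_activity": mat[:, 2],
            "n_slcs_tested": mat[:, 3].astype(int),
        }
    )


def _dominates(a, b):
    # independent oracle: minimise the entropies, maximise potency and count
    no_worse = (
        a[0] <= b[0] and a[1] <= b[1] and a[2] >= b[2] and a[3] >= b[3]
    )
    strictly = a[0] < b[0] or a[1] < b[1] or a[2] > b[2] or a[3] > b[3]
    return no_worse and strictly


def _oracle_ranks(mat):
    remaining = list(range(len(mat)))
    ranks = {}
    rank = 1
    while remaining:
        front = [
            i
            for i in remaining
            if not any(
                _dominates(tuple(mat[j]), tuple(mat[i]))
                for j in remaining
                if j != i
            )
        ]
        for i in front:
            ranks[i] = rank
        remaining = [i for i in remaining if i not in front]
        rank += 1
    return [ranks[i] for i in range(len(mat))]


def test_pareto_rank_known_example_and_edge_cases():
    # A dominates B on every objective
    mat = np.array([[0.0, 0.0, 9.0, 3], [0.5, 0.5, 8.0, 1]])
    ranked = pareto_rank(_scores_table(mat)).set_index("compound_id")
    assert ranked.loc["C000", "pareto_rank"] == 1
    assert ranked.loc["C001", "pareto_rank"] == 2
    single = pareto_rank(_scores_table(np.array([[0.1, 0.2, 7.0, 1]])))
    assert list(single["pareto_rank"]) == [1]
    twins = pareto_rank(
        _scores_table(np.array([[0.1, 0.2, 7.0, 2], [0.1, 0.2, 7.0, 2]]))
    )
    assert list(twins["pareto_rank"]) == [1, 1]


def test_pareto_ranks_match_brute_force_oracle_on_random_instances():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = int(rng.integers(1, 201))
        mat = np.column_stack(
            [
                rng.uniform(0, 2, n).round(2),
                rng.uniform(0, 3, n).round(2),
                rng.uniform(4, 9, n).round(1),
                rng.integers(1, 6, n),
            ]
        )
        ranked = pareto_rank(_scores_table(mat))
        got = (
            ranked.set_index("compound_id")["pareto_rank"]
            .loc[[f"C{i:03d}" for i in range(n)]]
            .to_list()
        )
        assert got == _oracle_ranks(mat)


def test_rank_one_compounds_are_never_dominated_and_order_invariant():
    rng = np.random.default_rng(13)
    mat = np.column_stack(
        [
            rng.uniform(0, 2, 80),
            rng.uniform(0, 3, 80),
            rng.uniform(4, 9, 80),
            rng.integers(1, 6, 80),
        ]
    )
    table = _scores_table(mat)
    ranked = pareto_rank(table).set_index("compound_id")
    front = ranked.index[ranked["pareto_rank"] == 1]
    for cid in front:
        i = int(cid[1:])
        assert not any(
            _dominates(tuple(mat[j]), tuple(mat[i]))
            for j in range(len(mat))
            if j != i
        )
    shuffled = table.sample(frac=1.0, random_state=7).reset_index(drop=True)
    pd.testing.assert_frame_equal(pareto_rank(shuffled), pareto_rank(table))
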