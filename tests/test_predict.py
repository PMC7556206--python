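"""Rank-zone prediction and the shuffled-label permutation machinery."""
import numpy as np
import pandas as pd
import pytest
from sympy.utilities.iterables import multiset_permutations

from hfoasym.predict import (count_matches, exact_match_distribution,
                             permutation_test, rank_and_predict, zone_pattern)


def test_reference_cohort_prediction(table2_cohort):
    res = rank_and_predict(table2_cohort)
    assert res.n_correct == 11
    assert res.accuracy == pytest.approx(11 / 16)
    assert not res.tie_warning
    # the patient with the highest ratio is predicted (and truly is) group 1
    assert res.ranking[0] == 2
    assert res.predicted_group[0] == 1 and res.true_group[0] == 1


def test_prediction_conserves_label_multiset(table2_cohort):
    res = rank_and_predict(table2_cohort)
    assert sorted(res.predicted_group) == sorted(res.true_group)


def test_perfect_biomarker_scores_everything():
    cohort = pd.DataFrame({
        "patient_id": list("abcdefg"),
        "true_group": [1, 1, 2, 2, 2, 3, 3],
        "r_fr": [0.9, 0.8, 0.5, 0.4, 0.3, -0.2, -0.5],
    })
    res = rank_and_predict(cohort)
    assert res.n_correct == 7


def test_tie_order_does_not_change_reference_result(table2_cohort):
    """Perturbing each tied pair's order (all 8 combinations) leaves the
    number of correct assignments unchanged: the ties at 0.02, 0.01 and
    -0.05 do not straddle zone boundaries."""
    tied_values = [0.02, 0.01, -0.05]
    for mask in range(8):
        cohort = table2_cohort.copy()
        for bit, v in enumerate(tied_values):
            idx = cohort.index[cohort["r_fr"] == v]
            assert len(idx) == 2
            eps = 1e-9 if (mask >> bit) & 1 else -1e-9
            cohort.loc[idx[0], "r_fr"] += eps
        assert rank_and_predict(cohort).n_correct == 11


def test_tie_straddling_boundary_raises_warning():
    cohort = pd.DataFrame({
        "patient_id": list("abcde"),
        "true_group": [1, 2, 2, 2, 3],
        "r_fr": [0.5, 0.5, 0.1, 0.0, -0.3],  # tie across the 1|2 boundary
    })
    assert rank_and_predict(cohort).tie_warning


def test_undefined_ratio_ranked_last_with_warning():
    cohort = pd.DataFrame({
        "patient_id": list("abcde"),
        "true_group": [1, 2, 2, 2, 3],
        "r_fr": [0.5, 0.3, 0.1, np.nan, -0.3],
    })
    res = rank_and_predict(cohort)
    assert res.ranking[-1] == "d"
    assert any("undefined" in w for w in res.warnings)


def test_missing_group_rejected():
    cohort = pd.DataFrame({
        "patient_id": list("abc"),
        "true_group": [1, 2, 2],
        "r_fr": [0.5, 0.3, 0.1],
    })
    with pytest.raises(ValueError, match="all three groups"):
        rank_and_predict(cohort)


def test_count_matches_reference_points():
    # positions 1, 3 and 5 agree
    assert count_matches([1, 1, 2, 2, 3], [1, 2, 2, 3, 3]) == 3
    assert count_matches([1, 2, 3], [1, 2, 3]) == 3
    assert count_matches([1, 1], [2, 2]) == 0


def test_exact_distribution_trivial_cases():
    pmf = exact_match_distribution((1, 0, 0), (1, 0, 0))
    assert pmf[1] == pytest.approx(1.0)
    pmf = exact_match_distribution((1, 1, 0), (1, 1, 0))
    assert pmf[2] == pytest.approx(0.5)
    assert pmf[0] == pytest.approx(0.5)
    assert pmf[1] == pytest.approx(0.0)


@pytest.mark.parametrize("counts", [(2, 2, 1), (2, 3, 2), (1, 4, 2)])
def test_exact_distribution_equals_multiset_enumeration(counts):
    """Contingency-table counting agrees with brute-force enumeration of
    every distinct permutation of the label multiset."""
    pattern = zone_pattern(counts)
    labels = list(pattern)
    n = len(labels)
    hist = np.zeros(n + 1)
    total = 0
    for perm in multiset_permutations(labels):
        hist[int((np.asarray(perm) == pattern).sum())] += 1
        total += 1
    assert np.allclose(exact_match_distribution(counts, counts),
                       hist / total, atol=1e-12)


def test_exact_distribution_mean_closed_form():
    """E[matches] = sum(n_i^2)/N when zone and label counts coincide."""
    for counts in ((5, 7, 4), (3, 3, 3), (1, 2, 7)):
        pmf = exact_match_distribution(counts, counts)
        n = sum(counts)
        expected = sum(c * c for c in counts) / n
        assert float(pmf @ np.arange(n + 1)) == pytest.approx(expected,
                                                              abs=1e-12)


def test_permutation_test_deterministic_and_consistent(table2_cohort):
    a = permutation_test(table2_cohort, n_shuffles=20_000, seed=123)
    b = permutation_test(table2_cohort, n_shuffles=20_000, seed=123)
    assert a.p_value == b.p_value
    assert a.null_counts.sum() == 20_000
    assert a.observed_matches == 11
    assert a.p_value_smoothed >= a.p_value


def test_monte_carlo_converges_to_exact_distribution(table2_cohort):
    """Total-variation distance between the 100k-shuffle histogram and the
    exact distribution stays below 0.01 for the (5,7,4) cohort."""
    res = permutation_test(table2_cohort, n_shuffles=100_000, seed=5)
    pmf = exact_match_distribution((5, 7, 4), (5, 7, 4))
    emp = res.null_counts / res.n_shuffles
    tv = 0.5 * np.abs(emp - pmf).sum()
    assert tv < 0.01


def test_zero_observed_matches_gives_p_one():
    cohort = pd.DataFrame({
        "patient_id": list("abc"),
        "true_group": [2, 3, 1],   # by rank: pattern (1,2,3) vs (2,3,1)
        "r_fr": [0.9, 0.5, 0.1],
    })
    res = permutation_test(cohort, n_shuffles=1000, seed=0)
    assert res.observed_matches == 0
    assert res.p_value == 1.0
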