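"""Rank-based prediction of the seizure-generating lesion and its null.

Patients are ranked by their fast-ripple asymmetry ratio R. With group
counts (n1, n2, n3) — hippocampal-onset, dual-onset, neocortical-onset —
the top n1 ranks are predicted group 1, the bottom n3 group 3 and the
middle group 2. Significance of the number of positionwise correct
assignments is assessed by shuffling the true-label multiset over the
rank positions (Monte-Carlo), backed by the exact distribution obtained
by counting label arrangements through 3x3 contingency tables with
multivariate-hypergeometric weights.
"""
from __future__ import annotations

from math import comb, factorial

import numpy as np
import pandas as pd

from .rates import RATIO_COLUMNS
from .types import PermutationResult, PredictionResult

__all__ = [
    "rank_and_predict",
    "count_matches",
    "permutation_test",
    "exact_match_distribution",
    "zone_pattern",
]

GROUPS = (1, 2, 3)


def _sort_cohort(cohort: pd.DataFrame, col: str) -> pd.DataFrame:
    """Descending ratio, stable patient-id tiebreak; undefined R last."""
    df = cohort.copy()
    pid = df["patient_id"]
    try:
        tiebreak = pid.astype(int)
    except (ValueError, TypeError):
        tiebreak = pid.astype(str)
    df["_tie"] = tiebreak
    df["_undef"] = df[col].isna()
    df = df.sort_values(["_undef", col, "_tie"],
                        ascending=[True, False, True], kind="mergesort")
    return df.drop(columns=["_tie", "_undef"]).reset_index(drop=True)


def zone_pattern(group_counts: tuple[int, int, int]) -> np.ndarray:
    """Predicted group by rank position: n1 ones, n2 twos, n3 threes."""
    return np.repeat(GROUPS, group_counts)


def rank_and_predict(
    cohort: pd.DataFrame,
    event_type: str = "fast_ripple",
) -> PredictionResult:
    """Rank patients on R and assign groups by rank zone.

    The zone sizes are the cohort's true group counts, so the predicted
    label multiset always equals the true one — the rule reassigns
    labels, it never invents them. A tie warning is raised when patients
    with identical R straddle a zone boundary (their predicted groups
    then depend on the arbitrary tiebreak).
    """
    col = RATIO_COLUMNS[event_type]
    if len(cohort) < 3:
        raise ValueError("need at least 3 patients")
    counts = tuple(int((cohort["true_group"] == g).sum()) for g in GROUPS)
    if any(c == 0 for c in counts):
        raise ValueError(
            f"all three groups must be present, got counts {counts}"
        )
    df = _sort_cohort(cohort, col)
    warnings: list[str] = []
    n_undef = int(df[col].isna().sum())
    if n_undef:
        warnings.append(
            f"{n_undef} patient(s) with undefined R ranked last"
        )
    predicted = zone_pattern(counts)
    true = df["true_group"].to_numpy(dtype=int)
    n_correct = int((predicted == true).sum())

    tie_warning = False
    r = df[col].to_numpy(dtype=float)
    for boundary in (counts[0], counts[0] + counts[1]):
        if 0 < boundary < len(r) and r[boundary - 1] == r[boundary]:
            tie_warning = True
            warnings.append(
                f"tie at R={r[boundary]:g} straddles a zone boundary"
            )
    return PredictionResult(
        ranking=list(df["patient_id"]),
        predicted_group=[int(g) for g in predicted],
        true_group=[int(g) for g in true],
        n_correct=n_correct,
        accuracy=n_correct / len(df),
        tie_warning=tie_warning,
        warnings=warnings,
    )


def count_matches(prediction_pattern, label_assignment) -> int:
    """Positionwise equality count between two equal-length label vectors."""
    a = np.asarray(prediction_pattern)
    b = np.asarray(label_assignment)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    return int((a == b).sum())


def permutation_test(
    cohort: pd.DataFrame,
    n_shuffles: int = 100_000,
    seed: int = 0,
    event_type: str = "fast_ripple",
    *,
    exact: bool = True,
) -> PermutationResult:
    """Shuffled-label null for the observed number of correct assignments.

    The zone pattern (predicted group per rank position) is held fixed;
    the true-label multiset is permuted uniformly ``n_shuffles`` times.
    p = (#shuffles with matches >= observed)/n_shuffles, one-sided: the
    question is whether the rule assigns better than chance. An add-one
    smoothed p and (by default) the exact enumeration p accompany it.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be at least 1")
    pred = rank_and_predict(cohort, event_type)
    pattern = np.asarray(pred.predicted_group)
    labels = np.asarray(pred.true_group)
    n = labels.size
    rng = np.random.default_rng(seed)
    tiled = np.tile(labels, (n_shuffles, 1))
    shuffled = rng.permuted(tiled, axis=1)
    matches = (shuffled == pattern).sum(axis=1)
    null_counts = np.bincount(matches, minlength=n + 1)
    obs = pred.n_correct
    p = float((matches >= obs).sum() / n_shuffles)
    p_smooth = float(((matches >= obs).sum() + 1) / (n_shuffles + 1))
    exact_p = None
    if exact:
        counts = tuple(int((labels == g).sum()) for g in GROUPS)
        pmf = exact_match_distribution(counts, counts)
        exact_p = float(pmf[obs:].sum())
    return PermutationResult(
        observed_matches=obs,
        n_shuffles=n_shuffles,
        null_counts=null_counts,
        p_value=p,
        p_value_smoothed=p_smooth,
        seed=seed,
        exact_p=exact_p,
    )


def _multinomial(n: int, parts: tuple[int, ...]) -> int:
    out = factorial(n)
    for k in parts:
        out //= factorial(k)
    return out


def exact_match_distribution(
    zone_counts: tuple[int, int, int],
    label_counts: tuple[int, int, int],
) -> np.ndarray:
    """Exact pmf of the match count under uniform label permutation.

    Sums over all 3x3 contingency tables m[i][j] (zone i assigned label
    j) with row margins ``zone_counts`` and column margins
    ``label_counts``; each table contributes prod_i multinomial(zone_i;
    m[i,:]) arrangements and m11+m22+m33 matches. Exact integer counting;
    the returned array (index = matches, 0..N) sums to 1.
    """
    z1, z2, z3 = zone_counts
    l1, l2, l3 = label_counts
    if min(zone_counts) < 0 or min(label_counts) < 0:
        raise ValueError("counts must be non-negative")
    n = z1 + z2 + z3
    if n != l1 + l2 + l3:
        raise ValueError("zone and label counts must sum to the same total")
    total = _multinomial(n, label_counts)
    counts = [0] * (n + 1)
    for m11 in range(min(z1, l1) + 1):
        for m12 in range(min(z1 - m11, l2) + 1):
            m13 = z1 - m11 - m12
            if m13 > l3:
                continue
            for m21 in range(min(z2, l1 - m11) + 1):
                for m22 in range(min(z2 - m21, l2 - m12) + 1):
                    m23 = z2 - m21 - m22
                    if m23 > l3 - m13:
                        continue
                    m31 = l1 - m11 - m21
                    m32 = l2 - m12 - m22
                    m33 = l3 - m13 - m23
                    if min(m31, m32, m33) < 0 or m31 + m32 + m33 != z3:
                        continue
                    ways = (_multinomial(z1, (m11, m12, m13))
                            * _multinomial(z2, (m21, m22, m23))
                            * _multinomial(z3, (m31, m32, m33)))
                    counts[m11 + m22 + m33] += ways
    assert sum(counts) == total
    return np.array([c / total for c in counts])
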