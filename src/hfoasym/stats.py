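"""Group-level statistics: lesion rate comparisons and rank correlation.

The Mann-Whitney U test compares pooled hippocampal vs neocortical
channel rates (channels treated as independent observations, as the
cohort-level contact counts imply); Spearman's rank-order correlation
relates the per-patient asymmetry ratio R to the seizure-generating
group. The exact Mann-Whitney branch handles ties via a subset-sum
count over doubled midranks, which scipy's exact method does not cover.
"""
from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .rates import RATE_COLUMNS, RATIO_COLUMNS
from .types import StatResult

__all__ = [
    "mann_whitney_u",
    "spearman_rho",
    "compare_lesion_rates",
    "correlate_group_with_ratio",
]

_EXACT_MAX_N = 40  # exact enumeration below this pooled sample size


def _exact_u_cdf(pooled_double_ranks: np.ndarray, n_a: int) -> np.ndarray:
    """Number of size-``n_a`` subsets per doubled rank-sum.

    Dynamic programme over the multiset of doubled midranks (doubling
    keeps tied midranks integral). Entry ``[s]`` of the returned array
    counts subsets whose doubled rank-sum equals ``s``.
    """
    max_sum = int(pooled_double_ranks.sum())
    ways = np.zeros((n_a + 1, max_sum + 1), dtype=object)
    ways[0, 0] = 1
    for r in pooled_double_ranks:
        r = int(r)
        for k in range(n_a, 0, -1):
            ways[k, r:] = ways[k, r:] + ways[k - 1, : max_sum + 1 - r]
    return ways[n_a]


def mann_whitney_u(
    sample_a,
    sample_b,
    *,
    method: str = "auto",
) -> StatResult:
    """Two-sided Mann-Whitney U test.

    The reported statistic is U of the first sample. For pooled sizes up
    to 40 (or ``method='exact'``) the p-value comes from exact
    enumeration of all rank arrangements, tie-aware; larger samples use
    the tie-corrected normal approximation.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)

    if method == "auto":
        method = "exact" if n_a + n_b <= _EXACT_MAX_N else "asymptotic"
    if method == "exact":
        dranks = np.round(2 * ranks).astype(int)
        counts = _exact_u_cdf(dranks, n_a)
        total = sum(counts)
        # doubled rank-sum s corresponds to U = (s - n_a(n_a+1))/2
        obs = int(round(2 * u_a)) + n_a * (n_a + 1)
        sums = np.arange(counts.size)
        p_le = sum(counts[sums <= obs]) / total
        p_ge = sum(counts[sums >= obs]) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        note = "exact enumeration (tie-aware)"
    elif method == "asymptotic":
        res = sstats.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
        note = "tie-corrected normal approximation"
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatResult("U", u_a, float(p), (n_a, n_b), note)


def spearman_rho(x, y, *, method: str = "t") -> StatResult:
    """Spearman rank-order correlation with average ranks for ties.

    rho is the Pearson correlation of the rank vectors; the default
    p-value uses the t approximation with n-2 degrees of freedom. For
    n <= 10, ``method='exact'`` enumerates all permutations of one rank
    vector (two-sided on |rho|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return StatResult("rho", float("nan"), float("nan"), (n,),
                          "undefined: constant input")
    rho, p_t = sstats.spearmanr(x, y)
    if method == "t":
        return StatResult("rho", float(rho), float(p_t), (n,),
                          "t approximation, n-2 df")
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    if n > 10:
        raise ValueError("exact permutation p limited to n <= 10")
    rx = sstats.rankdata(x) - (n + 1) / 2.0
    ry = sstats.rankdata(y) - (n + 1) / 2.0
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    obs = abs(float(rx @ ry))
    hits = total = 0
    for perm in permutations(range(n)):
        total += 1
        if abs(float(rx @ ry[list(perm)])) >= obs - 1e-12:
            hits += 1
    return StatResult("rho", float(rho), hits / total, (n,),
                      "exact permutation (all n! orderings)")


def compare_lesion_rates(
    rates: pd.DataFrame,
    soz_filter: str = "all",
) -> dict[str, StatResult]:
    """Hippocampal vs neocortical channel-rate comparison per event type.

    Channels are pooled across patients. ``soz_filter`` restricts both
    sides to SOZ or non-SOZ contacts. An empty side yields a flagged
    (NaN) result rather than an error.
    """
    if soz_filter not in ("all", "soz_only", "nonsoz_only"):
        raise ValueError(f"unknown soz_filter {soz_filter!r}")
    sel = rates
    if soz_filter == "soz_only":
        sel = sel[sel["soz"].astype(bool)]
    elif soz_filter == "nonsoz_only":
        sel = sel[~sel["soz"].astype(bool)]
    hip = sel[sel["lesion"] == "hippocampal"]
    neo = sel[sel["lesion"] == "neocortical"]
    out: dict[str, StatResult] = {}
    for etype, col in RATE_COLUMNS.items():
        if len(hip) == 0 or len(neo) == 0:
            out[etype] = StatResult("U", float("nan"), float("nan"),
                                    (len(hip), len(neo)),
                                    "undefined: empty contact subset")
        else:
            out[etype] = mann_whitney_u(hip[col].to_numpy(), neo[col].to_numpy())
    return out


def correlate_group_with_ratio(
    cohort: pd.DataFrame,
    event_type: str,
    *,
    method: str = "t",
) -> StatResult:
    """Spearman correlation between true group (1..3) and the ratio R.

    Patients with undefined R (NaN) are excluded; their number is
    reflected in the reported n.
    """
    col = RATIO_COLUMNS[event_type]
    sub = cohort[["true_group", col]].dropna()
    if len(sub) < 4:
        return StatResult("rho", float("nan"), float("nan"), (len(sub),),
                          "undefined: fewer than 4 patients with defined R")
    return spearman_rho(sub["true_group"].to_numpy(), sub[col].to_numpy(),
                        method=method)
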