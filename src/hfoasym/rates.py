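"""Per-channel event rates, lesion means and the asymmetry ratio R.

R = (hippocampal mean rate - neocortical mean rate) /
    (hippocampal mean rate + neocortical mean rate)

bounded in [-1, 1]: R near 1 means events concentrate in the hippocampal
lesion, near -1 in the neocortical lesion, near 0 similar on both sides.
"Mean rate" is the arithmetic mean over contacts of per-contact rates
(each contact weighted equally); a pooled-count alternative is available
via ``pooled=True``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import EVENT_TYPES, ChannelInfo, EventRecord

__all__ = [
    "RATE_COLUMNS",
    "compute_channel_rates",
    "lesion_mean_rates",
    "compute_ratio",
    "build_cohort_table",
    "RATIO_COLUMNS",
]

#: rate-table column per event type. ``rate_ripple`` holds ALL ripple-band
#: events (isolated ripples + IES-ripples); the IES-ripple subset is also
#: reported on its own, so users can subtract to get isolated ripples.
RATE_COLUMNS = {
    "IES": "rate_ies",
    "ripple": "rate_ripple",
    "IES_ripple": "rate_ies_ripple",
    "fast_ripple": "rate_fr",
}

RATIO_COLUMNS = {
    "IES": "r_ies",
    "ripple": "r_ripple",
    "IES_ripple": "r_ies_ripple",
    "fast_ripple": "r_fr",
}


def compute_channel_rates(
    events: list[EventRecord],
    channels: list[ChannelInfo],
    duration_min: float,
    *,
    patient_id: str = "",
    ripples_include_cooccurring: bool = True,
) -> pd.DataFrame:
    """Events/min per channel and event type.

    Every metadata channel appears, with zero rates if it had no events.
    With ``ripples_include_cooccurring`` (default) the ripple column counts
    IES-ripples too, mirroring how ripple rates are reported clinically.
    """
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    known = {c.channel_id for c in channels}
    counts: dict[str, dict[str, int]] = {
        c.channel_id: {t: 0 for t in EVENT_TYPES} for c in channels
    }
    for ev in events:
        if ev.channel_id not in known:
            raise ValueError(f"event on unknown channel {ev.channel_id!r}")
        counts[ev.channel_id][ev.event_type] += 1
    rows = []
    for c in channels:
        n = counts[c.channel_id]
        n_ripple = n["ripple"] + (n["IES_ripple"] if ripples_include_cooccurring else 0)
        rows.append({
            "patient_id": patient_id,
            "channel_id": c.channel_id,
            "lesion": c.lesion,
            "soz": c.soz,
            "rate_ies": n["IES"] / duration_min,
            "rate_ripple": n_ripple / duration_min,
            "rate_ies_ripple": n["IES_ripple"] / duration_min,
            "rate_fr": n["fast_ripple"] / duration_min,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LesionMeans:
    """Mean rate per event type over the selected contacts of one lesion."""

    lesion: str
    soz_filter: str
    n_contacts: int
    means: dict[str, float]  # rate column -> mean; NaN when n_contacts == 0

    @property
    def defined(self) -> bool:
        return self.n_contacts > 0


def lesion_mean_rates(
    rates: pd.DataFrame,
    lesion: str,
    soz_filter: str = "all",
    *,
    pooled: bool = False,
) -> LesionMeans:
    """Mean rates over one lesion's contacts, optionally SOZ-restricted.

    ``soz_filter`` is one of ``all``, ``soz_only``, ``nonsoz_only``. With
    zero contacts after filtering the means are NaN and ``defined`` is
    False. ``pooled=True`` weights contacts by their (equal) recording
    time via the plain mean of counts — identical here to the contact mean
    since all contacts share one duration, but kept as an explicit flag
    for datasets with unequal durations.
    """
    if soz_filter not in ("all", "soz_only", "nonsoz_only"):
        raise ValueError(f"unknown soz_filter {soz_filter!r}")
    sel = rates[rates["lesion"] == lesion]
    if soz_filter == "soz_only":
        sel = sel[sel["soz"]]
    elif soz_filter == "nonsoz_only":
        sel = sel[~sel["soz"].astype(bool)]
    n = len(sel)
    means = {}
    for col in RATE_COLUMNS.values():
        means[col] = float(sel[col].mean()) if n else float("nan")
    return LesionMeans(lesion, soz_filter, n, means)


def compute_ratio(hip_mean: float, neo_mean: float) -> float:
    """Asymmetry ratio R = (h - n)/(h + n); NaN when both means are zero.

    Antisymmetric under lesion exchange and invariant to rescaling both
    means by the same positive factor; equals +/-1 iff exactly one mean
    is zero.
    """
    if hip_mean < 0 or neo_mean < 0:
        raise ValueError("rates must be non-negative")
    if math.isnan(hip_mean) or math.isnan(neo_mean):
        return float("nan")
    total = hip_mean + neo_mean
    if total == 0:
        return float("nan")
    return (hip_mean - neo_mean) / total


def build_cohort_table(
    rates: pd.DataFrame,
    groups: pd.DataFrame,
) -> pd.DataFrame:
    """Per-patient asymmetry ratios with true group labels.

    Ratios use ALL contacts in either lesion (never the SOZ flag), so R is
    computed independent of any seizure information. Columns:
    patient_id, true_group, r_ies, r_ripple, r_ies_ripple, r_fr. An
    undefined ratio (both lesion means zero) is NaN.
    """
    group_of = dict(zip(groups["patient_id"], groups["group"]))
    rows = []
    for pid, sub in rates.groupby("patient_id", sort=True):
        if pid not in group_of:
            raise ValueError(f"patient {pid!r} missing from group table")
        hip = lesion_mean_rates(sub, "hippocampal", "all")
        neo = lesion_mean_rates(sub, "neocortical", "all")
        row = {"patient_id": pid, "true_group": int(group_of[pid])}
        for etype, rcol in RATE_COLUMNS.items():
            if hip.defined and neo.defined:
                row[RATIO_COLUMNS[etype]] = compute_ratio(
                    hip.means[rcol], neo.means[rcol])
            else:  # a lesion without contacts gives no asymmetry information
                row[RATIO_COLUMNS[etype]] = float("nan")
        rows.append(row)
    out = pd.DataFrame(rows)
    if not set(np.unique(out["true_group"])) <= {1, 2, 3}:
        raise ValueError("true_group values must be in {1, 2, 3}")
    return out
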