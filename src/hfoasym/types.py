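"""Core data containers shared across the pipeline.

All times are seconds from segment start; intervals are half-open
``[start, end)``. Signals are microvolts. Event rates are events/min.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The four interictal event classes analysed by the pipeline. ``ripple``
#: denotes a ripple-band (80-250 Hz) oscillation not co-occurring with a
#: spike; ``IES_ripple`` is a ripple that does. Reported "ripple" rates
#: may include IES_ripples (see :mod:`hfoasym.rates`).
EVENT_TYPES = ("IES", "ripple", "IES_ripple", "fast_ripple")

LESIONS = ("hippocampal", "neocortical", "other")


@dataclass(frozen=True)
class ChannelInfo:
    """One SEEG contact: identifier, lesion membership and SOZ flag."""

    channel_id: str
    lesion: str  # hippocampal | neocortical | other
    soz: bool

    def __post_init__(self) -> None:
        if self.lesion not in LESIONS:
            raise ValueError(
                f"channel {self.channel_id!r}: lesion must be one of "
                f"{LESIONS}, got {self.lesion!r}"
            )


@dataclass(frozen=True)
class GroundTruthEvent:
    """A transient injected by the simulator (the detector never sees these)."""

    channel_id: str
    event_type: str
    onset: float
    duration: float
    center_frequency: float | None = None  # Hz; None for IES
    amplitude: float = 0.0  # µV, peak

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class EventRecord:
    """One detected event on a channel."""

    channel_id: str
    event_type: str
    start: float
    end: float
    peak_envelope: float = float("nan")  # µV
    n_cycles: int | None = None  # HFO types only

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.start < self.end:
            raise ValueError("start must precede end")


@dataclass
class SeegRecording:
    """Multichannel interictal SEEG segment with channel metadata.

    ``signals`` has shape (n_channels, n_samples) in µV; row order matches
    ``channels``. ``ground_truth`` is empty for real recordings.
    """

    patient_id: str
    signals: np.ndarray
    sampling_rate: float
    channels: list[ChannelInfo]
    ground_truth: list[GroundTruthEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2 or self.signals.shape[0] != len(self.channels):
            raise ValueError(
                f"signals shape {self.signals.shape} does not match "
                f"{len(self.channels)} channels"
            )
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("channel_id values must be unique")

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.signals.shape[1] / self.sampling_rate

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    def channel_index(self, channel_id: str) -> int:
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"channel {channel_id!r} not in recording") from None


@dataclass(frozen=True)
class StatResult:
    """Outcome of one hypothesis test or correlation."""

    statistic_name: str
    statistic_value: float
    p_value: float
    n_per_group: tuple[int, ...]
    method_note: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def defined(self) -> bool:
        return not np.isnan(self.statistic_value)


@dataclass
class PredictionResult:
    """Rank-based assignment of seizure-generating lesions in a cohort.

    ``ranking`` is patient ids in descending order of the fast-ripple
    asymmetry ratio; ``predicted_group``/``true_group`` align with it.
    """

    ranking: list[str]
    predicted_group: list[int]
    true_group: list[int]
    n_correct: int
    accuracy: float
    tie_warning: bool
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "ranking": list(self.ranking),
            "predicted_group": list(self.predicted_group),
            "true_group": list(self.true_group),
            "n_correct": self.n_correct,
            "accuracy": self.accuracy,
            "tie_warning": self.tie_warning,
            "warnings": list(self.warnings),
        }


@dataclass
class PermutationResult:
    """Monte-Carlo (and optionally exact) null for the match count."""

    observed_matches: int
    n_shuffles: int
    null_counts: np.ndarray  # histogram over 0..n_patients
    p_value: float
    p_value_smoothed: float
    seed: int
    exact_p: float | None = None

    def as_dict(self) -> dict:
        return {
            "observed_matches": self.observed_matches,
            "n_shuffles": self.n_shuffles,
            "null_counts": [int(c) for c in self.null_counts],
            "p_value": self.p_value,
            "p_value_smoothed": self.p_value_smoothed,
            "seed": self.seed,
            "exact_p": self.exact_p,
        }
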