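"""Configuration objects for simulation and detection.

Defaults mirror the clinical recording setup the pipeline targets:
2 kHz SEEG sampled through an 800 Hz anti-aliasing low-pass, 1-hour
slow-wave-sleep segments, a 16-patient dual-pathology cohort with
5/7/4 patients whose seizures arise from the hippocampal lesion, both
lesions, or the neocortical lesion respectively, and roughly 60
hippocampal vs 124 neocortical contacts cohort-wide.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

from .types import EVENT_TYPES


def _default_rates() -> dict[str, tuple[float, float]]:
    # (hippocampal, neocortical) baseline rates, events/min. Hippocampal
    # baselines exceed neocortical ones for every type: hippocampal
    # lesions generate more interictal events overall, which is exactly
    # why the asymmetry ratio (not the raw rate) carries the focus signal.
    return {
        "IES": (4.0, 1.5),
        "ripple": (2.0, 0.8),
        "IES_ripple": (1.0, 0.4),
        "fast_ripple": (1.0, 0.4),
    }


def _default_snr() -> dict[str, float]:
    return {t: 6.0 for t in EVENT_TYPES}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dual-pathology SEEG cohort generator.

    Parameters
    ----------
    n_patients, group_counts
        Cohort size and the number of patients per seizure-generating
        group (1 = hippocampal, 2 = both, 3 = neocortical).
    cohort_channel_totals
        Total (hippocampal, neocortical) contact counts across the whole
        cohort; split over patients uniformly at random with at least one
        contact per lesion per patient.
    segment_duration, sampling_rate
        Seconds of interictal recording per patient and Hz.
    background_spectral_exponent, background_sd
        1/f^alpha exponent of the background noise and its standard
        deviation in µV after the 800 Hz low-pass.
    event_rate_params
        Per event type, (hippocampal, neocortical) baseline rates in
        events/min. Fast-ripple lesion means are rescaled per group by
        ``fastripple_asymmetry_by_group`` (total level preserved).
    fastripple_asymmetry_by_group
        Target expected asymmetry ratio R of fast-ripple rates for
        groups 1..3, each in [-1, 1].
    rate_dispersion_shape
        Gamma shape of per-channel true rates around the lesion mean
        (shape 4 gives a coefficient of variation of 0.5 across contacts).
    snr_params
        Event peak amplitude as a multiple of ``background_sd``.
    lowpass_hz
        Acquisition low-pass cut-off applied to the background.
    seed
        Base seed; every derived stream is deterministic given it.
    """

    n_patients: int = 16
    group_counts: tuple[int, int, int] = (5, 7, 4)
    cohort_channel_totals: tuple[int, int] = (60, 124)
    segment_duration: float = 3600.0
    sampling_rate: float = 2000.0
    background_spectral_exponent: float = 1.0
    background_sd: float = 25.0
    event_rate_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_rates
    )
    fastripple_asymmetry_by_group: tuple[float, float, float] = (0.6, 0.1, -0.3)
    rate_dispersion_shape: float = 4.0
    snr_params: dict[str, float] = field(default_factory=_default_snr)
    lowpass_hz: float = 800.0
    soz_assignment_rule: str = "by_group"
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if sum(self.group_counts) != self.n_patients:
            raise ValueError(
                f"group_counts {self.group_counts} sum to "
                f"{sum(self.group_counts)}, expected n_patients={self.n_patients}"
            )
        if any(g < 0 for g in self.group_counts):
            raise ValueError("group counts must be non-negative")
        for t, (h, n) in self.event_rate_params.items():
            if t not in EVENT_TYPES:
                raise ValueError(f"unknown event type {t!r} in event_rate_params")
            if h < 0 or n < 0:
                raise ValueError(f"negative rate for {t}: ({h}, {n})")
        missing = set(EVENT_TYPES) - set(self.event_rate_params)
        if missing:
            raise ValueError(f"event_rate_params missing types: {sorted(missing)}")
        if self.sampling_rate < 2 * 500.0:
            raise ValueError(
                "sampling_rate must be at least 1000 Hz so the fast-ripple "
                "band (up to 500 Hz) is below Nyquist"
            )
        for a in self.fastripple_asymmetry_by_group:
            if not -1.0 <= a <= 1.0:
                raise ValueError(f"asymmetry {a} outside [-1, 1]")
        if any(c < self.n_patients for c in self.cohort_channel_totals):
            raise ValueError("need at least one contact per lesion per patient")
        if self.segment_duration <= 0 or self.background_sd <= 0:
            raise ValueError("segment_duration and background_sd must be positive")
        if self.rate_dispersion_shape <= 0:
            raise ValueError("rate_dispersion_shape must be positive")
        if self.soz_assignment_rule != "by_group":
            raise ValueError("only the 'by_group' SOZ rule is implemented")
        return self

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        for key in ("group_counts", "cohort_channel_totals",
                    "fastripple_asymmetry_by_group"):
            if key in d:
                d[key] = tuple(d[key])
        if "event_rate_params" in d:
            d["event_rate_params"] = {
                k: tuple(v) for k, v in d["event_rate_params"].items()
            }
        return cls(**d).validate()


@dataclass
class DetectionParams:
    """Thresholds of the band-energy event detector.

    The detector band-passes each channel (zero-phase FIR), takes an RMS
    envelope, sets the threshold at ``threshold_k`` robust standard
    deviations (1.4826 x MAD) above the envelope median, and keeps
    supra-threshold intervals sustaining at least ``min_cycles``
    oscillation cycles. Spikes use an amplitude + half-width criterion in
    ``spike_band``.
    """

    ripple_band: tuple[float, float] = (80.0, 250.0)
    fastripple_band: tuple[float, float] = (250.0, 500.0)
    spike_band: tuple[float, float] = (10.0, 60.0)
    envelope_window_ms: dict[str, float] = field(
        default_factory=lambda: {"ripple": 10.0, "fast_ripple": 5.0}
    )
    threshold_k: float = 3.0
    min_cycles: int = 4
    merge_gap_ms: float = 10.0
    spike_amp_k: float = 3.0
    spike_duration_ms: tuple[float, float] = (20.0, 200.0)
    #: fraction of peak prominence descended before measuring spike width
    #: (0.65 -> width taken at 35% of peak amplitude)
    spike_width_rel_height: float = 0.65
    spike_merge_gap_ms: float = 50.0
    cooccurrence_window_ms: float = 50.0
    #: require the event's dominant frequency (above 60 Hz) to lie inside
    #: the detection band; rejects cross-band spectral leakage
    spectral_peak_check: bool = True

    def validate(self) -> "DetectionParams":
        for name, (lo, hi) in (
            ("ripple_band", self.ripple_band),
            ("fastripple_band", self.fastripple_band),
            ("spike_band", self.spike_band),
        ):
            if not 0 < lo < hi:
                raise ValueError(f"{name} must satisfy 0 < low < high, got {(lo, hi)}")
        if self.ripple_band[1] > self.fastripple_band[0]:
            raise ValueError("ripple band must not extend above the fast-ripple band")
        if self.threshold_k <= 0 or self.spike_amp_k <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_cycles < 1:
            raise ValueError("min_cycles must be at least 1")
        lo, hi = self.spike_duration_ms
        if not 0 < lo < hi:
            raise ValueError("spike_duration_ms must satisfy 0 < low < high")
        return self

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DetectionParams":
        d = dict(d)
        for key in ("ripple_band", "fastripple_band", "spike_band",
                    "spike_duration_ms"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()


def load_yaml_config(path: str) -> dict[str, Any]:
    """Load a YAML file holding ``simulation:`` and/or ``detection:`` blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, Any] = {}
    if "simulation" in raw:
        out["simulation"] = SimulationConfig.from_dict(raw["simulation"])
    if "detection" in raw:
        out["detection"] = DetectionParams.from_dict(raw["detection"])
    for k in raw:
        if k not in ("simulation", "detection"):
            out[k] = raw[k]
    return out
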