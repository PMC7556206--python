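"""Synthetic dual-pathology SEEG cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-channel true event rates are gamma-distributed around
lesion-level means, observed counts are Poisson, hippocampal baselines
exceed neocortical ones for every event type, and the hippocampo-
neocortical fast-ripple asymmetry decreases from group 1 (hippocampal
focus) to group 3 (neocortical focus).

Two tiers are provided: :func:`simulate_rate_table` draws per-channel
observed rates directly (milliseconds; for exercising the statistics),
while :func:`simulate_recording` synthesises full µV time series —
1/f background noise with transient spikes and Gaussian-windowed HFO
bursts — for exercising the detector.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import SimulationConfig
from .types import EVENT_TYPES, ChannelInfo, GroundTruthEvent, SeegRecording

__all__ = [
    "PatientSpec",
    "generate_cohort",
    "simulate_recording",
    "simulate_rate_table",
    "pink_noise",
]

#: SOZ membership per group: which lesion(s) contain seizure-onset contacts.
_SOZ_LESIONS = {1: ("hippocampal",), 2: ("hippocampal", "neocortical"),
                3: ("neocortical",)}

#: Cycle-count range of injected HFO bursts.
_HFO_CYCLES = (6, 10)

#: One-sided spectral margin, in units of the burst's Gaussian power-spectrum
#: width, kept between the burst's centre frequency and the band edge. 2.9
#: standard deviations leaves < 1% of the energy outside the band, so
#: injected ripples/fast ripples are spectrally unambiguous ground truth.
_EDGE_SIGMAS = 2.9


@dataclass
class PatientSpec:
    """Ground-truth description of one simulated patient."""

    patient_id: str
    group: int
    channels: list[ChannelInfo]
    true_rates: dict[str, dict[str, float]]  # channel_id -> type -> events/min
    lesion_means: dict[str, tuple[float, float]] = field(default_factory=dict)


def _split_total(total: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly split ``total`` contacts over ``n`` patients, each >= 1."""
    extra = rng.multinomial(total - n, np.full(n, 1.0 / n))
    return extra + 1


def _lesion_means(config: SimulationConfig, group: int) -> dict[str, tuple[float, float]]:
    """Lesion-level mean rates for one patient, after asymmetry scaling.

    Fast-ripple means are rescaled so the expected asymmetry ratio
    (h - n)/(h + n) equals the group's configured value while h + n is
    preserved; other event types keep their baselines.
    """
    means = {t: tuple(config.event_rate_params[t]) for t in EVENT_TYPES}
    a = config.fastripple_asymmetry_by_group[group - 1]
    h0, n0 = config.event_rate_params["fast_ripple"]
    s = 0.5 * (h0 + n0)
    means["fast_ripple"] = (s * (1.0 + a), s * (1.0 - a))
    return means


def generate_cohort(config: SimulationConfig) -> list[PatientSpec]:
    """Draw the cohort structure: groups, channel layouts, true rates.

    Deterministic given ``config.seed``. Per-channel true rates are
    Gamma(shape, mean/shape) around the lesion mean, independently per
    channel and event type.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    groups = np.repeat([1, 2, 3], config.group_counts)
    hip_counts = _split_total(config.cohort_channel_totals[0], config.n_patients, rng)
    neo_counts = _split_total(config.cohort_channel_totals[1], config.n_patients, rng)
    shape = config.rate_dispersion_shape

    cohort: list[PatientSpec] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:02d}"
        group = int(groups[i])
        soz_lesions = _SOZ_LESIONS[group]
        channels = [
            ChannelInfo(f"{pid}-H{j + 1}", "hippocampal", "hippocampal" in soz_lesions)
            for j in range(hip_counts[i])
        ] + [
            ChannelInfo(f"{pid}-N{j + 1}", "neocortical", "neocortical" in soz_lesions)
            for j in range(neo_counts[i])
        ]
        means = _lesion_means(config, group)
        true_rates: dict[str, dict[str, float]] = {}
        for ch in channels:
            side = 0 if ch.lesion == "hippocampal" else 1
            true_rates[ch.channel_id] = {
                t: float(rng.gamma(shape, means[t][side] / shape))
                if means[t][side] > 0 else 0.0
                for t in EVENT_TYPES
            }
        cohort.append(PatientSpec(pid, group, channels, true_rates, means))
    return cohort


# ---------------------------------------------------------------------------
# signal synthesis


def pink_noise(n_samples: int, fs: float, exponent: float, sd: float,
               lowpass_hz: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha Gaussian noise, low-pass filtered, scaled to ``sd`` µV."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n_samples)
    if lowpass_hz < fs / 2:
        taps = sps.firwin(301, lowpass_hz, fs=fs)
        x = sps.filtfilt(taps, 1.0, x)
    return x * (sd / x.std())


def _feasible_band(band: tuple[float, float], n_cycles: int) -> tuple[float, float]:
    """Frequency sub-band keeping >= ~99% of burst energy inside ``band``.

    A burst of ``n`` cycles Gaussian-windowed at sigma = duration/6 has an
    amplitude-spectrum width sigma_f = 6f/(2*pi*n); its power spectrum is
    Gaussian with sigma_f/sqrt(2). The centre frequency must sit
    ``_EDGE_SIGMAS`` of those widths away from both edges.
    """
    c = _EDGE_SIGMAS * 6.0 / (2.0 * np.pi * n_cycles * np.sqrt(2.0))
    lo = band[0] / (1.0 - c) if c < 1 else np.inf
    hi = band[1] / (1.0 + c)
    if not lo < hi:
        raise ValueError(
            f"band {band} too narrow for a {n_cycles}-cycle burst"
        )
    return lo, hi


def _hfo_burst(fs: float, band: tuple[float, float], amplitude: float,
               rng: np.random.Generator) -> tuple[np.ndarray, float, float]:
    """Gaussian-windowed sinusoid; returns (waveform, duration_s, freq_hz)."""
    n_cycles = int(rng.integers(_HFO_CYCLES[0], _HFO_CYCLES[1] + 1))
    f = float(rng.uniform(*_feasible_band(band, n_cycles)))
    duration = n_cycles / f
    t = np.arange(int(round(duration * fs))) / fs
    center = duration / 2.0
    window = np.exp(-0.5 * ((t - center) / (duration / 6.0)) ** 2)
    phase = rng.uniform(0, 2 * np.pi)
    return amplitude * window * np.sin(2 * np.pi * f * t + phase), duration, f


def _spike_wave(fs: float, amplitude: float,
                rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Biphasic sharp transient with an optional after-going slow wave.

    One raised-cosine-windowed cycle whose positive (peak) lobe spans
    50-80 ms, so the dominant spectral content (6-10 Hz fundamental plus
    harmonics) reaches into the spike detection band; half the events
    carry a 200 ms slow wave of opposite polarity at 35% amplitude.
    """
    peak_width = rng.uniform(0.05, 0.08)
    n = int(round(2 * peak_width * fs))
    t = np.arange(n) / n
    wave = np.sin(2 * np.pi * t) * np.hanning(n)
    wave = wave / np.abs(wave).max()
    if rng.random() < 0.5:
        slow = -0.35 * np.hanning(int(round(0.2 * fs)))
        wave = np.concatenate([wave, slow])
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return sign * amplitude * wave, len(wave) / fs


def _place_events(n: int, durations: np.ndarray, segment: float,
                  rng: np.random.Generator, channel_id: str,
                  max_tries: int = 200) -> np.ndarray:
    """Uniform non-overlapping onsets for ``n`` events; same-type overlap
    is forbidden so ground truth stays unambiguous."""
    if n == 0:
        return np.empty(0)
    if durations.sum() > segment:
        raise ValueError(
            f"channel {channel_id}: requested event rate too high — total "
            f"event duration exceeds the segment"
        )
    for _ in range(max_tries):
        onsets = rng.uniform(0, segment - durations.max(), size=n)
        order = np.argsort(onsets)
        o, d = onsets[order], durations[order]
        if np.all(o[1:] >= o[:-1] + d[:-1]):
            return onsets
    raise ValueError(
        f"channel {channel_id}: could not place {n} non-overlapping events "
        f"after {max_tries} attempts — rate too high for the segment"
    )


def simulate_recording(spec: PatientSpec, config: SimulationConfig) -> SeegRecording:
    """Synthesise the full µV time series for one patient.

    Background is 1/f^alpha noise low-pass filtered at the acquisition
    cut-off; event counts per channel and type are Poisson(rate x
    duration); event times are uniform and non-overlapping within a type
    (types may overlap — IES-ripples are a ripple summed onto a spike).
    Every injected event is returned in ``ground_truth``.
    """
    config.validate()
    fs = config.sampling_rate
    n_samples = int(round(config.segment_duration * fs))
    duration_min = config.segment_duration / 60.0
    patient_index = int(spec.patient_id.lstrip("P"))
    signals = np.empty((len(spec.channels), n_samples))
    ground_truth: list[GroundTruthEvent] = []

    for ci, ch in enumerate(spec.channels):
        rng = np.random.default_rng([config.seed, 202, patient_index, ci])
        x = pink_noise(n_samples, fs, config.background_spectral_exponent,
                       config.background_sd, config.lowpass_hz, rng)
        rates = spec.true_rates[ch.channel_id]
        for etype in EVENT_TYPES:
            lam = rates[etype] * duration_min
            n_ev = int(rng.poisson(lam)) if lam > 0 else 0
            if n_ev == 0:
                continue
            amp = config.snr_params[etype] * config.background_sd
            waves: list[np.ndarray] = []
            durs = np.empty(n_ev)
            freqs: list[float | None] = []
            for k in range(n_ev):
                if etype == "IES":
                    w, d = _spike_wave(fs, amp, rng)
                    f: float | None = None
                elif etype in ("ripple", "fast_ripple"):
                    band = (80.0, 250.0) if etype == "ripple" else (250.0, 500.0)
                    w, d, f = _hfo_burst(fs, band, amp, rng)
                else:  # IES_ripple: ripple summed onto a spike at the same time
                    ws, ds = _spike_wave(fs, amp, rng)
                    wr, dr, f = _hfo_burst(fs, (80.0, 250.0), amp, rng)
                    d = max(ds, dr)
                    w = np.zeros(int(round(d * fs)))
                    w[: len(ws)] += ws
                    # centre the ripple on the spike peak
                    off = max(0, int(round(0.25 * len(ws))) - len(wr) // 2)
                    w[off: off + len(wr)] += wr[: len(w) - off]
                waves.append(w)
                durs[k] = d
                freqs.append(f)
            onsets = _place_events(n_ev, durs, config.segment_duration, rng,
                                   ch.channel_id)
            for w, onset, d, f in zip(waves, onsets, durs, freqs):
                i0 = int(round(onset * fs))
                seg = x[i0: i0 + len(w)]
                seg += w[: len(seg)]
                ground_truth.append(GroundTruthEvent(
                    ch.channel_id, etype, float(onset), float(d),
                    None if f is None else float(f), float(amp)))
        signals[ci] = x

    ground_truth.sort(key=lambda e: (e.channel_id, e.onset))
    return SeegRecording(spec.patient_id, signals, fs, list(spec.channels),
                         ground_truth)


def simulate_rate_table(
    config: SimulationConfig,
    cohort: list[PatientSpec] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fast tier: draw observed per-channel rates without signal synthesis.

    Observed rate = Poisson(true_rate x duration)/duration, per channel and
    event type. Returns ``(rates, groups)``: the per-channel rate table
    (patient_id, channel_id, lesion, soz, rate_ies, rate_ripple,
    rate_ies_ripple, rate_fr; ``rate_ripple`` includes IES-ripples) and the
    patient_id -> true group table.
    """
    config.validate()
    if cohort is None:
        cohort = generate_cohort(config)
    rng = np.random.default_rng([config.seed, 303])
    duration_min = config.segment_duration / 60.0
    rows = []
    for spec in cohort:
        for ch in spec.channels:
            counts = {
                t: int(rng.poisson(spec.true_rates[ch.channel_id][t] * duration_min))
                for t in EVENT_TYPES
            }
            rows.append({
                "patient_id": spec.patient_id,
                "channel_id": ch.channel_id,
                "lesion": ch.lesion,
                "soz": ch.soz,
                "rate_ies": counts["IES"] / duration_min,
                "rate_ripple": (counts["ripple"] + counts["IES_ripple"]) / duration_min,
                "rate_ies_ripple": counts["IES_ripple"] / duration_min,
                "rate_fr": counts["fast_ripple"] / duration_min,
            })
    rates = pd.DataFrame(rows)
    groups = pd.DataFrame(
        {"patient_id": [s.patient_id for s in cohort],
         "group": [s.group for s in cohort]}
    )
    return rates, groups
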