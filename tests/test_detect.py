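"""Event detector: constructed injections, band selectivity, invariants."""
import numpy as np
import pytest

from hfoasym.config import DetectionParams
from hfoasym.detect import (classify_cooccurrence, detect_band_events,
                            detect_spikes)
from hfoasym.types import EventRecord

FS = 2000.0


def _burst(freq, n_cycles, amplitude, fs=FS):
    dur = n_cycles / freq
    t = np.arange(int(dur * fs)) / fs
    window = np.exp(-0.5 * ((t - dur / 2) / (dur / 6)) ** 2)
    return amplitude * window * np.sin(2 * np.pi * freq * t)


def _biphasic_spike(amplitude, peak_width=0.06, fs=FS):
    n = int(2 * peak_width * fs)
    t = np.arange(n) / n
    w = np.sin(2 * np.pi * t) * np.hanning(n)
    return amplitude * w / np.abs(w).max()


def test_single_ripple_burst_detected_once(noise_60s):
    x = noise_60s.copy()
    burst = _burst(150.0, 8, 250.0)  # 10x background SD
    i0 = 60_000
    x[i0:i0 + len(burst)] += burst
    events = detect_band_events(x, FS, (80.0, 250.0), event_type="ripple")
    assert len(events) == 1
    mid = (i0 + len(burst) / 2) / FS
    assert events[0].start <= mid <= events[0].end
    assert events[0].n_cycles >= 4


def test_band_exclusivity_of_pure_tone_bursts(noise_60s):
    params = DetectionParams()
    for freq, home in ((150.0, "ripple"), (320.0, "fast_ripple")):
        x = noise_60s.copy()
        burst = _burst(freq, 8, 250.0)
        x[30_000:30_000 + len(burst)] += burst
        n_rip = len(detect_band_events(x, FS, params.ripple_band, params,
                                       event_type="ripple"))
        n_fr = len(detect_band_events(x, FS, params.fastripple_band, params,
                                      event_type="fast_ripple"))
        assert (n_rip, n_fr) == ((1, 0) if home == "ripple" else (0, 1))


def test_flat_signal_yields_no_events():
    x = np.zeros(int(20 * FS))
    assert detect_band_events(x, FS, (80.0, 250.0)) == []
    assert detect_spikes(x, FS) == []


def test_short_signal_and_bad_band_rejected():
    with pytest.raises(ValueError, match="10 s"):
        detect_band_events(np.random.default_rng(0).normal(size=1000), FS,
                           (80.0, 250.0))
    with pytest.raises(ValueError, match="incompatible"):
        detect_band_events(np.zeros(40_000), 800.0, (250.0, 500.0))


def test_injected_spike_detected_exactly_once(noise_60s):
    x = noise_60s.copy()
    spike = _biphasic_spike(8 * 25.0)
    i0 = 90_000
    x[i0:i0 + len(spike)] += spike
    events = detect_spikes(x, FS)
    assert len(events) == 1
    assert events[0].start < (i0 + len(spike)) / FS and events[0].end > i0 / FS


def test_spike_sensitivity_at_five_sd():
    """At 5x background SD the spike detector recovers >= 90% of events."""
    hits = 0
    n = 30
    for seed in range(n):
        rng = np.random.default_rng(1000 + seed)
        from hfoasym.simulate import pink_noise
        x = pink_noise(int(30 * FS), FS, 1.0, 25.0, 800.0, rng)
        spike = _biphasic_spike(5 * 25.0, peak_width=rng.uniform(0.05, 0.08))
        i0 = 30_000
        x[i0:i0 + len(spike)] += spike
        ev = detect_spikes(x, FS)
        hits += any(e.start < (i0 + len(spike)) / FS and e.end > i0 / FS
                    for e in ev)
    assert hits / n >= 0.9


def test_threshold_monotonicity(noise_60s):
    """Raising the detection threshold never increases the event count."""
    x = noise_60s.copy()
    rng = np.random.default_rng(3)
    for _ in range(20):  # sprinkle bursts of mixed strength
        f = rng.uniform(100, 240)
        b = _burst(f, int(rng.integers(6, 11)), rng.uniform(40, 250))
        i0 = int(rng.uniform(0, len(x) - len(b)))
        x[i0:i0 + len(b)] += b
    counts = []
    for k in (2.0, 2.5, 3.0, 4.0, 5.0, 8.0):
        params = DetectionParams(threshold_k=k)
        counts.append(len(detect_band_events(x, FS, params.ripple_band,
                                             params, event_type="ripple")))
    assert counts == sorted(counts, reverse=True)


def test_detected_intervals_inside_signal_and_disjoint(noise_60s):
    x = noise_60s.copy()
    rng = np.random.default_rng(5)
    for _ in range(30):
        b = _burst(rng.uniform(100, 240), 8, 200.0)
        i0 = int(rng.uniform(0, len(x) - len(b)))
        x[i0:i0 + len(b)] += b
    events = detect_band_events(x, FS, (80.0, 250.0), event_type="ripple")
    assert events, "expected some detections"
    last_end = 0.0
    for ev in sorted(events, key=lambda e: e.start):
        assert 0.0 <= ev.start < ev.end <= len(x) / FS
        assert ev.start >= last_end
        last_end = ev.end


def _ev(start, end, etype="ripple"):
    return EventRecord("c1", etype, start, end, 10.0, 6)


def test_cooccurrence_partition_and_boundary():
    spikes = [_ev(10.0, 10.1, "IES")]
    ripples = [
        _ev(10.02, 10.06),            # inside the spike interval
        _ev(11.5, 11.55),             # 1.4 s away -> isolated
        _ev(10.15, 10.20),            # starts exactly at end + 50 ms
        _ev(10.149, 10.20),           # 1 ms inside the dilated window
    ]
    cooc, isolated = classify_cooccurrence(ripples, spikes)
    assert {round(r.start, 3) for r in cooc} == {10.02, 10.149}
    assert {round(r.start, 3) for r in isolated} == {11.5, 10.15}
    assert len(cooc) + len(isolated) == len(ripples)
    assert all(r.event_type == "IES_ripple" for r in cooc)
    assert all(r.event_type == "ripple" for r in isolated)
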