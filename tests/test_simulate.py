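"""Synthetic-cohort generator: structure, determinism, count statistics."""
import numpy as np
import pytest
from scipy import stats as sstats

from hfoasym.config import SimulationConfig
from hfoasym.rates import build_cohort_table
from hfoasym.simulate import (PatientSpec, _hfo_burst, generate_cohort,
                              simulate_rate_table, simulate_recording)
from hfoasym.types import ChannelInfo


def test_cohort_structure_matches_config():
    cfg = SimulationConfig(seed=0)
    cohort = generate_cohort(cfg)
    assert len(cohort) == 16
    assert sorted(s.group for s in cohort) == [1] * 5 + [2] * 7 + [3] * 4
    hip = sum(1 for s in cohort for c in s.channels if c.lesion == "hippocampal")
    neo = sum(1 for s in cohort for c in s.channels if c.lesion == "neocortical")
    assert (hip, neo) == cfg.cohort_channel_totals
    # every patient records from both lesions
    for s in cohort:
        lesions = {c.lesion for c in s.channels}
        assert lesions == {"hippocampal", "neocortical"}


def test_soz_flags_follow_group_definition():
    for spec in generate_cohort(SimulationConfig(seed=3)):
        soz_lesions = {c.lesion for c in spec.channels if c.soz}
        expected = {1: {"hippocampal"}, 2: {"hippocampal", "neocortical"},
                    3: {"neocortical"}}[spec.group]
        assert soz_lesions == expected


def test_generate_cohort_deterministic():
    a = generate_cohort(SimulationConfig(seed=5))
    b = generate_cohort(SimulationConfig(seed=5))
    for sa, sb in zip(a, b):
        assert sa.true_rates == sb.true_rates
        assert sa.channels == sb.channels


def test_zero_asymmetry_gives_equal_fastripple_means():
    cfg = SimulationConfig(seed=1, fastripple_asymmetry_by_group=(0.0, 0.0, 0.0))
    for spec in generate_cohort(cfg):
        h, n = spec.lesion_means["fast_ripple"]
        assert h == pytest.approx(n)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="group_counts"):
        SimulationConfig(group_counts=(5, 7, 5)).validate()
    with pytest.raises(ValueError, match="negative rate"):
        SimulationConfig(
            event_rate_params={"IES": (-1.0, 1.0), "ripple": (1, 1),
                               "IES_ripple": (1, 1), "fast_ripple": (1, 1)}
        ).validate()
    with pytest.raises(ValueError, match="Nyquist|sampling"):
        SimulationConfig(sampling_rate=800.0).validate()
    with pytest.raises(ValueError, match=r"\[-1, 1\]"):
        SimulationConfig(fastripple_asymmetry_by_group=(1.5, 0, 0)).validate()


def _single_channel_spec(rates):
    ch = ChannelInfo("P01-H1", "hippocampal", True)
    return PatientSpec("P01", 1, [ch], {"P01-H1": rates},
                       {t: (r, r) for t, r in rates.items()})


_ZERO = {"IES": 0.0, "ripple": 0.0, "IES_ripple": 0.0, "fast_ripple": 0.0}


def test_zero_rates_give_pure_background():
    cfg = SimulationConfig(n_patients=1, group_counts=(1, 0, 0),
                           cohort_channel_totals=(1, 1),
                           segment_duration=30.0, seed=2)
    rec = simulate_recording(_single_channel_spec(_ZERO), cfg)
    assert rec.ground_truth == []
    assert rec.signals.shape == (1, 60_000)
    assert rec.signals.std() == pytest.approx(25.0, rel=0.05)


def test_recording_deterministic_and_events_within_segment():
    cfg = SimulationConfig(n_patients=1, group_counts=(1, 0, 0),
                           cohort_channel_totals=(1, 1),
                           segment_duration=60.0, seed=9)
    spec = _single_channel_spec({**_ZERO, "fast_ripple": 3.0, "IES": 4.0})
    rec1 = simulate_recording(spec, cfg)
    rec2 = simulate_recording(spec, cfg)
    assert np.array_equal(rec1.signals, rec2.signals)
    assert len(rec1.ground_truth) > 0
    for ev in rec1.ground_truth:
        assert ev.onset + ev.duration <= cfg.segment_duration
    # same-type events never overlap
    by_type = {}
    for ev in rec1.ground_truth:
        by_type.setdefault(ev.event_type, []).append((ev.onset, ev.end))
    for ivs in by_type.values():
        ivs.sort()
        for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
            assert s2 >= e1


def test_overfull_channel_rejected_with_channel_name():
    cfg = SimulationConfig(n_patients=1, group_counts=(1, 0, 0),
                           cohort_channel_totals=(1, 1),
                           segment_duration=20.0, seed=4)
    spec = _single_channel_spec({**_ZERO, "IES": 600.0})
    with pytest.raises(ValueError, match="P01-H1"):
        simulate_recording(spec, cfg)


def test_injected_event_counts_are_poisson():
    """Counts of injected fast ripples over repeated 60 s simulations follow
    Poisson(rate x duration): mean within 3 SE and chi-square GoF at 1%."""
    lam = 2.0  # 2/min for 1 minute
    cfg = SimulationConfig(n_patients=1, group_counts=(1, 0, 0),
                           cohort_channel_totals=(1, 1),
                           segment_duration=60.0)
    counts = []
    for seed in range(250):
        cfg.seed = seed
        spec = _single_channel_spec({**_ZERO, "fast_ripple": lam})
        counts.append(len(simulate_recording(spec, cfg).ground_truth))
    counts = np.asarray(counts)
    se = np.sqrt(lam / len(counts))
    assert abs(counts.mean() - lam) < 3 * se
    edges = [0, 1, 2, 3, 4, np.inf]
    obs = np.array([((counts >= lo) & (counts < hi)).sum()
                    for lo, hi in zip(edges, edges[1:])], dtype=float)
    pk = np.array([sstats.poisson.pmf(k, lam) for k in range(4)])
    expected = np.append(pk, 1 - pk.sum()) * len(counts)
    chi2 = ((obs - expected) ** 2 / expected).sum()
    assert chi2 < sstats.chi2.ppf(0.99, df=len(obs) - 1)


@pytest.mark.parametrize("band", [(80.0, 250.0), (250.0, 500.0)])
def test_injected_hfo_energy_inside_band(band):
    """At least 99% of every injected burst's energy lies in its band."""
    rng = np.random.default_rng(7)
    fs = 2000.0
    for _ in range(200):
        wave, _, f = _hfo_burst(fs, band, 150.0, rng)
        assert band[0] <= f <= band[1]
        spec = np.abs(np.fft.rfft(wave, n=8192)) ** 2
        freqs = np.fft.rfftfreq(8192, 1 / fs)
        inband = spec[(freqs >= band[0]) & (freqs <= band[1])].sum()
        assert inband / spec.sum() >= 0.99


def test_rate_table_zero_rates_and_determinism():
    cfg = SimulationConfig(
        seed=8,
        event_rate_params={t: (0.0, 0.0) for t in
                           ("IES", "ripple", "IES_ripple", "fast_ripple")},
        fastripple_asymmetry_by_group=(0.0, 0.0, 0.0),
    )
    rates, groups = simulate_rate_table(cfg)
    assert (rates[["rate_ies", "rate_ripple", "rate_ies_ripple",
                   "rate_fr"]].to_numpy() == 0).all()
    assert groups["group"].value_counts().sort_index().tolist() == [5, 7, 4]
    again, _ = simulate_rate_table(cfg)
    assert rates.equals(again)


def test_strong_asymmetry_gradient_yields_negative_correlation():
    cfg = SimulationConfig(seed=21,
                           fastripple_asymmetry_by_group=(0.8, 0.0, -0.8))
    cohort = build_cohort_table(*simulate_rate_table(cfg))
    rho = sstats.spearmanr(cohort["true_group"], cohort["r_fr"]).statistic
    assert rho < 0


def test_asymmetry_recovery_calibration():
    """Mean realized R per group over 100 cohorts is within 0.05 of the
    configured (0.6, 0.1, -0.3) asymmetries."""
    sums = {1: [], 2: [], 3: []}
    for seed in range(100):
        cohort = build_cohort_table(
            *simulate_rate_table(SimulationConfig(seed=seed)))
        for g in (1, 2, 3):
            sums[g].extend(cohort.loc[cohort.true_group == g, "r_fr"])
    for g, target in zip((1, 2, 3), (0.6, 0.1, -0.3)):
        assert abs(np.mean(sums[g]) - target) < 0.05
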