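"""Spectral metrics: periodogram contract, band powers, respiratory SNR."""

import numpy as np
import pytest

import imubreath as ib
from imubreath.spectral import DegenerateSignalError, SegmentTooShortError

FS = 10.0


def _sine(freq, duration=300.0, fs=FS, amp=1.0):
    t = np.arange(0, duration, 1 / fs)
    return amp * np.sin(2 * np.pi * freq * t)


def _signal(values, fs=FS):
    t = np.arange(len(values)) / fs
    return ib.BreathingSignal(timestamps=t, values=values)


def _brute_force_band(x, fs, lo, hi, window="hann", max_df=0.005):
    """Independent oracle: direct DFT summation over [lo, hi)."""
    x = np.asarray(x, float)
    n = len(x)
    w = np.hanning(n) if window == "hann" else np.ones(n)
    y = w * (x - x.mean())
    nfft = max(n, int(np.ceil(fs / max_df)))
    total = 0.0
    norm = nfft * np.sum(w**2)
    for k in range(nfft // 2 + 1):
        f = k * fs / nfft
        if lo <= f < hi:
            c = np.sum(y * np.exp(-2j * np.pi * k * np.arange(n) / nfft))
            d = 1.0 if k in (0, nfft // 2) and nfft % 2 == 0 or k == 0 else 2.0
            total += d * abs(c) ** 2 / norm
    return total


# ---------------------------------------------------------------- spectrum

def test_total_power_matches_variance():
    rng = np.random.default_rng(0)
    x = _sine(0.1) + 0.3 * rng.standard_normal(3000)
    spec = ib.compute_spectrum(x, sampling_rate=FS)
    assert spec.total_power == pytest.approx(x.var(), rel=0.05)


def test_constant_signal_has_no_nondc_power():
    spec = ib.compute_spectrum(np.full(1000, 3.7), sampling_rate=FS)
    assert spec.total_power == pytest.approx(0.0, abs=1e-20)


def test_sine_power_concentrates_in_recommended_band():
    """300 s 0.1 Hz sine: < 5% of total power outside 0.09-0.11 Hz."""
    spec = ib.compute_spectrum(_sine(0.1), sampling_rate=FS)
    inband = ib.band_power(spec, 0.09, 0.11)
    assert inband / spec.total_power > 0.95


def test_equal_amplitude_sines_have_equal_band_powers():
    x = _sine(0.1) + _sine(0.2)
    spec = ib.compute_spectrum(x, sampling_rate=FS)
    p1 = ib.band_power(spec, 0.09, 0.11)
    p2 = ib.band_power(spec, 0.19, 0.21)
    assert p1 == pytest.approx(p2, rel=0.05)


def test_grid_never_coarser_than_5_mHz():
    spec = ib.compute_spectrum(_sine(0.1, duration=60.0), sampling_rate=FS)
    assert np.max(np.diff(spec.frequencies)) <= 0.005 + 1e-12


def test_too_short_segment_raises_with_minimum_named():
    with pytest.raises(SegmentTooShortError, match="minimum"):
        ib.compute_spectrum(_sine(0.1, duration=10.0), sampling_rate=FS)


# ---------------------------------------------------------------- band power

def test_disjoint_cover_sums_to_total_power():
    rng = np.random.default_rng(1)
    spec = ib.compute_spectrum(rng.standard_normal(2000), sampling_rate=FS)
    edges = np.linspace(0.0, spec.nyquist, 11)
    parts = sum(ib.band_power(spec, lo, hi) for lo, hi in zip(edges[:-1], edges[1:]))
    parts += spec.power[spec.frequencies >= spec.nyquist].sum()   # the last bin
    assert parts == pytest.approx(float(spec.power.sum()), rel=1e-12)


def test_empty_band_has_zero_power():
    spec = ib.compute_spectrum(_sine(0.1, duration=60.0), sampling_rate=FS)
    df = spec.frequencies[1] - spec.frequencies[0]
    lo = spec.frequencies[10] + 0.1 * df
    assert ib.band_power(spec, lo, lo + 0.5 * df) == 0.0


def test_inverted_or_out_of_range_bounds_rejected():
    spec = ib.compute_spectrum(_sine(0.1, duration=60.0), sampling_rate=FS)
    with pytest.raises(ValueError):
        ib.band_power(spec, 0.2, 0.1)
    with pytest.raises(ValueError):
        ib.band_power(spec, 0.1, 2 * spec.nyquist)


@pytest.mark.parametrize("freqs", [(0.1,), (0.08, 0.21)])
def test_band_power_agrees_with_direct_dft_summation(freqs):
    """Oracle equivalence on <= 1024-sample signals, 1e-9 relative."""
    fs = 4.0
    x = sum(_sine(f, duration=256.0, fs=fs) for f in freqs)
    assert len(x) == 1024
    spec = ib.compute_spectrum(x, sampling_rate=fs)
    for lo, hi in [(0.05, 0.5), (0.09, 0.11), (0.0, 1.0)]:
        mine = ib.band_power(spec, lo, hi)
        oracle = _brute_force_band(x, fs, lo, hi)
        assert mine == pytest.approx(oracle, rel=1e-9, abs=1e-15)


# ---------------------------------------------------------------- slow bands

def test_fourteen_contiguous_slow_bands():
    edges = ib.slow_band_edges()
    assert len(edges) == 14
    assert edges[0][0] == pytest.approx(0.055)
    assert edges[-1][1] == pytest.approx(0.195)
    for (_, hi), (lo, _) in zip(edges[:-1], edges[1:]):
        assert hi == pytest.approx(lo)


def test_novice_baseline_peaks_in_topmost_slow_band(reference_model):
    """0.2 Hz-dominant spontaneous breathing: the 0.185-0.195 band is hottest."""
    cfg = ib.SimulationConfig(duration=300, breathing_freq=0.2, tilt_amplitude=5,
                              noise_sd=0.05, freq_jitter_sd=0.02, seed=8,
                              baseline_orientation=ib.default_mount_orientation())
    sig = ib.extract_breathing_signal(ib.simulate_breathing_trace(cfg), reference_model)
    table = ib.slow_band_powers(ib.compute_spectrum(sig))
    assert np.argmax(table.band_power) == 13


def test_white_noise_spreads_evenly_over_slow_bands():
    rng = np.random.default_rng(2)
    acc = np.zeros(14)
    for _ in range(100):
        spec = ib.compute_spectrum(rng.standard_normal(600), sampling_rate=FS)
        acc += ib.slow_band_powers(spec).band_power
    assert acc.max() / acc.min() < 3.0


# ---------------------------------------------------------------- SNR

def test_equal_power_in_band_and_off_band_gives_unit_snr():
    x = _sine(0.10) + _sine(0.15)
    res = ib.respiratory_snr(ib.compute_spectrum(x, sampling_rate=FS))
    assert res.snr == pytest.approx(1.0, rel=0.10)


def test_component_inside_exclusion_band_leaves_snr_unchanged():
    """A 0.04 Hz component sits below the 0.05 Hz edge and must not count."""
    rng = np.random.default_rng(3)
    dither = 0.01 * rng.standard_normal(3000)     # fixed noise floor
    base = _sine(0.10) + dither
    with_low = base + _sine(0.04)
    snr_a = ib.respiratory_snr(ib.compute_spectrum(base, sampling_rate=FS)).snr
    snr_b = ib.respiratory_snr(ib.compute_spectrum(with_low, sampling_rate=FS)).snr
    assert snr_b == pytest.approx(snr_a, rel=0.05)


def test_pure_recommended_sine_has_high_snr():
    res = ib.respiratory_snr(ib.compute_spectrum(_sine(0.10), sampling_rate=FS))
    assert res.snr > 20.0


def test_snr_monotonicity_in_added_power():
    rng = np.random.default_rng(4)
    base = _sine(0.10) + 0.05 * rng.standard_normal(3000)
    snr0 = ib.respiratory_snr(ib.compute_spectrum(base, sampling_rate=FS)).snr
    worse = ib.respiratory_snr(
        ib.compute_spectrum(base + _sine(0.15, amp=0.5), sampling_rate=FS)).snr
    better = ib.respiratory_snr(
        ib.compute_spectrum(base + _sine(0.10, amp=0.5), sampling_rate=FS)).snr
    assert worse < snr0 < better


def test_degenerate_denominator_raises():
    # all power inside the recommended band, none elsewhere: zero-ish noise
    spec = ib.PowerSpectrum(frequencies=np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5]),
                            power=np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0]))
    with pytest.raises(DegenerateSignalError):
        ib.respiratory_snr(spec)


def test_snr_beats_matched_off_target_simulation_at_all_noise_levels(reference_model):
    """Breathing at 0.1 Hz scores higher SNR than matched breathing at 0.13 Hz
    for every tested sensor-noise level up to 0.2 m/s^2."""
    for noise in (0.0, 0.1, 0.2):
        snrs = {}
        for freq in (0.10, 0.13):
            cfg = ib.SimulationConfig(duration=300, breathing_freq=freq,
                                      tilt_amplitude=6, noise_sd=noise, seed=13,
                                      baseline_orientation=ib.default_mount_orientation())
            sig = ib.extract_breathing_signal(
                ib.simulate_breathing_trace(cfg), reference_model)
            snrs[freq] = ib.respiratory_snr(ib.compute_spectrum(sig)).snr
        assert snrs[0.10] > snrs[0.13]


# ---------------------------------------------------------------- per minute

def test_stationary_signal_gives_five_stable_minutes():
    sig = _signal(_sine(0.1, duration=300.0))
    series = ib.per_minute_metrics(sig)
    assert len(series.snr) == 5 and len(series.recommended_power) == 5
    assert np.std(series.snr) / np.mean(series.snr) < 0.10


def test_frequency_switch_raises_later_minute_snr():
    x = np.concatenate([_sine(0.2, duration=60.0), _sine(0.1, duration=240.0)])
    series = ib.per_minute_metrics(_signal(x))
    assert series.snr[1] > series.snr[0]


def test_wrong_duration_rejected():
    with pytest.raises(ValueError, match="300"):
        ib.per_minute_metrics(_signal(_sine(0.1, duration=200.0)))


# ---------------------------------------------------------------- cohort

@pytest.fixture(scope="module")
def small_cohort():
    return ib.simulate_cohort(ib.default_group_specs(n_subjects=3), seed=17)


def test_cohort_training_block_beats_baseline(small_cohort, reference_model):
    df = ib.cohort_block_summary(small_cohort, reference_model)
    for group in ("pacing_only", "biofeedback"):
        g = df[df.group == group].set_index("block")
        assert g.loc["training", "snr_mean"] > g.loc["baseline", "snr_mean"]
        assert g.loc["training", "power_mean"] > g.loc["baseline", "power_mean"]


def test_missing_block_subject_is_warned_and_excluded(small_cohort, reference_model):
    partial = [t for t in small_cohort
               if not (t.metadata["subject"] == "pacing_only-s00"
                       and t.metadata["block"] == "post")]
    with pytest.warns(UserWarning, match="s00"):
        df = ib.cohort_block_summary(partial, reference_model)
    assert set(df.n) == {2, 3}


def test_single_subject_group_reports_sd_as_nan(reference_model):
    specs = ib.default_group_specs(n_subjects=1)[:1]
    traces = ib.simulate_cohort(specs, seed=23)
    df = ib.cohort_block_summary(traces, reference_model)
    assert df["snr_sd"].isna().all()
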