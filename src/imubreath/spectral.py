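"""Spectral outcome measures of breathing performance.

The estimator is a mean-removed, Hann-tapered periodogram, zero-padded when
necessary so the frequency grid is no coarser than 0.005 Hz (a 60 s segment
natively resolves only ~0.017 Hz, too coarse for the 0.02 Hz-wide recommended
band). Bins are normalized so that the non-DC bins sum to the signal variance
(Parseval, up to taper-dependent leakage of a few percent at segment edges).

Metrics built on it:

* band power -- sum of bins over a half-open interval [lo, hi), so contiguous
  bands partition the spectrum without double counting;
* the 14 slow-breathing band powers, 0.055-0.195 Hz in 0.01 Hz steps;
* power in the recommended band, 0.09-0.11 Hz, around the instructed 0.1 Hz;
* respiratory SNR -- recommended-band power over the power of the remaining
  breathing spectrum, excluding the DC offset (by mean removal), frequencies
  below 0.05 Hz (slow posture/baseline drift) and the recommended band
  itself; a compliance measure for paced breathing;
* per-minute trajectories over a 5-min block, and per-group, per-block cohort
  summary tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULTS
from .reference import BreathingSignal, FilterSpec, ReferenceModel, extract_breathing_signal
from .simulate import AccelTrace, STUDY_BLOCKS

__all__ = [
    "PowerSpectrum",
    "BandPowerTable",
    "SNRResult",
    "MinuteSeries",
    "SegmentTooShortError",
    "DegenerateSignalError",
    "compute_spectrum",
    "band_power",
    "slow_band_powers",
    "slow_band_edges",
    "respiratory_snr",
    "per_minute_metrics",
    "cohort_block_summary",
]


class SegmentTooShortError(ValueError):
    """Signal segment too short for a meaningful spectral estimate."""


class DegenerateSignalError(ValueError):
    """The SNR denominator is empty (no power outside the recommended band)."""


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray   # Hz, 0 .. Nyquist, strictly increasing
    power: np.ndarray         # non-negative, sums (excl. DC) ~ signal variance
    segment_start: float = 0.0
    segment_duration: float = 0.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def nyquist(self) -> float:
        return float(self.frequencies[-1])

    @property
    def total_power(self) -> float:
        """Total non-DC power (~ signal variance)."""
        return float(self.power[1:].sum())


@dataclass
class BandPowerTable:
    band_edges: list[tuple[float, float]]
    band_power: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "f_lo": [e[0] for e in self.band_edges],
            "f_hi": [e[1] for e in self.band_edges],
            "power": self.band_power,
        })


@dataclass
class SNRResult:
    recommended_power: float
    noise_power: float
    snr: float


@dataclass
class MinuteSeries:
    """One value per non-overlapping 60 s segment of a 5-min block."""

    recommended_power: np.ndarray   # (5,)
    snr: np.ndarray                 # (5,)


# Minimum segment: two cycles of the lowest slow-band edge.
_MIN_DURATION = 2.0 / DEFAULTS["slow_band_range"][0]


def compute_spectrum(signal: BreathingSignal | np.ndarray,
                     sampling_rate: float | None = None,
                     window: str = "hann",
                     max_df: float = DEFAULTS["spectrum_max_df"],
                     min_duration: float = _MIN_DURATION) -> PowerSpectrum:
    """Mean-removed tapered periodogram on a grid no coarser than ``max_df``.

    Accepts a BreathingSignal, or a plain array plus ``sampling_rate``.
    ``window`` is "hann" or "boxcar".
    """
    if isinstance(signal, BreathingSignal):
        x = signal.values
        fs = signal.sampling_rate
        start = float(signal.timestamps[0])
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for plain arrays")
        x = np.asarray(signal, dtype=float)
        fs = float(sampling_rate)
        start = 0.0
    n = len(x)
    duration = n / fs
    if duration < min_duration:
        raise SegmentTooShortError(
            f"segment of {duration:.1f} s is too short; minimum {min_duration:.1f} s "
            f"(two cycles of the lowest analysis band)")

    if window == "hann":
        w = np.hanning(n)
    elif window == "boxcar":
        w = np.ones(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    y = w * (x - x.mean())
    nfft = max(n, int(np.ceil(fs / max_df)))
    spec = np.fft.rfft(y, nfft)
    p = np.abs(spec) ** 2
    # One-sided doubling; normalize so sum over bins ~ variance (Parseval).
    d = np.full(len(p), 2.0)
    d[0] = 1.0
    if nfft % 2 == 0:
        d[-1] = 1.0
    power = d * p / (nfft * np.sum(w**2))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    return PowerSpectrum(frequencies=freqs, power=power,
                         segment_start=start, segment_duration=duration)


def band_power(spectrum: PowerSpectrum, lo: float, hi: float) -> float:
    """Sum of spectral power over bins with lo <= f < hi (half-open)."""
    if not 0.0 <= lo < hi:
        raise ValueError(f"need 0 <= lo < hi, got ({lo}, {hi})")
    if hi > spectrum.nyquist * (1.0 + 1e-12):
        raise ValueError(f"hi={hi} exceeds the Nyquist frequency {spectrum.nyquist}")
    mask = (spectrum.frequencies >= lo) & (spectrum.frequencies < hi)
    return float(spectrum.power[mask].sum())


def slow_band_edges(lo: float = DEFAULTS["slow_band_range"][0],
                    hi: float = DEFAULTS["slow_band_range"][1],
                    width: float = DEFAULTS["slow_band_width"]
                    ) -> list[tuple[float, float]]:
    """Contiguous slow-breathing bands: 0.055-0.195 Hz in 0.01 Hz steps (14 bands)."""
    n = int(round((hi - lo) / width))
    return [(lo + k * width, lo + (k + 1) * width) for k in range(n)]


def slow_band_powers(spectrum: PowerSpectrum) -> BandPowerTable:
    """Power in each of the 14 slow-breathing frequency bands."""
    edges = slow_band_edges()
    powers = np.array([band_power(spectrum, lo, hi) for lo, hi in edges])
    return BandPowerTable(band_edges=edges, band_power=powers)


def respiratory_snr(spectrum: PowerSpectrum,
                    f_max: float = DEFAULTS["snr_f_max"],
                    recommended: tuple[float, float] = DEFAULTS["recommended_band"],
                    exclusion: float = DEFAULTS["snr_exclusion"]) -> SNRResult:
    """Recommended-band power over the rest of the breathing spectrum.

    numerator = power in [0.09, 0.11); denominator = power in
    [exclusion, f_max) minus the numerator band. DC is excluded by the mean
    removal of the spectral estimate; frequencies below ``exclusion``
    (default 0.05 Hz) are dropped to remove slow non-respiratory fluctuations.
    """
    lo, hi = recommended
    if f_max <= hi:
        raise ValueError(f"f_max={f_max} must lie above the recommended band edge {hi}")
    recommended_power = band_power(spectrum, lo, hi)
    noise_power = band_power(spectrum, exclusion, f_max) - band_power(spectrum, lo, hi)
    if noise_power <= 0.0:
        raise DegenerateSignalError(
            "no spectral power outside the recommended band; SNR undefined")
    return SNRResult(recommended_power=recommended_power, noise_power=noise_power,
                     snr=recommended_power / noise_power)


def per_minute_metrics(signal: BreathingSignal, segment_duration: float = 60.0,
                       n_segments: int = 5, **snr_kwargs) -> MinuteSeries:
    """Recommended-band power and SNR per non-overlapping minute of a 5-min block."""
    fs = signal.sampling_rate
    seg_len = int(round(segment_duration * fs))
    expected = seg_len * n_segments
    if abs(len(signal) - expected) > 1:
        raise ValueError(
            f"expected a {segment_duration * n_segments:.0f} s signal "
            f"({expected} samples at {fs:g} Hz, tolerance one sample); got {len(signal)}")
    rec, snrs = [], []
    for k in range(n_segments):
        seg = slice(k * seg_len, (k + 1) * seg_len)
        spec = compute_spectrum(signal.values[seg], sampling_rate=fs)
        res = respiratory_snr(spec, **snr_kwargs)
        rec.append(res.recommended_power)
        snrs.append(res.snr)
    return MinuteSeries(recommended_power=np.array(rec), snr=np.array(snrs))


def cohort_block_summary(traces: Iterable[AccelTrace], model: ReferenceModel,
                         filter_spec: FilterSpec = FilterSpec(),
                         blocks: Sequence[str] = STUDY_BLOCKS,
                         **snr_kwargs) -> pd.DataFrame:
    """Per-group, per-block mean and SD of recommended-band power and SNR.

    Runs the full extraction pipeline per subject-block trace, then aggregates
    by (group, block). Subjects missing any required block are excluded from
    the whole summary (block comparisons are paired) with a warning naming
    them. Groups with a single subject report SD as NaN.
    """
    rows = []
    by_subject: dict[tuple[str, str], set[str]] = {}
    for trace in traces:
        meta = trace.metadata
        key = (meta.get("group", "?"), meta.get("subject", "?"))
        by_subject.setdefault(key, set()).add(meta.get("block", "?"))
        signal = extract_breathing_signal(trace, model, filter_spec)
        spec = compute_spectrum(signal)
        res = respiratory_snr(spec, **snr_kwargs)
        rows.append({
            "group": key[0], "subject": key[1], "block": meta.get("block", "?"),
            "recommended_power": res.recommended_power, "snr": res.snr,
        })
    incomplete = sorted(subj for (grp, subj), got in by_subject.items()
                        if not set(blocks) <= got)
    if incomplete:
        warnings.warn(
            f"subjects missing required blocks excluded from summary: {incomplete}",
            stacklevel=2)
    df = pd.DataFrame(rows)
    df = df[~df["subject"].isin(incomplete)]
    if df.empty:
        raise ValueError("no complete subjects to summarize")
    summary = (
        df.groupby(["group", "block"], sort=False)
        .agg(n=("subject", "size"),
             power_mean=("recommended_power", "mean"),
             power_sd=("recommended_power", lambda v: v.std(ddof=1)),
             snr_mean=("snr", "mean"),
             snr_sd=("snr", lambda v: v.std(ddof=1)))
        .reset_index()
    )
    # Order blocks in protocol order for readability.
    order = {b: i for i, b in enumerate(blocks)}
    summary = summary.sort_values(
        ["group", "block"], key=lambda c: c.map(order).fillna(99) if c.name == "block" else c
    ).reset_index(drop=True)
    return summary
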