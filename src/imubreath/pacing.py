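"""Paced-breathing instruction waveform and target-vs-actual deviation.

The instructed pattern is a sine at the recommended slow-breathing rate
(default 0.1 Hz, 6 cycles/min), started at the trough so the first
instruction is an inhale. Each sample carries the phase label (inhale while
the target rises, exhale while it falls) and a count 1-4 that divides each
half-cycle into four equal sub-intervals -- at 0.1 Hz, 1.25 s per count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULTS
from .reference import BreathingSignal

__all__ = ["PacingWaveform", "generate_pacing", "tracking_deviation", "NoOverlapError"]


class NoOverlapError(ValueError):
    """Signal and pacing waveform share no time range."""


@dataclass
class PacingWaveform:
    timestamps: np.ndarray   # s
    target: np.ndarray       # dimensionless, in [-1, 1]
    phase: np.ndarray        # "inhale" / "exhale" per sample
    count: np.ndarray        # int 1..4 per sample
    freq: float              # Hz

    def __len__(self) -> int:
        return len(self.timestamps)


def generate_pacing(duration: float, freq: float = DEFAULTS["pacing_freq"],
                    sampling_rate: float = DEFAULTS["sampling_rate"]) -> PacingWaveform:
    """Generate the instructed sine target with phase and count annotations.

    target(t) = sin(2 pi f t - pi/2): each cycle starts at the trough (-1,
    inhale onset) and peaks at the half period (inhale -> exhale boundary).
    """
    if duration <= 0 or freq <= 0 or sampling_rate <= 0:
        raise ValueError("duration, freq and sampling_rate must be > 0")
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    target = np.sin(2.0 * np.pi * freq * t - np.pi / 2.0)

    cycle_pos = (freq * t) % 1.0                    # position within cycle, [0, 1)
    inhale = cycle_pos < 0.5                        # rising half
    phase = np.where(inhale, "inhale", "exhale")
    half_frac = (cycle_pos % 0.5) / 0.5             # position within half-cycle
    count = np.minimum(4, 1 + np.floor(4.0 * half_frac).astype(int))
    return PacingWaveform(timestamps=t, target=target, phase=phase,
                          count=count, freq=freq)


def tracking_deviation(signal: BreathingSignal, pacing: PacingWaveform
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """Pointwise target minus actual on the overlapping time range.

    The target is resampled onto the signal's timestamps by linear
    interpolation. Returns (timestamps, error, rms).
    """
    t0 = max(signal.timestamps[0], pacing.timestamps[0])
    t1 = min(signal.timestamps[-1], pacing.timestamps[-1])
    if t1 <= t0:
        raise NoOverlapError("signal and pacing waveform do not overlap in time")
    mask = (signal.timestamps >= t0) & (signal.timestamps <= t1)
    t = signal.timestamps[mask]
    target = np.interp(t, pacing.timestamps, pacing.target)
    error = target - signal.values[mask]
    rms = float(np.sqrt(np.mean(error**2)))
    return t, error, rms
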