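"""Central defaults and run configuration.

Every constant of the published method lives here, in one table, so the math
modules never hard-code them: the paced-breathing rate (0.1 Hz, i.e.
6 cycles/min), the RC low-pass cutoff (0.5 Hz), the traffic-light thresholds
(green below 5 deg, orange below 15 deg) and dwell time (5 s), the recommended
breathing band (0.09-0.11 Hz), the slow-breathing analysis bands
(0.055-0.195 Hz in 0.01 Hz steps) and the low-frequency exclusion edge of the
respiratory SNR denominator (0.05 Hz).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

logger = logging.getLogger("imubreath")

#: Canonical method constants. Units in the comments.
DEFAULTS: dict[str, Any] = {
    "sampling_rate": 50.0,        # Hz; typical phone accelerometer rate
    "gravity_magnitude": 9.81,    # m/s^2
    "pacing_freq": 0.1,           # Hz; 6 cycles/min paced breathing target
    "filter_cutoff": 0.5,         # Hz; RC low-pass -3 dB point
    "green_deg": 5.0,             # deg; green traffic-light threshold (strict <)
    "orange_deg": 15.0,           # deg; orange threshold (strict <), red otherwise
    "dwell_s": 5.0,               # s; required continuous both-green dwell
    "recommended_band": (0.09, 0.11),   # Hz; instructed-frequency band
    "slow_band_range": (0.055, 0.195),  # Hz; slow-breathing analysis range
    "slow_band_width": 0.01,      # Hz; width of each slow band (14 bands)
    "snr_exclusion": 0.05,        # Hz; SNR denominator excludes [0, 0.05)
    "snr_f_max": 0.5,             # Hz; upper edge of the breathing spectrum
    "block_duration": 300.0,      # s; one 5-min measurement block
    "block_names": ("baseline", "training", "post"),
    "spectrum_max_df": 0.005,     # Hz; max spectral grid spacing (zero-padding)
}


def setup_logging(verbose: bool = False) -> None:
    """Configure the package logger for CLI runs."""
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)


@dataclass
class RunConfig:
    """Configuration for a full study-protocol run.

    Unknown keys are rejected on load so that typos in a config file cannot
    silently fall back to defaults.
    """

    out_dir: str = "run"
    seed: int = 0
    verbose: bool = False
    sampling_rate: float = DEFAULTS["sampling_rate"]
    gravity_magnitude: float = DEFAULTS["gravity_magnitude"]
    pacing_freq: float = DEFAULTS["pacing_freq"]
    filter_cutoff: float = DEFAULTS["filter_cutoff"]
    green_deg: float = DEFAULTS["green_deg"]
    orange_deg: float = DEFAULTS["orange_deg"]
    dwell_s: float = DEFAULTS["dwell_s"]
    recommended_band: tuple[float, float] = DEFAULTS["recommended_band"]
    snr_exclusion: float = DEFAULTS["snr_exclusion"]
    snr_f_max: float = DEFAULTS["snr_f_max"]
    block_duration: float = DEFAULTS["block_duration"]
    block_names: tuple[str, ...] = DEFAULTS["block_names"]
    spectrum_max_df: float = DEFAULTS["spectrum_max_df"]
    #: optional per-block simulation overrides, keyed by block name
    block_overrides: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("recommended_band", "block_names"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["recommended_band"] = list(self.recommended_band)
        d["block_names"] = list(self.block_names)
        return d
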