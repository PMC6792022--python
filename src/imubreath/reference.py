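"""Reference-model fitting and live breathing-signal extraction.

Fitting: accelerometer samples from trained-breather trials are pooled and
mean-centred; the first principal component of the pooled cloud is the major
dispersion direction -- the axis along which breathing moves the measurement
most. The pooled mean is the reference vector used by the positioning
procedure. Projecting each person's samples onto the principal direction and
averaging the per-person minima and maxima gives the reference range that deep
abdominal breathing is expected to span.

Extraction: each axis of the live trace is passed through a first-order RC
low-pass (single-pole IIR, cutoff 0.5 Hz) to suppress sensor noise, the
filtered vector is projected onto the principal direction by scalar product,
and the projection is affinely mapped so the reference range covers (-1, 1).

Sign convention: a principal component is defined only up to sign. The fitted
direction is oriented to have a non-negative component along the sensor
x-axis, falling back to y then z on exact zeros, so extraction polarity is
reproducible across fits. Which polarity is inhalation is a display choice,
not a property of the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .config import DEFAULTS
from .simulate import AccelTrace

__all__ = [
    "ReferenceModel",
    "BreathingSignal",
    "FilterSpec",
    "FitError",
    "fit_reference_model",
    "rc_lowpass",
    "project_trace",
    "extract_breathing_signal",
]


class FitError(ValueError):
    """Raised when the reference model cannot be fitted from the given trials."""


class NonUniformSamplingError(ValueError):
    """Raised when a trace's timestamps deviate from a uniform grid."""


@dataclass(frozen=True)
class FilterSpec:
    """Single-pole RC low-pass specification."""

    cutoff: float = DEFAULTS["filter_cutoff"]  # Hz, -3 dB point

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")

    def alpha(self, dt: float) -> float:
        """Smoothing coefficient of y[n] = y[n-1] + alpha (x[n] - y[n-1]).

        The analog RC pole is mapped exactly: alpha = 1 - exp(-dt/RC),
        RC = 1/(2 pi cutoff). This keeps the discrete -3 dB point at the
        designed cutoff; the first-order Euler form dt/(RC + dt) (identical
        for dt << RC) realizes its -3 dB point ~2% low at 50 Hz sampling.
        """
        rc = 1.0 / (2.0 * np.pi * self.cutoff)
        return 1.0 - np.exp(-dt / rc)


@dataclass
class ReferenceModel:
    principal_direction: np.ndarray   # unit 3-vector, sensor frame
    reference_vector: np.ndarray      # 3-vector, m/s^2 (pooled mean)
    ref_min: float                    # m/s^2, averaged per-person min projection
    ref_max: float                    # m/s^2, averaged per-person max projection
    provenance: dict | None = None

    def __post_init__(self) -> None:
        self.principal_direction = np.asarray(self.principal_direction, dtype=float)
        self.reference_vector = np.asarray(self.reference_vector, dtype=float)
        if abs(np.linalg.norm(self.principal_direction) - 1.0) > 1e-9:
            raise ValueError("principal_direction must be a unit vector (within 1e-9)")
        if not self.ref_min < self.ref_max:
            raise ValueError("ref_min must be strictly below ref_max")

    def to_dict(self) -> dict:
        return {
            "principal_direction": self.principal_direction.tolist(),
            "reference_vector": self.reference_vector.tolist(),
            "ref_min": self.ref_min,
            "ref_max": self.ref_max,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceModel":
        return cls(
            principal_direction=np.asarray(d["principal_direction"], dtype=float),
            reference_vector=np.asarray(d["reference_vector"], dtype=float),
            ref_min=float(d["ref_min"]),
            ref_max=float(d["ref_max"]),
            provenance=d.get("provenance"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class BreathingSignal:
    """Scaled 1-D breathing displacement; the reference range maps to (-1, 1)."""

    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("breathing signal contains non-finite values")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    @property
    def duration(self) -> float:
        return float(len(self.values) / self.sampling_rate)

    def __len__(self) -> int:
        return len(self.values)


def _orient_sign(u: np.ndarray) -> np.ndarray:
    """Fix PCA sign ambiguity: non-negative dot with x, falling back to y, z."""
    for k in range(3):
        if abs(u[k]) > 1e-12:
            return u if u[k] > 0 else -u
    return u


def fit_reference_model(
    pretest_traces: Mapping[str, Sequence[AccelTrace]] | Sequence[Sequence[AccelTrace]],
    extrema_percentile: float | None = None,
) -> ReferenceModel:
    """Fit the reference model from trained-breather trials grouped by person.

    All samples from all persons and trials are pooled for one PCA; the
    projection extrema are taken per person (over that person's pooled trials)
    and averaged across persons. ``extrema_percentile`` optionally replaces
    the raw min/max with the (q, 100-q) percentiles for noisy recordings;
    the default uses the raw extrema.
    """
    if isinstance(pretest_traces, Mapping):
        groups: list[Sequence[AccelTrace]] = list(pretest_traces.values())
        names = list(pretest_traces.keys())
    else:
        groups = list(pretest_traces)
        names = [f"person-{i}" for i in range(len(groups))]
    if not groups or any(len(g) == 0 for g in groups):
        raise FitError("need at least one person, each with at least one trace")
    for g in groups:
        for tr in g:
            if len(tr) < 2:
                raise FitError("each trace needs at least 2 samples")

    pooled = np.vstack([tr.samples for g in groups for tr in g])
    mean = pooled.mean(axis=0)
    centred = pooled - mean
    if np.allclose(centred, 0.0):
        raise FitError("degenerate dispersion: all samples identical")
    # First right singular vector of the centred cloud = first principal axis.
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = _orient_sign(vt[0] / np.linalg.norm(vt[0]))

    mins, maxs = [], []
    for g in groups:
        proj = np.concatenate([tr.samples @ direction for tr in g])
        if extrema_percentile is not None:
            lo, hi = np.percentile(proj, [extrema_percentile, 100.0 - extrema_percentile])
        else:
            lo, hi = proj.min(), proj.max()
        mins.append(lo)
        maxs.append(hi)
    ref_min = float(np.mean(mins))
    ref_max = float(np.mean(maxs))
    if not ref_min < ref_max:
        raise FitError("degenerate reference range: ref_min == ref_max")

    return ReferenceModel(
        principal_direction=direction,
        reference_vector=mean,
        ref_min=ref_min,
        ref_max=ref_max,
        provenance={
            "n_persons": len(groups),
            "persons": names,
            "n_samples": int(len(pooled)),
            "extrema_percentile": extrema_percentile,
        },
    )


def _check_uniform(timestamps: np.ndarray) -> float:
    dts = np.diff(timestamps)
    dt = float(np.median(dts))
    if np.any(np.abs(dts - dt) > 0.01 * dt):
        raise NonUniformSamplingError(
            "timestamps deviate from a uniform grid by more than 1% of dt")
    return dt


def rc_lowpass(trace: AccelTrace, spec: FilterSpec = FilterSpec()) -> AccelTrace:
    """Apply the single-pole RC low-pass per axis.

    Recursion y[n] = y[n-1] + alpha (x[n] - y[n-1]) with the pole-mapped
    coefficient (see FilterSpec.alpha); the state starts at the first sample
    (no start-up transient from zero).
    """
    dt = _check_uniform(trace.timestamps)
    a = spec.alpha(dt)
    x = trace.samples
    # lfilter with b=[a], a=[1, -(1-a)]; zi chosen so that y[0] == x[0].
    zi = (1.0 - a) * x[0][None, :]
    y, _ = lfilter([a], [1.0, -(1.0 - a)], x, axis=0, zi=zi)
    return AccelTrace(timestamps=trace.timestamps.copy(), samples=y,
                      metadata={**trace.metadata, "filtered_cutoff": spec.cutoff})


def project_trace(trace: AccelTrace, model: ReferenceModel) -> np.ndarray:
    """Scalar projection of each sample onto the principal direction (m/s^2)."""
    return trace.samples @ model.principal_direction


def extract_breathing_signal(trace: AccelTrace, model: ReferenceModel,
                             spec: FilterSpec = FilterSpec()) -> BreathingSignal:
    """Filter, project, and scale a raw trace into the biofeedback signal.

    value(t) = 2 (p(t) - ref_min) / (ref_max - ref_min) - 1 where p(t) is the
    projection of the RC-filtered sample onto the principal direction, so the
    reference range maps onto (-1, 1); excursions outside are permitted.
    The filter runs before the projection, though the two commute because the
    filter acts per-axis with identical coefficients and projection is linear.
    """
    filtered = rc_lowpass(trace, spec)
    p = project_trace(filtered, model)
    values = 2.0 * (p - model.ref_min) / (model.ref_max - model.ref_min) - 1.0
    return BreathingSignal(timestamps=trace.timestamps.copy(), values=values)
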