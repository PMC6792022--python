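"""Interactive sensor-positioning procedure with traffic-light feedback.

The phone is held still while being positioned, so the accelerometer reads
(mostly) gravity. Alignment quality is the angle between the live vector and
a reference vector recorded from correctly positioned trials, measured
separately in the sensor's xy- and xz-planes: each vector is orthogonally
projected onto the plane and the unsigned angle between the projections is
taken via the normalized scalar product. Each plane's deviation is classified
green (< 5 deg), orange (< 15 deg) or red; positioning succeeds once both
planes have been green continuously for 5 s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import DEFAULTS
from .simulate import AccelTrace

__all__ = [
    "ReferenceVector",
    "PlaneDeviation",
    "TrafficLight",
    "CalibrationSession",
    "DegenerateProjectionError",
    "plane_angle",
    "classify_traffic_light",
    "step_calibration",
    "run_calibration",
]

_PLANE_AXES = {"xy": (0, 1), "xz": (0, 2)}


class DegenerateProjectionError(ValueError):
    """The vector's projection onto the requested plane is (near) zero.

    Signals that the sensor is oriented so the plane carries no directional
    information (e.g. the vector is normal to the plane).
    """


@dataclass(frozen=True)
class ReferenceVector:
    """Reference accelerometer vector (sensor frame, m/s^2)."""

    vector: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if v.shape != (3,) or not np.all(np.isfinite(v)):
            raise ValueError("reference vector must be a finite 3-vector")
        if np.linalg.norm(v) == 0.0:
            raise ValueError("reference vector must be non-zero")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vector, dtype=float)


@dataclass(frozen=True)
class PlaneDeviation:
    """Unsigned in-plane angle deviations, degrees in [0, 180]."""

    xy_deg: float
    xz_deg: float

    def __post_init__(self) -> None:
        for a in (self.xy_deg, self.xz_deg):
            if not np.isfinite(a) or a < 0:
                raise ValueError("plane deviations must be finite and non-negative")


@dataclass(frozen=True)
class TrafficLight:
    xy_color: str
    xz_color: str
    both_green: bool


@dataclass(frozen=True)
class CalibrationSession:
    """Dwell-timer state of the positioning procedure. Success is latched."""

    green_dwell_elapsed: float = 0.0
    required_dwell: float = DEFAULTS["dwell_s"]
    success: bool = False


def plane_angle(measured, reference, plane: str) -> float:
    """Angle (deg) between two vectors' orthogonal projections onto a sensor plane.

    Computed as arccos of the normalized scalar product of the projections;
    unsigned, in [0, 180]. ``plane`` is ``"xy"`` or ``"xz"``.
    """
    try:
        i, j = _PLANE_AXES[plane]
    except KeyError:
        raise ValueError(f"unknown plane {plane!r}; expected 'xy' or 'xz'") from None
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    if np.linalg.norm(m) == 0.0 or np.linalg.norm(r) == 0.0:
        raise ValueError("vectors must be non-zero")
    pm = m[[i, j]]
    pr = r[[i, j]]
    for proj, full in ((pm, m), (pr, r)):
        if np.linalg.norm(proj) < 1e-6 * np.linalg.norm(full):
            raise DegenerateProjectionError(
                f"projection onto the {plane}-plane is degenerate "
                f"(norm < 1e-6 of the vector norm)")
    cosang = np.dot(pm, pr) / (np.linalg.norm(pm) * np.linalg.norm(pr))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def classify_traffic_light(dev: PlaneDeviation,
                           green_deg: float = DEFAULTS["green_deg"],
                           orange_deg: float = DEFAULTS["orange_deg"]) -> TrafficLight:
    """Classify per-plane deviations: green < 5 deg, orange < 15 deg, red otherwise.

    Thresholds are strict, so exactly 5 deg is orange and exactly 15 deg red.
    """
    def color(angle: float) -> str:
        if angle < green_deg:
            return "green"
        if angle < orange_deg:
            return "orange"
        return "red"

    xy = color(dev.xy_deg)
    xz = color(dev.xz_deg)
    return TrafficLight(xy_color=xy, xz_color=xz,
                        both_green=(xy == "green" and xz == "green"))


def step_calibration(session: CalibrationSession, sample, reference: ReferenceVector,
                     dt: float,
                     green_deg: float = DEFAULTS["green_deg"],
                     orange_deg: float = DEFAULTS["orange_deg"]) -> CalibrationSession:
    """Advance the dwell timer by one sample.

    Both planes green: the dwell accumulates by ``dt``; otherwise it resets to
    zero. Success latches once the dwell reaches the requirement and is never
    revoked by later samples.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    dev = PlaneDeviation(
        xy_deg=plane_angle(sample, reference.as_array(), "xy"),
        xz_deg=plane_angle(sample, reference.as_array(), "xz"),
    )
    light = classify_traffic_light(dev, green_deg, orange_deg)
    if light.both_green:
        elapsed = session.green_dwell_elapsed + dt
    else:
        elapsed = 0.0
    # tolerance absorbs float accumulation of many small dt increments
    success = session.success or elapsed >= session.required_dwell - 1e-9
    return replace(session, green_dwell_elapsed=elapsed, success=success)


def run_calibration(trace: AccelTrace, reference: ReferenceVector,
                    required_dwell: float = DEFAULTS["dwell_s"],
                    green_deg: float = DEFAULTS["green_deg"],
                    orange_deg: float = DEFAULTS["orange_deg"],
                    ) -> tuple[CalibrationSession, list[TrafficLight]]:
    """Run the procedure over a recorded trace; returns final state and per-sample lights."""
    dt = 1.0 / trace.sampling_rate
    session = CalibrationSession(required_dwell=required_dwell)
    lights: list[TrafficLight] = []
    for sample in trace.samples:
        dev = PlaneDeviation(
            xy_deg=plane_angle(sample, reference.as_array(), "xy"),
            xz_deg=plane_angle(sample, reference.as_array(), "xz"),
        )
        light = classify_traffic_light(dev, green_deg, orange_deg)
        lights.append(light)
        if light.both_green:
            elapsed = session.green_dwell_elapsed + dt
        else:
            elapsed = 0.0
        session = replace(session, green_dwell_elapsed=elapsed,
                          success=session.success
                          or elapsed >= session.required_dwell - 1e-9)
    return session, lights
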