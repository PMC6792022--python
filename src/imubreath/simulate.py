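"""Synthetic accelerometer traces for a supine torso with abdominal breathing.

The model: the sensor is stationary apart from breathing, so gravity dominates
the triaxial measurement. Abdominal breathing tilts the sensor periodically
about a body-fixed axis by a small angle; the measured vector is the resting
gravity vector rotated by the (time-varying) inverse tilt, plus white sensor
noise. Rotations are isometries, so the noise-free sample norm always equals
the gravity magnitude -- the key invariant of the model.

Breathing is a sinusoid in tilt angle. Cycle-to-cycle irregularity (novice
breathing) is modelled by resampling the instantaneous frequency once per
breathing cycle from a Gaussian around the nominal trajectory; richer waveform
shapes are unnecessary because all downstream evaluation is spectral.

Body acceleration (the small up-and-down translation of the abdomen) is
optional and off by default; gravity carries the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "SimulationConfig",
    "default_mount_orientation",
    "AccelTrace",
    "BlockSpec",
    "GroupSpec",
    "STUDY_BLOCKS",
    "simulate_breathing_trace",
    "simulate_cohort",
    "default_group_specs",
    "simulate_pretest_traces",
]


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def default_mount_orientation() -> Rotation:
    """Typical resting pose of a phone strapped to the upper abdomen.

    The device is never perfectly leveled: a modest fixed tilt (8 deg about x,
    5 deg about y) keeps gravity's projection onto both the xy- and xz-sensor
    planes well away from degeneracy, as on a real torso.
    """
    return Rotation.from_euler("xy", [8.0, 5.0], degrees=True)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic breathing recording.

    ``breathing_freq`` is either a scalar (Hz) or a piecewise-constant
    trajectory given as a sequence of ``(start_time_s, freq_hz)`` knots; the
    first knot must start at 0.
    """

    duration: float = 300.0
    sampling_rate: float = 50.0
    breathing_freq: float | Sequence[tuple[float, float]] = 0.1
    tilt_amplitude: float = 5.0       # deg, peak tilt away from baseline
    tilt_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    baseline_orientation: Any = None  # scipy Rotation (world -> sensor); None = identity
    gravity_magnitude: float = 9.81   # m/s^2
    freq_jitter_sd: float = 0.0       # Hz, per-cycle frequency wobble
    noise_sd: float = 0.0             # m/s^2 additive white noise per axis
    body_accel_amplitude: float = 0.0  # m, optional translational displacement amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidConfigError("sampling_rate must be > 0")
        if self.duration <= 0:
            raise InvalidConfigError("duration must be > 0")
        if self.tilt_amplitude < 0:
            raise InvalidConfigError("tilt_amplitude must be >= 0")
        if self.freq_jitter_sd < 0 or self.noise_sd < 0:
            raise InvalidConfigError("noise parameters must be >= 0")
        axis = np.asarray(self.tilt_axis, dtype=float)
        if axis.shape != (3,) or abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise InvalidConfigError("tilt_axis must be a unit 3-vector (|n|=1 within 1e-9)")
        freqs = self._freq_knots()
        if np.any(freqs[:, 1] <= 0):
            raise InvalidConfigError("breathing_freq must be > 0")
        if freqs[0, 0] != 0.0:
            raise InvalidConfigError("breathing_freq trajectory must start at t=0")
        if np.any(np.diff(freqs[:, 0]) <= 0):
            raise InvalidConfigError("breathing_freq knots must have increasing times")

    def _freq_knots(self) -> np.ndarray:
        """Trajectory as an (k, 2) array of (start_time, freq) rows."""
        if np.isscalar(self.breathing_freq):
            return np.array([[0.0, float(self.breathing_freq)]])
        return np.asarray(self.breathing_freq, dtype=float).reshape(-1, 2)

    def nominal_freq(self, t: float) -> float:
        knots = self._freq_knots()
        idx = int(np.searchsorted(knots[:, 0], t, side="right")) - 1
        return float(knots[max(idx, 0), 1])


@dataclass
class AccelTrace:
    """Timestamped triaxial acceleration in the sensor frame (m/s^2)."""

    timestamps: np.ndarray            # (n,) s, strictly increasing uniform grid
    samples: np.ndarray               # (n, 3) m/s^2
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if len(self.timestamps) != len(self.samples):
            raise ValueError("timestamps and samples must have equal length")
        if not (np.all(np.isfinite(self.timestamps)) and np.all(np.isfinite(self.samples))):
            raise ValueError("trace contains non-finite values")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def sampling_rate(self) -> float:
        dt = np.median(np.diff(self.timestamps))
        return 1.0 / float(dt)

    @property
    def duration(self) -> float:
        n = len(self.timestamps)
        return float(n / self.sampling_rate)

    def __len__(self) -> int:
        return len(self.timestamps)


def _breathing_phase(config: SimulationConfig, t: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Accumulated breathing phase (rad): 2*pi * integral of f(tau) d tau.

    With jitter, the frequency is redrawn at the start of every breathing
    cycle from N(f_nominal(t), freq_jitter_sd), truncated below at a tenth of
    the nominal rate so a pathological draw cannot stall the cycle clock.
    """
    if config.freq_jitter_sd == 0.0 and np.isscalar(config.breathing_freq):
        return 2.0 * np.pi * float(config.breathing_freq) * t

    # Build piecewise-linear phase knots: one segment per breathing cycle
    # (or per nominal-trajectory segment when jitter is off).
    t_end = float(t[-1]) + 1.0 / config.sampling_rate
    knot_t = [0.0]
    knot_phase = [0.0]
    cur_t = 0.0
    while cur_t < t_end:
        f_nom = config.nominal_freq(cur_t)
        f = f_nom
        if config.freq_jitter_sd > 0.0:
            f = rng.normal(f_nom, config.freq_jitter_sd)
            f = max(f, 0.1 * f_nom)
        cycle_len = 1.0 / f
        cur_t += cycle_len
        knot_t.append(cur_t)
        knot_phase.append(knot_phase[-1] + 2.0 * np.pi)
    return np.interp(t, knot_t, knot_phase)


def simulate_breathing_trace(config: SimulationConfig) -> AccelTrace:
    """Generate one synthetic accelerometer trace.

    The sample at time t is ``R_axis(theta(t))^T @ a_rest + eps(t)`` with
    ``theta(t) = tilt_amplitude * sin(phase(t))``, where ``a_rest`` is the
    resting gravity vector expressed in the sensor frame and ``R_axis`` is the
    rotation about ``tilt_axis``. Deterministic given the seed.
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(config.seed)

    g_world = np.array([0.0, 0.0, -config.gravity_magnitude])
    if config.baseline_orientation is None:
        a_rest = g_world
    else:
        a_rest = config.baseline_orientation.apply(g_world)

    phase = _breathing_phase(config, t, rng)
    theta = np.deg2rad(config.tilt_amplitude) * np.sin(phase)
    axis = np.asarray(config.tilt_axis, dtype=float)
    rotvecs = theta[:, None] * axis[None, :]
    samples = Rotation.from_rotvec(rotvecs).inv().apply(a_rest)

    if config.body_accel_amplitude > 0.0:
        # Second derivative of a sinusoidal displacement along the resting
        # vertical; a minor additive term the gravity model dominates.
        f_inst = np.gradient(phase, t) / (2.0 * np.pi)
        accel = -config.body_accel_amplitude * (2.0 * np.pi * f_inst) ** 2 * np.sin(phase)
        vertical = a_rest / np.linalg.norm(a_rest)
        samples = samples + accel[:, None] * vertical[None, :]

    if config.noise_sd > 0.0:
        samples = samples + rng.normal(0.0, config.noise_sd, size=samples.shape)

    return AccelTrace(timestamps=t, samples=samples, metadata={"seed": config.seed})


# ---------------------------------------------------------------------------
# Cohort simulation: two groups x subjects x three 5-min measurement blocks
# ---------------------------------------------------------------------------

STUDY_BLOCKS: tuple[str, ...] = ("baseline", "training", "post")


@dataclass(frozen=True)
class BlockSpec:
    """Distribution of per-subject simulation parameters within one block."""

    breathing_freq_mean: float
    breathing_freq_sd: float = 0.0    # between-subject spread, Hz
    freq_jitter_sd: float = 0.0       # within-subject cycle wobble, Hz
    tilt_amplitude_mean: float = 5.0  # deg
    tilt_amplitude_sd: float = 1.0    # deg
    noise_sd: float = 0.05            # m/s^2
    duration: float = 300.0           # s

    def draw_config(self, rng: np.random.Generator, sampling_rate: float,
                    seed: int) -> SimulationConfig:
        freq = rng.normal(self.breathing_freq_mean, self.breathing_freq_sd)
        freq = max(freq, 0.25 * self.breathing_freq_mean)
        amp = max(rng.normal(self.tilt_amplitude_mean, self.tilt_amplitude_sd), 0.5)
        return SimulationConfig(
            duration=self.duration,
            sampling_rate=sampling_rate,
            breathing_freq=freq,
            tilt_amplitude=amp,
            baseline_orientation=default_mount_orientation(),
            freq_jitter_sd=self.freq_jitter_sd,
            noise_sd=self.noise_sd,
            seed=seed,
        )


@dataclass(frozen=True)
class GroupSpec:
    """One study group: a label, a size, and per-block parameter distributions."""

    label: str
    n_subjects: int
    blocks: Mapping[str, BlockSpec]

    def __post_init__(self) -> None:
        missing = set(STUDY_BLOCKS) - set(self.blocks)
        unknown = set(self.blocks) - set(STUDY_BLOCKS)
        if missing:
            raise InvalidConfigError(f"group {self.label!r} missing blocks: {sorted(missing)}")
        if unknown:
            raise InvalidConfigError(f"group {self.label!r} unknown blocks: {sorted(unknown)}")


def default_group_specs(n_subjects: int = 10, block_duration: float = 300.0
                        ) -> list[GroupSpec]:
    """Study conditions for the two-arm synthetic cohort.

    Spontaneous slow-deep breathing in untrained subjects sits around 0.2 Hz
    (12 cycles/min) with noticeable cycle irregularity; both groups share this
    baseline and revert to it in the post block. During training, both groups
    are paced at 0.1 Hz; the biofeedback-compliant arm holds the target with
    little cycle wobble, the pacing-only arm tracks it more loosely.
    """
    baseline = BlockSpec(breathing_freq_mean=0.20, breathing_freq_sd=0.03,
                         freq_jitter_sd=0.02, duration=block_duration)
    compliant_training = BlockSpec(breathing_freq_mean=0.10, breathing_freq_sd=0.0,
                                   freq_jitter_sd=0.005, duration=block_duration)
    pacing_training = BlockSpec(breathing_freq_mean=0.10, breathing_freq_sd=0.005,
                                freq_jitter_sd=0.02, duration=block_duration)
    return [
        GroupSpec("pacing_only", n_subjects,
                  {"baseline": baseline, "training": pacing_training, "post": baseline}),
        GroupSpec("biofeedback", n_subjects,
                  {"baseline": baseline, "training": compliant_training, "post": baseline}),
    ]


def simulate_cohort(group_specs: Sequence[GroupSpec], seed: int = 0,
                    sampling_rate: float = 50.0) -> list[AccelTrace]:
    """Simulate every subject of every group through the three blocks.

    Returns one trace per (group, subject, block), labelled in ``metadata``
    with keys ``group``, ``subject`` and ``block``. Reproducible given seed:
    each subject gets an independent child of the root seed sequence.
    """
    traces: list[AccelTrace] = []
    root = np.random.SeedSequence(seed)
    for gi, group in enumerate(group_specs):
        for si in range(group.n_subjects):
            child = root.spawn(1)[0]
            rng = np.random.default_rng(child)
            subject = f"{group.label}-s{si:02d}"
            for block in STUDY_BLOCKS:
                cfg_seed = int(rng.integers(0, 2**31 - 1))
                cfg = group.blocks[block].draw_config(rng, sampling_rate, cfg_seed)
                trace = simulate_breathing_trace(cfg)
                trace.metadata.update(
                    group=group.label, subject=subject, block=block,
                    breathing_freq=float(np.atleast_2d(cfg._freq_knots())[0, 1]),
                )
                traces.append(trace)
    return traces


def simulate_pretest_traces(n_persons: int = 5, n_trials: int = 3,
                            trial_duration: float = 60.0, seed: int = 0,
                            sampling_rate: float = 50.0,
                            tilt_amplitude: float = 7.0,
                            noise_sd: float = 0.05,
                            ) -> dict[str, list[AccelTrace]]:
    """Trained-breather trials used to fit the reference model.

    Emulates the calibration recordings: a handful of persons already trained
    in deep abdominal breathing, several one-minute trials each, breathing
    slowly with a large, regular tilt excursion.
    """
    root = np.random.SeedSequence(seed)
    out: dict[str, list[AccelTrace]] = {}
    for p in range(n_persons):
        rng = np.random.default_rng(root.spawn(1)[0])
        person = f"trained-{p:02d}"
        freq = float(rng.uniform(0.08, 0.12))
        amp = float(rng.normal(tilt_amplitude, 0.5))
        out[person] = []
        for trial in range(n_trials):
            cfg = SimulationConfig(
                duration=trial_duration, sampling_rate=sampling_rate,
                breathing_freq=freq, tilt_amplitude=amp,
                baseline_orientation=default_mount_orientation(),
                freq_jitter_sd=0.003, noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            trace = simulate_breathing_trace(cfg)
            trace.metadata.update(person=person, trial=trial)
            out[person].append(trace)
    return out
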