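"""File formats and the reproducible block-protocol runner.

Canonical on-disk formats, all plain text and diffable:

* accelerometer trace -- CSV with header ``t,ax,ay,az`` (s, m/s^2), optional
  metadata in a ``<name>.meta.json`` sidecar;
* breathing signal -- CSV with header ``t,value``;
* pacing waveform -- CSV with header ``t,target,phase,count``;
* reference model, configs, metrics, run manifests -- JSON.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import DEFAULTS, RunConfig, logger
from .pacing import PacingWaveform, generate_pacing
from .reference import (BreathingSignal, FilterSpec, ReferenceModel,
                        extract_breathing_signal, fit_reference_model)
from .simulate import (AccelTrace, SimulationConfig, simulate_breathing_trace,
                       simulate_pretest_traces)
from .spectral import compute_spectrum, per_minute_metrics, respiratory_snr

__all__ = [
    "TraceParseError",
    "read_trace",
    "write_trace",
    "read_signal",
    "write_signal",
    "write_pacing",
    "run_block_protocol",
]

_TRACE_HEADER = ["t", "ax", "ay", "az"]
_FLOAT_FMT = "%.12g"   # round-trip safe well past 9 significant digits


class TraceParseError(ValueError):
    """Malformed trace file; the message names the offending line."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trace(trace: AccelTrace, path: str | Path) -> None:
    """Write a trace as ``t,ax,ay,az`` CSV plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {"t": trace.timestamps, "ax": trace.samples[:, 0],
         "ay": trace.samples[:, 1], "az": trace.samples[:, 2]})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if trace.metadata:
        _sidecar(path).write_text(json.dumps(trace.metadata, indent=2, default=str))


def read_trace(path: str | Path) -> AccelTrace:
    """Read a ``t,ax,ay,az`` CSV trace, validating header, finiteness and time grid."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TraceParseError(f"{path}: empty file, not an empty trace") from None
    if list(df.columns) != _TRACE_HEADER:
        raise TraceParseError(
            f"{path}, line 1: expected header {','.join(_TRACE_HEADER)!r}, "
            f"got {','.join(map(str, df.columns))!r}")
    if len(df) == 0:
        raise TraceParseError(f"{path}: no data rows")
    values = df.to_numpy(dtype=float)
    bad = ~np.isfinite(values).all(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2   # 1-based, after the header
        raise TraceParseError(f"{path}, line {line}: non-finite value")
    t = values[:, 0]
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        line = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 3
        raise TraceParseError(f"{path}, line {line}: timestamps not strictly increasing")
    metadata = {}
    side = _sidecar(path)
    if side.exists():
        metadata = json.loads(side.read_text())
    return AccelTrace(timestamps=t, samples=values[:, 1:4], metadata=metadata)


def write_signal(signal: BreathingSignal, path: str | Path) -> None:
    pd.DataFrame({"t": signal.timestamps, "value": signal.values}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_signal(path: str | Path) -> BreathingSignal:
    df = pd.read_csv(path)
    if list(df.columns) != ["t", "value"]:
        raise TraceParseError(f"{path}, line 1: expected header 't,value'")
    return BreathingSignal(timestamps=df["t"].to_numpy(float),
                           values=df["value"].to_numpy(float))


def write_pacing(pacing: PacingWaveform, path: str | Path) -> None:
    pd.DataFrame({"t": pacing.timestamps, "target": pacing.target,
                  "phase": pacing.phase, "count": pacing.count}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def run_block_protocol(config: RunConfig) -> dict:
    """Run the full three-block study protocol for one simulated subject.

    Fits a reference model from simulated trained-breather pretest trials,
    then per block (baseline, training, post) simulates a recording, extracts
    the breathing signal and computes whole-block and per-minute metrics.
    Writes traces, signals, pacing, metrics and a manifest to
    ``config.out_dir``; a fixed seed makes the run bit-reproducible.
    """
    required = set(DEFAULTS["block_names"])
    if not required <= set(config.block_names):
        missing = sorted(required - set(config.block_names))
        raise ValueError(f"config must name the required blocks; missing {missing}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    pretest_seed, *block_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                                  for s in root.spawn(1 + len(config.block_names))]

    logger.info("fitting reference model from simulated pretest trials")
    pretest = simulate_pretest_traces(seed=pretest_seed,
                                      sampling_rate=config.sampling_rate)
    model = fit_reference_model(pretest)
    model.to_json(out / "model.json")
    fspec = FilterSpec(cutoff=config.filter_cutoff)

    pace = generate_pacing(config.block_duration, config.pacing_freq,
                           config.sampling_rate)
    write_pacing(pace, out / "pacing.csv")

    block_defaults = {
        "baseline": dict(breathing_freq=0.2, freq_jitter_sd=0.02),
        "training": dict(breathing_freq=config.pacing_freq, freq_jitter_sd=0.005),
        "post": dict(breathing_freq=0.2, freq_jitter_sd=0.02),
    }
    metrics: dict[str, dict] = {}
    for name, seed in zip(config.block_names, block_seeds):
        params = dict(duration=config.block_duration,
                      sampling_rate=config.sampling_rate,
                      tilt_amplitude=5.0, noise_sd=0.05, seed=seed,
                      gravity_magnitude=config.gravity_magnitude)
        params.update(block_defaults.get(name, {}))
        params.update(config.block_overrides.get(name, {}))
        try:
            trace = simulate_breathing_trace(SimulationConfig(**params))
            trace.metadata.update(block=name)
            write_trace(trace, out / f"{name}_trace.csv")
            signal = extract_breathing_signal(trace, model, fspec)
            write_signal(signal, out / f"{name}_signal.csv")
            spec = compute_spectrum(signal, max_df=config.spectrum_max_df)
            res = respiratory_snr(spec, f_max=config.snr_f_max,
                                  recommended=config.recommended_band,
                                  exclusion=config.snr_exclusion)
            minutes = per_minute_metrics(signal)
            metrics[name] = {
                "recommended_power": res.recommended_power,
                "noise_power": res.noise_power,
                "snr": res.snr,
                "per_minute_power": minutes.recommended_power.tolist(),
                "per_minute_snr": minutes.snr.tolist(),
            }
        except Exception as exc:
            raise RuntimeError(f"block {name!r} failed: {exc}") from exc
        logger.info("block %s: SNR %.3f", name, metrics[name]["snr"])

    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    manifest = {
        "package": "imubreath",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": config.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return metrics
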