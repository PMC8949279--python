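"""Scalar summaries of acceleration traces and field exports.

Summaries are pure functions of the series: summarising a trace re-read from
CSV gives the same numbers as summarising the in-memory result.  A
configuration fingerprint (SHA-256 of the canonical JSON of all inputs) is
attached to run manifests so any parameter change is detectable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .impact import TimeSeries

__all__ = [
    "RunSummary",
    "peak_acceleration",
    "delay_to_threshold",
    "rise_time",
    "summarise",
    "export_acceleration_map",
    "config_fingerprint",
]


@dataclass
class RunSummary:
    peak_acceleration: float   # m/s^2
    time_of_peak: float        # s
    rise_time: float           # s, first crossing of 50% of peak
    channel: str
    fingerprint: str = ""


def peak_acceleration(series: TimeSeries) -> tuple[float, float]:
    """Maximum |value| and its first attainment time (ties -> earliest)."""
    if len(series.times) == 0:
        raise ValueError("empty series")
    mag = np.abs(series.values)
    i = int(np.argmax(mag))  # argmax returns the first maximiser
    return float(mag[i]), float(series.times[i])


def delay_to_threshold(series: TimeSeries, fraction: float = 0.5) -> float:
    """First time |value| exceeds ``fraction`` of the peak magnitude.

    This is the delay metric separating wave-lagged viscoelastic responses
    from the immediate rise of the softening viscoplastic material.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    peak, _ = peak_acceleration(series)
    if peak == 0.0:
        raise ValueError("delay undefined: series peak is zero")
    mag = np.abs(series.values)
    idx = np.flatnonzero(mag >= fraction * peak)
    return float(series.times[idx[0]])


def rise_time(series: TimeSeries) -> float:
    return delay_to_threshold(series, 0.5)


def summarise(series: TimeSeries, config: dict | None = None) -> RunSummary:
    peak, t_peak = peak_acceleration(series)
    rt = rise_time(series) if peak > 0 else 0.0
    return RunSummary(
        peak_acceleration=peak,
        time_of_peak=t_peak,
        rise_time=rt,
        channel=series.label,
        fingerprint=config_fingerprint(config) if config is not None else "",
    )


def export_acceleration_map(snapshots, mesh, directory, basename: str = "frame") -> list:
    """One VTU per snapshot frame with point data ``acceleration_magnitude``,
    plus a ``.pvd`` collection index listing the frames in time order."""
    from . import formats

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, (t, field) in enumerate(sorted(snapshots, key=lambda s: s[0])):
        field = np.asarray(field, dtype=float)
        if field.shape != (mesh.n_nodes,):
            raise ValueError(f"snapshot {k}: field length {field.shape} != node count")
        fname = f"{basename}_{k:04d}.vtu"
        formats.write_vtu_fields(
            directory / fname, mesh.nodes, mesh.tets,
            point_data={"acceleration_magnitude": field},
        )
        entries.append((t, fname))
    formats.write_pvd(directory / f"{basename}.pvd", entries)
    return [directory / f for _, f in entries]


def _canonical(obj):
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_fingerprint(config: dict) -> str:
    """SHA-256 over the canonical JSON encoding of a configuration mapping."""
    payload = json.dumps(_canonical(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()
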