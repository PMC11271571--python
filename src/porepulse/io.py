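"""Trace and table file formats.

Two trace dialects: a CSV with ``time_s, current_nA`` columns (inspectable)
and a flat little-endian 32-bit float file with a JSON metadata sidecar
(compact).  Both round-trip losslessly at 32-bit precision.  Ground-truth
event lists travel as TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trace_sim import GroundTruthEvent

__all__ = [
    "Trace",
    "TraceFormatError",
    "read_trace",
    "write_trace",
    "write_ground_truth",
    "read_ground_truth",
]

SCHEMA_VERSION = 1


class TraceFormatError(ValueError):
    """A trace file violates its format contract."""


@dataclass
class Trace:
    """Current samples (nA) at a fixed sampling rate, plus file metadata."""

    samples: np.ndarray
    sampling_rate_hz: float
    metadata: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace(trace, path) -> Path:
    """Write a trace as CSV (``.csv``) or float32 binary plus JSON sidecar.

    Accepts any object with ``samples`` (nA) and ``sampling_rate_hz``;
    simulated traces additionally record their seed and baseline in the
    metadata so that the producing run can be reproduced.
    """
    path = Path(path)
    samples = np.asarray(trace.samples, dtype=np.float32)
    fs = float(trace.sampling_rate_hz)
    meta = {
        "sampling_rate_hz": fs,
        "schema_version": SCHEMA_VERSION,
        "baseline_nA": float(getattr(trace, "baseline_na", np.median(samples))),
        "seed": getattr(trace, "seed", None),
    }
    meta.update(getattr(trace, "metadata", {}))
    if path.suffix == ".csv":
        with open(path, "w") as fh:
            for key, value in sorted(meta.items()):
                fh.write(f"# {key}: {json.dumps(value)}\n")
            pd.DataFrame(
                {"time_s": np.arange(len(samples)) / fs, "current_nA": samples}
            ).to_csv(fh, index=False)
    else:
        samples.astype("<f4").tofile(path)
        _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_trace(path) -> Trace:
    """Read a CSV or binary+sidecar trace; returns samples in nA.

    Raises :class:`TraceFormatError` on NaN samples (naming the row),
    non-monotone time, or a missing/incomplete sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"{path}: no such file")
    if path.suffix == ".csv":
        meta: dict = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                key, _, value = line[1:].partition(":")
                try:
                    meta[key.strip()] = json.loads(value.strip())
                except json.JSONDecodeError:
                    meta[key.strip()] = value.strip()
                pos = fh.tell()
            df = pd.read_csv(fh)
        if not {"time_s", "current_nA"} <= set(df.columns):
            raise TraceFormatError(f"{path}: expected columns time_s, current_nA")
        bad = df.index[df.isna().any(axis=1)]
        if len(bad):
            raise TraceFormatError(f"{path}: NaN sample at data row {int(bad[0])}")
        t = df["time_s"].to_numpy(dtype=float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            row = int(np.argmax(np.diff(t) <= 0)) + 1
            raise TraceFormatError(f"{path}: non-monotone time at data row {row}")
        fs = meta.get("sampling_rate_hz")
        if fs is None:
            if len(t) < 2:
                raise TraceFormatError(f"{path}: cannot infer sampling rate")
            fs = 1.0 / float(np.median(np.diff(t)))
        return Trace(
            samples=df["current_nA"].to_numpy(dtype=float),
            sampling_rate_hz=float(fs),
            metadata=meta,
        )
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise TraceFormatError(f"{path}: missing metadata sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    if "sampling_rate_hz" not in meta:
        raise TraceFormatError(f"{sidecar}: sidecar lacks sampling_rate_hz")
    samples = np.fromfile(path, dtype="<f4").astype(float)
    if np.isnan(samples).any():
        raise TraceFormatError(
            f"{path}: NaN sample at offset {int(np.argmax(np.isnan(samples)))}"
        )
    return Trace(samples=samples, sampling_rate_hz=float(meta["sampling_rate_hz"]), metadata=meta)


def write_ground_truth(events, path) -> Path:
    """Ground-truth TSV: event_id, t_s, cluster_size, amp_nA, dur_ms."""
    path = Path(path)
    pd.DataFrame(
        {
            "event_id": np.arange(len(events)),
            "t_s": [e.t_s for e in events],
            "cluster_size": [e.cluster_size for e in events],
            "amp_nA": [e.amplitude_na for e in events],
            "dur_ms": [e.duration_ms for e in events],
            "label": [e.label for e in events],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def read_ground_truth(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        GroundTruthEvent(
            t_s=float(r.t_s),
            cluster_size=int(r.cluster_size),
            amplitude_na=float(r.amp_nA),
            duration_ms=float(r.dur_ms),
            label="" if pd.isna(r.label) else str(r.label),
        )
        for r in df.itertuples()
    ]
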