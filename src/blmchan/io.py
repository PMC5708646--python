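"""Shared data model and on-disk formats for BLM voltage-clamp recordings.

Units are fixed repo-wide: seconds, pA, mV, pS, mM, K.  Conductance in
pS = pA/mV x 1000.  The recording geometry follows the usual BLM convention:
the command electrode sits in the *cis* chamber, the reference electrode in
*trans*, and positive current is cation flux cis -> trans; depolarization is
a positive command voltage.

Sampling is half-open: sample k holds the value at t = k/sample_rate, and a
segment of duration d contributes round(d * sample_rate) samples, so segments
concatenate without duplicated boundary samples.

On-disk trace format: comma-separated text, columns ``time_s, current_pA,
voltage_mV``, preceded by ``#``-prefixed metadata lines (``sample_rate_hz``,
``filter_cutoff_hz``, ``label``, ``seed``).  Event tables are TSV.  Voltage
protocols and channel models are YAML.
"""

from __future__ import annotations

import dataclasses
import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ValidationError

__all__ = [
    "Trace",
    "Segment",
    "VoltageProtocol",
    "RecordingGeometry",
    "GEOMETRY",
    "render_protocol",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "validate_events",
    "read_protocol",
    "write_protocol",
    "EVENT_COLUMNS",
]

#: Canonical column names of the trace CSV format.
TIME_COL = "time_s"
CURRENT_COL = "current_pA"
VOLTAGE_COL = "voltage_mV"
TRACE_COLUMNS = (TIME_COL, CURRENT_COL, VOLTAGE_COL)

#: Canonical columns of the idealized event table (TSV).
EVENT_COLUMNS = (
    "trace_id",
    "start_s",
    "duration_s",
    "amplitude_pA",
    "step_voltage_mV",
    "level",
)

_TIME_UNIFORMITY_TOL_S = 1e-9
_RATE_REL_TOL = 1e-6


@dataclass(frozen=True)
class RecordingGeometry:
    """Fixed orientation convention shared by simulator and analysis."""

    command_side: str = "cis"
    reference_side: str = "trans"
    positive_current_direction: str = "cation flux cis->trans"


GEOMETRY = RecordingGeometry()


@dataclass
class Trace:
    """A sampled voltage-clamp recording on a uniform time grid.

    Parameters
    ----------
    time : array, seconds.  Strictly increasing, uniform within 1 ns.
    current : array, pA.  Same length as ``time``.
    voltage : array, mV.  Command voltage on the same grid.
    sample_rate : float, Hz.  Must satisfy sample_rate * dt == 1 within 1e-6.
    filter_cutoff : float or None, Hz.  Low-pass cutoff already applied.
    label : str.  Free-text metadata (e.g. provenance, simulation seed).
    """

    time: np.ndarray
    current: np.ndarray
    voltage: np.ndarray
    sample_rate: float
    filter_cutoff: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        n = self.time.size
        if self.time.ndim != 1 or n < 2:
            raise ValidationError(
                f"trace needs >= 2 samples on a 1-d grid, got shape {self.time.shape}"
            )
        if self.current.shape != self.time.shape or self.voltage.shape != self.time.shape:
            raise ValidationError(
                "time, current and voltage must have identical length: "
                f"{self.time.size}, {self.current.size}, {self.voltage.size}"
            )
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0))
            raise ValidationError(f"time grid not strictly increasing at index {idx + 1}")
        bad = np.abs(dt - dt[0]) > _TIME_UNIFORMITY_TOL_S
        if np.any(bad):
            idx = int(np.argmax(bad))
            raise ValidationError(f"time grid not uniform at index {idx + 1}")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if abs(self.sample_rate * float(dt[0]) - 1.0) > _RATE_REL_TOL:
            raise ValidationError(
                f"sample_rate {self.sample_rate} Hz inconsistent with grid step {dt[0]} s"
            )

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    def replace(self, **kwargs) -> "Trace":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class Segment:
    """One piece of a voltage protocol: hold/step (constant) or ramp (linear)."""

    kind: str
    start_mV: float
    duration_s: float
    end_mV: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("hold", "step", "ramp"):
            raise ValidationError(f"unknown segment kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ValidationError("segment duration must be positive")
        if self.kind == "ramp" and self.end_mV is None:
            raise ValidationError("ramp segments need both start_mV and end_mV")


@dataclass(frozen=True)
class VoltageProtocol:
    """Ordered voltage-command segments, optionally repeated."""

    segments: tuple[Segment, ...]
    repeats: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if len(self.segments) == 0:
            raise ValidationError("protocol needs at least one segment")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")

    @property
    def sweep_duration(self) -> float:
        """Duration of one repeat, s."""
        return float(sum(s.duration_s for s in self.segments))

    @property
    def total_duration(self) -> float:
        return self.sweep_duration * self.repeats

    @property
    def ramp_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind == "ramp")


def render_protocol(
    protocol: VoltageProtocol, sample_rate: float, include_repeats: bool = True
) -> np.ndarray:
    """Render a protocol to a command-voltage series (mV) on the uniform grid.

    Half-open sampling: a segment of duration d contributes round(d * rate)
    samples; ramps are linear in time with slope (end-start)/duration, so the
    last sample of a ramp stops one grid step short of ``end_mV``.
    """
    if sample_rate <= 0:
        raise ValidationError("sample_rate must be positive")
    pieces: list[np.ndarray] = []
    for seg in protocol.segments:
        n = int(round(seg.duration_s * sample_rate))
        if n == 0:
            continue
        if seg.kind == "ramp":
            t = np.arange(n) / sample_rate
            v = seg.start_mV + (seg.end_mV - seg.start_mV) * t / seg.duration_s
        else:
            v = np.full(n, float(seg.start_mV))
        pieces.append(v)
    if not pieces:
        raise ValidationError("protocol renders to zero samples at this sample rate")
    sweep = np.concatenate(pieces)
    reps = protocol.repeats if include_repeats else 1
    return np.tile(sweep, reps)


# ---------------------------------------------------------------------------
# trace files
# ---------------------------------------------------------------------------

def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as commented CSV; round-trips to >= 9 significant digits."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"# sample_rate_hz={trace.sample_rate:.12g}\n")
    if trace.filter_cutoff is not None:
        buf.write(f"# filter_cutoff_hz={trace.filter_cutoff:.12g}\n")
    if trace.label:
        buf.write(f"# label={trace.label}\n")
    buf.write(",".join(TRACE_COLUMNS) + "\n")
    data = np.column_stack([trace.time, trace.current, trace.voltage])
    np.savetxt(buf, data, fmt="%.12g", delimiter=",")
    path.write_text(buf.getvalue())


def read_trace(path: str | Path) -> Trace:
    """Read a trace CSV written by :func:`write_trace` (or equivalent)."""
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    n_skip = 0
    with open(path) as fh:
        for line in fh:
            n_skip += 1
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            header = [c.strip() for c in line.split(",")]
            break
    if header is None:
        raise FormatError(f"{path}: no header line found")
    for col in TRACE_COLUMNS:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    data = np.loadtxt(path, delimiter=",", skiprows=n_skip, ndmin=2)
    if data.shape[1] != len(header):
        raise FormatError(
            f"{path}: {data.shape[1]} data columns but {len(header)} header names"
        )
    cols = {name: data[:, i] for i, name in enumerate(header)}
    time = cols[TIME_COL]
    if "sample_rate_hz" in meta:
        rate = float(meta["sample_rate_hz"])
    else:
        if time.size < 2:
            raise ValidationError(f"{path}: trace shorter than 2 samples")
        rate = 1.0 / float(np.median(np.diff(time)))
    cutoff = float(meta["filter_cutoff_hz"]) if "filter_cutoff_hz" in meta else None
    return Trace(
        time=time,
        current=cols[CURRENT_COL],
        voltage=cols[VOLTAGE_COL],
        sample_rate=rate,
        filter_cutoff=cutoff,
        label=meta.get("label", ""),
    )


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def empty_events() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in EVENT_COLUMNS})
    df["trace_id"] = df["trace_id"].astype(str)
    df["level"] = df["level"].astype("Int64")
    return df


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check the event-table invariants: schema, ordering, non-overlap."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"event table missing columns {missing}")
    for tid, grp in events.groupby("trace_id", sort=False):
        start = grp["start_s"].to_numpy(float)
        dur = grp["duration_s"].to_numpy(float)
        order = np.argsort(start)
        s, d = start[order], dur[order]
        if np.any(s[1:] < s[:-1] + d[:-1] - 1e-12):
            raise ValidationError(f"overlapping events in trace {tid!r}")
    return events


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events)
    events.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="")


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: event table missing columns {missing}")
    df["level"] = df["level"].astype("Int64")
    df["trace_id"] = df["trace_id"].astype(str)
    return validate_events(df)


# ---------------------------------------------------------------------------
# protocol config files (YAML)
# ---------------------------------------------------------------------------

def protocol_to_dict(protocol: VoltageProtocol) -> dict:
    segs = []
    for s in protocol.segments:
        d = {"kind": s.kind, "start_mV": s.start_mV, "duration_s": s.duration_s}
        if s.end_mV is not None:
            d["end_mV"] = s.end_mV
        segs.append(d)
    return {"repeats": protocol.repeats, "segments": segs}


def protocol_from_dict(d: dict) -> VoltageProtocol:
    try:
        segs = tuple(
            Segment(
                kind=s["kind"],
                start_mV=float(s["start_mV"]),
                duration_s=float(s["duration_s"]),
                end_mV=float(s["end_mV"]) if "end_mV" in s and s["end_mV"] is not None else None,
            )
            for s in d["segments"]
        )
    except KeyError as exc:
        raise FormatError(f"protocol config missing key {exc}") from exc
    return VoltageProtocol(segments=segs, repeats=int(d.get("repeats", 1)))


def write_protocol(protocol: VoltageProtocol, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(protocol_to_dict(protocol), sort_keys=False))


def read_protocol(path: str | Path) -> VoltageProtocol:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise FormatError(f"{path}: protocol config must be a mapping")
    return protocol_from_dict(d)
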