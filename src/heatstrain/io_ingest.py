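"""Ingestion of smartwatch device exports.

Device uploads arrive either as JSON payloads (one object per upload, possibly
chunked across several objects) or as a flat CSV download of the whole record.
Both are normalized into a :class:`WearRecord` keyed by an opaque study ID —
no personally identifiable fields are ever parsed or stored.

Timestamps are held internally as UTC epoch seconds (floats, since
beat-to-beat events are sub-second); ISO-8601 strings in exports are converted
at the boundary so a single clock is used across multiday wear.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Metrics exported by the watch, in canonical order.
METRICS = ("steps", "rr", "spo2", "bbi")

#: Engineering units per metric.
UNITS = {
    "steps": "steps/min",
    "rr": "breaths/min",
    "spo2": "percent",
    "bbi": "ms",
}

#: Nominal seconds between samples; beat-to-beat intervals are event-driven.
CADENCE_S = {"steps": 60, "rr": 60, "spo2": 60, "bbi": None}


class ParseError(ValueError):
    """Raised when an export file violates the documented schema."""


@dataclass
class SampleStream:
    """One metric's timestamped samples.

    Timestamps are UTC epoch seconds, non-decreasing.  Ties (same timestamp,
    different value) are permitted — ingestion is lossless and downstream
    cleaning decides — but are flagged with a warning.
    """

    metric: str
    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ParseError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape or self.timestamps.ndim != 1:
            raise ValueError("timestamps and values must be 1-D arrays of equal length")
        if self.timestamps.size and np.any(np.diff(self.timestamps) < 0):
            raise ValueError(f"{self.metric}: timestamps must be sorted")
        ties = self.timestamps.size and np.any(np.diff(self.timestamps) == 0)
        if ties:
            logger.warning("%s: conflicting samples share a timestamp; all retained", self.metric)

    @property
    def units(self) -> str:
        return UNITS[self.metric]

    @property
    def cadence_s(self):
        return CADENCE_S[self.metric]

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass
class WearRecord:
    """All streams for one participant plus optional reference temperatures."""

    participant_id: str
    device_uuid: str = ""
    streams: dict = field(default_factory=dict)
    reference_temps: pd.DataFrame | None = None  # columns: timestamp, temp_c

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ValueError("participant_id must be non-empty")
        for metric, stream in self.streams.items():
            if metric != stream.metric:
                raise ValueError(f"stream keyed {metric!r} carries metric {stream.metric!r}")

    def stream(self, metric: str) -> SampleStream | None:
        return self.streams.get(metric)


def _to_epoch_seconds(raw) -> np.ndarray:
    """Accept epoch seconds or ISO-8601 strings; return float seconds UTC."""
    arr = np.asarray(raw)
    if arr.dtype.kind in "ifu":
        return arr.astype(float)
    ts = pd.to_datetime(arr.ravel(), utc=True, format="ISO8601")
    return (ts.astype("int64") / 1e9).to_numpy().reshape(arr.shape)


def _build_streams(frames: dict[str, list[tuple]]) -> dict[str, SampleStream]:
    streams = {}
    for metric, pairs in frames.items():
        pairs.sort()
        t = np.array([p[0] for p in pairs], dtype=float)
        v = np.array([p[1] for p in pairs], dtype=float)
        streams[metric] = SampleStream(metric, t, v)
    return streams


def read_record(path, fmt: str | None = None) -> WearRecord:
    """Read a device export (JSON or CSV) into a :class:`WearRecord`.

    Metrics absent from the file yield absent streams, not errors: device
    initialization failures in the field routinely drop whole channels.

    Parameters
    ----------
    path
        Export file.
    fmt
        ``"json"`` or ``"csv"``; inferred from the suffix when omitted.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "json":
        return _read_json(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unsupported format {fmt!r}; expected json or csv")


def _read_json(path: Path) -> WearRecord:
    text = Path(path).read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    payload = json.loads(text)
    uploads = payload if isinstance(payload, list) else [payload]
    pid, uuid = None, None
    frames: dict[str, list] = {}
    for i, obj in enumerate(uploads):
        try:
            metric = obj["metric"]
            samples = obj["samples"]
        except (TypeError, KeyError) as exc:
            raise ParseError(f"{path}: upload {i} missing field {exc}") from None
        if metric not in METRICS:
            raise ParseError(f"{path}: upload {i} has unknown metric {metric!r}")
        if pid is None:
            pid = obj.get("participant_id", path.stem)
            uuid = obj.get("device_uuid", "")
        elif obj.get("participant_id", pid) != pid:
            raise ParseError(f"{path}: uploads mix participant IDs")
        for j, pair in enumerate(samples):
            try:
                t, v = pair
                frames.setdefault(metric, []).append((float(_to_epoch_seconds([t])[0]), float(v)))
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}: upload {i} sample {j}: {exc}") from None
    if not frames:
        raise ParseError(f"{path}: no samples found")
    return WearRecord(pid, uuid, _build_streams(frames))


def _read_csv(path: Path) -> WearRecord:
    try:
        # round_trip: device timestamps carry sub-second precision that the
        # default float parser does not preserve bit-exactly
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    required = {"timestamp", "metric", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ParseError(f"{path}: no samples found")
    unknown = set(df["metric"].unique()) - set(METRICS)
    if unknown:
        raise ParseError(f"{path}: unknown metric(s) {sorted(unknown)}")
    try:
        t = _to_epoch_seconds(df["timestamp"].to_numpy())
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: malformed timestamp: {exc}") from None
    pid = str(df["participant_id"].iloc[0]) if "participant_id" in df else path.stem
    uuid = str(df["device_uuid"].iloc[0]) if "device_uuid" in df else ""
    frames: dict[str, list] = {}
    values = df["value"].to_numpy(dtype=float)
    for metric, ts, v in zip(df["metric"], t, values):
        frames.setdefault(metric, []).append((float(ts), float(v)))
    return WearRecord(pid, uuid, _build_streams(frames))


def write_record(record: WearRecord, path, fmt: str | None = None) -> None:
    """Write a record in the same dialects :func:`read_record` accepts."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "json":
        uploads = [
            {
                "participant_id": record.participant_id,
                "device_uuid": record.device_uuid,
                "metric": metric,
                "samples": [[float(t), float(v)] for t, v in zip(s.timestamps, s.values)],
            }
            for metric, s in sorted(record.streams.items())
        ]
        path.write_text(json.dumps(uploads, indent=1))
    elif fmt == "csv":
        rows = []
        for metric in METRICS:
            s = record.streams.get(metric)
            if s is None:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "timestamp": s.timestamps,
                        "metric": metric,
                        "value": s.values,
                        "participant_id": record.participant_id,
                        "device_uuid": record.device_uuid,
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def read_reference_temps(path) -> pd.DataFrame:
    """Read sparse reference (tympanic) temperatures: columns timestamp,temp_c."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"timestamp", "temp_c"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = pd.DataFrame(
        {"timestamp": _to_epoch_seconds(df["timestamp"].to_numpy()), "temp_c": df["temp_c"].astype(float)}
    )
    return out.sort_values("timestamp", ignore_index=True)


def merge_records(parts: list[WearRecord]) -> WearRecord:
    """Merge chunked uploads of one participant into a single record.

    Streams are concatenated, re-sorted, and exact duplicate (timestamp, value)
    pairs dropped.  Same-timestamp conflicts with different values are both
    retained (flagged by :class:`SampleStream`) — merging is lossless.
    """
    if not parts:
        raise ValueError("no records to merge")
    pid, uuid = parts[0].participant_id, parts[0].device_uuid
    for p in parts[1:]:
        if p.participant_id != pid:
            raise ValueError(f"conflicting participant IDs: {pid!r} vs {p.participant_id!r}")
        if p.device_uuid != uuid:
            raise ValueError(f"conflicting device UUIDs for {pid!r}")
    merged: dict[str, SampleStream] = {}
    refs = [p.reference_temps for p in parts if p.reference_temps is not None]
    for metric in METRICS:
        chunks = [p.streams[metric] for p in parts if metric in p.streams]
        if not chunks:
            continue
        t = np.concatenate([c.timestamps for c in chunks])
        v = np.concatenate([c.values for c in chunks])
        pairs = np.unique(np.column_stack([t, v]), axis=0)  # sorts and de-duplicates
        merged[metric] = SampleStream(metric, pairs[:, 0], pairs[:, 1])
    ref = None
    if refs:
        ref = pd.concat(refs).drop_duplicates().sort_values("timestamp", ignore_index=True)
    return WearRecord(pid, uuid, merged, ref)


def clone_with_stream(record: WearRecord, stream: SampleStream) -> WearRecord:
    """Return a copy of *record* with one stream replaced (used by cleaning)."""
    streams = dict(record.streams)
    streams[stream.metric] = stream
    return replace(record, streams=streams)
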