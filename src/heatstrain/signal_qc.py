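"""Artifact removal and NN-interval preparation.

Two distinct cleaning notions are implemented, matching how wearable pipelines
treat raw streams versus HRV substrates:

* raw streams — samples outside a metric's physiologic validity range are
  *deleted*, and the removal rate ("% correction") is reported as a signal
  quality figure;
* NN intervals — ectopic/outlier beats in the beat-to-beat series are
  *replaced* by linear interpolation so the series keeps its length and the
  variability statistics stay well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_ingest import SampleStream, WearRecord, clone_with_stream

#: Physiologic validity ranges per metric (inclusive bounds).
#: steps/min, breaths/min, percent, and ms; the BBI bounds correspond to a
#: heart rate of 40-200 beats/min.
DEFAULT_RANGES = {
    "steps": (0.0, 220.0),
    "rr": (6.0, 60.0),
    "spo2": (60.0, 100.0),
    "bbi": (300.0, 1500.0),
}

#: Relative deviation from the previous accepted beat above which a beat is
#: flagged ectopic (Malik criterion).
DEFAULT_ECTOPIC_THRESHOLD = 0.20


@dataclass(frozen=True)
class ValidRange:
    metric: str
    lo: float
    hi: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"{self.metric}: lo {self.lo} > hi {self.hi}")

    @classmethod
    def default(cls, metric: str) -> "ValidRange":
        lo, hi = DEFAULT_RANGES[metric]
        return cls(metric, lo, hi)


@dataclass
class CleanResult:
    """Outcome of valid-range filtering on one stream."""

    cleaned: SampleStream
    n_total: int
    n_removed: int

    @property
    def pct_correction(self) -> float:
        """Percent of samples removed; NaN for an empty stream."""
        if self.n_total == 0:
            return float("nan")
        return 100.0 * self.n_removed / self.n_total


def apply_valid_range(stream: SampleStream, valid_range: ValidRange | None = None) -> CleanResult:
    """Delete samples outside [lo, hi] (bounds inclusive), preserving order."""
    if valid_range is None:
        valid_range = ValidRange.default(stream.metric)
    if valid_range.metric != stream.metric:
        raise ValueError(
            f"range is for {valid_range.metric!r} but stream carries {stream.metric!r}"
        )
    keep = (stream.values >= valid_range.lo) & (stream.values <= valid_range.hi)
    cleaned = SampleStream(stream.metric, stream.timestamps[keep], stream.values[keep])
    return CleanResult(cleaned, n_total=len(stream), n_removed=int((~keep).sum()))


def clean_record(record: WearRecord, ranges: dict | None = None):
    """Apply valid-range filtering to every stream of a record.

    Returns ``(cleaned_record, results)`` where ``results`` maps metric name
    to its :class:`CleanResult`.
    """
    results: dict[str, CleanResult] = {}
    cleaned = record
    for metric, stream in record.streams.items():
        if ranges and metric in ranges:
            lo, hi = ranges[metric]
            vr = ValidRange(metric, lo, hi)
        else:
            vr = ValidRange.default(metric)
        res = apply_valid_range(stream, vr)
        results[metric] = res
        cleaned = clone_with_stream(cleaned, res.cleaned)
    return cleaned, results


def flag_ectopic(values: np.ndarray, threshold: float = DEFAULT_ECTOPIC_THRESHOLD) -> np.ndarray:
    """Flag beats deviating from the previous *accepted* beat by > threshold.

    The first beat anchors the comparison and is never flagged.  Returns a
    boolean mask of flagged beats.
    """
    values = np.asarray(values, dtype=float)
    flagged = np.zeros(values.size, dtype=bool)
    if values.size == 0:
        return flagged
    ref = values[0]
    for i in range(1, values.size):
        if abs(values[i] - ref) > threshold * ref:
            flagged[i] = True
        else:
            ref = values[i]
    return flagged


def clean_nn_intervals(
    bbi: SampleStream,
    threshold: float = DEFAULT_ECTOPIC_THRESHOLD,
    valid_range: ValidRange | None = None,
) -> SampleStream:
    """Replace ectopic/outlier beats by linear interpolation between the
    nearest non-flagged neighbours.

    The series length is unchanged and output values are clipped into the BBI
    validity range.  Flagged beats at the edges take the nearest accepted
    value (flat extension).
    """
    if bbi.metric != "bbi":
        raise ValueError(f"expected a bbi stream, got {bbi.metric!r}")
    if len(bbi) < 3:
        raise ValueError("need at least 3 beats to interpolate ectopic replacements")
    if valid_range is None:
        valid_range = ValidRange.default("bbi")
    flagged = flag_ectopic(bbi.values, threshold)
    if not flagged.any():
        return bbi
    idx = np.arange(len(bbi))
    good = ~flagged
    if not good.any():
        raise ValueError("all beats flagged; cannot interpolate")
    values = bbi.values.copy()
    values[flagged] = np.interp(idx[flagged], idx[good], bbi.values[good])
    values = np.clip(values, valid_range.lo, valid_range.hi)
    return SampleStream("bbi", bbi.timestamps.copy(), values)
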