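"""Fixed-width epoch aggregation of cleaned streams.

Windows are left-closed right-open ``[start, start+width)`` and wall-clock
aligned (``floor(t / width) * width``) so epochs join cleanly across metrics
whose first samples differ.  Five-minute statistics are computed from raw
cleaned samples, not from 60-second means: the window SD is a first-class
output and the SD of means would understate it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_ingest import METRICS, SampleStream, WearRecord

EPOCH_WIDTHS = (60, 300)

REST, ACTIVE, UNKNOWN = "rest", "active", "unknown"


def window_grid(t_first: float, t_last: float, width: int) -> np.ndarray:
    """Start times of all width-second windows intersecting [t_first, t_last]."""
    lo = np.floor(t_first / width) * width
    hi = np.floor(t_last / width) * width
    return np.arange(lo, hi + width, width)


def aggregate(stream: SampleStream, width: int, span: tuple[float, float] | None = None) -> pd.DataFrame:
    """Aggregate one stream into fixed windows.

    Returns a DataFrame indexed by ``window_start`` with columns
    ``mean, sd, n, valid``.  Empty windows are present with ``n == 0`` and
    ``valid == False``; ``sd`` is reported only when ``n >= 2``.

    Parameters
    ----------
    stream
        A cleaned stream with sorted timestamps.
    width
        Window width in seconds (60 or 300).
    span
        Optional (t_first, t_last) defining the window grid; defaults to the
        stream's own span.  Partial leading/trailing windows are kept.
    """
    if width not in EPOCH_WIDTHS:
        raise ValueError(f"width must be one of {EPOCH_WIDTHS}, got {width}")
    if len(stream) and np.any(np.diff(stream.timestamps) < 0):
        raise ValueError("stream timestamps must be sorted")
    if span is None:
        if len(stream) == 0:
            raise ValueError("cannot infer a window grid from an empty stream without span")
        span = (stream.timestamps[0], stream.timestamps[-1])
    grid = window_grid(span[0], span[1], width)
    starts = np.floor(stream.timestamps / width) * width
    df = pd.DataFrame({"start": starts, "value": stream.values})
    g = df.groupby("start")["value"]
    agg = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.count()})
    agg = agg.reindex(grid)
    agg["n"] = agg["n"].fillna(0).astype(int)
    agg.loc[agg["n"] < 2, "sd"] = np.nan
    agg["valid"] = agg["n"] >= 1
    agg.index.name = "window_start"
    return agg


def bbi_to_hr(mean_bbi):
    """Convert a mean beat-to-beat interval (ms) to heart rate (beats/min).

    Maps the BBI validity range [300, 1500] ms onto HR [200, 40] bpm.
    """
    arr = np.asarray(mean_bbi, dtype=float)
    if np.any(arr[np.isfinite(arr)] <= 0):
        raise ValueError("mean BBI must be positive")
    out = 60000.0 / arr
    return float(out) if np.isscalar(mean_bbi) else out


def classify_activity(steps_mean: float, steps_n: int) -> str:
    """Rest iff the window's mean step rate is 0 with at least one sample;
    active iff it is positive; unknown when no step samples are present."""
    if steps_n < 1 or not np.isfinite(steps_mean):
        return UNKNOWN
    return ACTIVE if steps_mean > 0 else REST


def epoch_frame(record: WearRecord, width: int, span: tuple[float, float] | None = None) -> pd.DataFrame:
    """Joint epoch table for all four metrics of a cleaned record.

    Columns per metric: ``<metric>_mean, <metric>_sd, <metric>_n,
    <metric>_valid``; plus ``hr_bpm`` derived from the mean BBI and
    ``activity_state`` from the step channel.  Metrics without a stream
    contribute all-invalid columns (n=0), mirroring channel dropouts in the
    field.
    """
    if span is None:
        firsts = [s.timestamps[0] for s in record.streams.values() if len(s)]
        lasts = [s.timestamps[-1] for s in record.streams.values() if len(s)]
        if not firsts:
            raise ValueError("record has no samples")
        span = (min(firsts), max(lasts))
    grid = window_grid(span[0], span[1], width)
    out = pd.DataFrame(index=pd.Index(grid, name="window_start"))
    for metric in METRICS:
        stream = record.streams.get(metric)
        if stream is not None and len(stream):
            agg = aggregate(stream, width, span)
        else:
            agg = pd.DataFrame(
                {"mean": np.nan, "sd": np.nan, "n": 0, "valid": False}, index=out.index
            )
        for col in ("mean", "sd", "n", "valid"):
            out[f"{metric}_{col}"] = agg[col]
    with np.errstate(divide="ignore"):
        out["hr_bpm"] = 60000.0 / out["bbi_mean"]
    out["activity_state"] = [
        classify_activity(m, n) for m, n in zip(out["steps_mean"], out["steps_n"])
    ]
    out["width"] = width
    return out
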