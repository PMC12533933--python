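"""Wear detection, compliance, and the per-participant data-quality report.

The watch counts as worn in a 5-minute window when valid data are present for
at least 2 of the 4 device metrics.  The wear period runs from the first to
the last valid beat-to-beat sample; compliance is the percentage of 5-minute
windows in that period that are worn.  Validity percentages per metric are
reported over worn windows (switchable to all windows) and stratified by
rest (step mean = 0) versus active (step mean > 0) windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_ingest import METRICS, WearRecord
from .signal_qc import DEFAULT_ECTOPIC_THRESHOLD, clean_nn_intervals, clean_record
from .windowing import ACTIVE, REST, epoch_frame

#: Minimum cleaned samples for a metric to count as valid in a 5-min window.
DEFAULT_MIN_SAMPLES = 1
#: Minimum NN beats for a 5-min window to support HRV computation.
DEFAULT_MIN_HRV_BEATS = 120
#: Number of the four metrics that must be valid for a window to count as worn.
WORN_MIN_METRICS = 2

#: Rows of the rendered quality table.
REPORT_METRICS = ("hrv", "rr", "spo2", "steps", "bbi")


def window_worn(valid_flags) -> bool:
    """True iff at least 2 of the 4 metrics are valid in the window.

    ``valid_flags`` maps metric name to a boolean (missing metrics count as
    invalid).
    """
    return sum(bool(valid_flags.get(m, False)) for m in METRICS) >= WORN_MIN_METRICS


def worn_mask(epochs_5min: pd.DataFrame) -> pd.Series:
    """Vectorized wear decision over an epoch table."""
    flags = sum(epochs_5min[f"{m}_valid"].astype(int) for m in METRICS)
    return flags >= WORN_MIN_METRICS


@dataclass
class QualityReport:
    """Per-participant wearability and data-quality summary."""

    participant_id: str
    wear_duration_days: float
    compliance_pct: float
    #: metric -> percent of raw samples removed by valid-range filtering
    pct_correction: dict = field(default_factory=dict)
    #: metric (incl. "hrv") -> {"overall"|"rest"|"active": percent or NaN}
    pct_valid_windows: dict = field(default_factory=dict)
    n_windows: int = 0
    n_worn: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Machine-readable long table (one row per metric/stratum figure)."""
        rows = []
        for metric, pct in sorted(self.pct_correction.items()):
            rows.append((self.participant_id, "pct_correction", metric, "overall", pct))
        for metric, strata in self.pct_valid_windows.items():
            for stratum, pct in strata.items():
                rows.append((self.participant_id, "pct_valid_windows", metric, stratum, pct))
        rows.append((self.participant_id, "wear_duration_days", "", "overall", self.wear_duration_days))
        rows.append((self.participant_id, "compliance_pct", "", "overall", self.compliance_pct))
        return pd.DataFrame(rows, columns=["participant_id", "measure", "metric", "stratum", "value"])


def wear_period(record: WearRecord) -> tuple[float, float]:
    """(first, last) valid BBI timestamp of a cleaned record."""
    bbi = record.streams.get("bbi")
    if bbi is None or len(bbi) == 0:
        raise ValueError("wear period undefined: record has no valid BBI samples")
    return float(bbi.timestamps[0]), float(bbi.timestamps[-1])


def compliance(record: WearRecord, ranges: dict | None = None,
               min_samples: int = DEFAULT_MIN_SAMPLES) -> tuple[float, float]:
    """Return ``(wear_duration_days, compliance_pct)`` for a raw record.

    The record is cleaned internally; compliance is the percentage of worn
    5-minute windows between the first and last valid BBI sample.
    """
    cleaned, _ = clean_record(record, ranges)
    t0, t1 = wear_period(cleaned)
    epochs = epoch_frame(cleaned, 300, span=(t0, t1))
    worn = _apply_min_samples(epochs, min_samples)
    pct = 100.0 * worn.sum() / len(epochs)
    return (t1 - t0) / 86400.0, float(pct)


def _apply_min_samples(epochs: pd.DataFrame, min_samples: int) -> pd.Series:
    if min_samples != 1:
        epochs = epochs.copy()
        for m in METRICS:
            epochs[f"{m}_valid"] = epochs[f"{m}_n"] >= min_samples
    return worn_mask(epochs)


def _stratified_pct(valid: pd.Series, masks: dict) -> dict:
    out = {}
    for name, mask in masks.items():
        denom = int(mask.sum())
        out[name] = float(100.0 * valid[mask].sum() / denom) if denom else float("nan")
    return out


def quality_report(
    record: WearRecord,
    ranges: dict | None = None,
    ectopic_threshold: float = DEFAULT_ECTOPIC_THRESHOLD,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    min_hrv_beats: int = DEFAULT_MIN_HRV_BEATS,
    over_worn_only: bool = True,
) -> QualityReport:
    """Clean, window, and summarize one participant's record.

    Valid-window percentages are reported for each metric and for "hrv"
    (windows with enough NN beats to support HRV), over worn windows by
    default, split by rest/active.  Strata with no windows are reported as
    NaN rather than 0.
    """
    cleaned, results = clean_record(record, ranges)
    t0, t1 = wear_period(cleaned)
    epochs = epoch_frame(cleaned, 300, span=(t0, t1))
    worn = _apply_min_samples(epochs, min_samples)

    base = worn if over_worn_only else pd.Series(True, index=epochs.index)
    masks = {
        "overall": base,
        "rest": base & (epochs["activity_state"] == REST),
        "active": base & (epochs["activity_state"] == ACTIVE),
    }

    pct_valid: dict[str, dict] = {}
    pct_valid["hrv"] = _stratified_pct(epochs["bbi_n"] >= min_hrv_beats, masks)
    for metric in METRICS:
        if record.streams.get(metric) is None:
            pct_valid[metric] = {k: float("nan") for k in masks}
        else:
            pct_valid[metric] = _stratified_pct(epochs[f"{metric}_valid"], masks)

    return QualityReport(
        participant_id=record.participant_id,
        wear_duration_days=(t1 - t0) / 86400.0,
        compliance_pct=float(100.0 * worn.sum() / len(epochs)),
        pct_correction={m: r.pct_correction for m, r in results.items()},
        pct_valid_windows=pct_valid,
        n_windows=len(epochs),
        n_worn=int(worn.sum()),
    )


def render_report(report: QualityReport, decimals: int = 1) -> str:
    """Human-readable quality table, rest/active as columns."""
    def fmt(x):
        return "—" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.{decimals}f}"

    lines = [
        f"Participant: {report.participant_id}",
        f"Wear duration: {report.wear_duration_days:.2f} days",
        f"Wear compliance: {report.compliance_pct:.{decimals}f}% "
        f"({report.n_worn}/{report.n_windows} five-minute windows)",
        "",
        f"{'':28s}{'Rest (%)':>10s}{'Active (%)':>12s}{'Overall (%)':>13s}",
    ]
    bbi_corr = report.pct_correction.get("bbi", float("nan"))
    lines.append(f"{'% Correction (beats)':28s}{fmt(bbi_corr):>10s}{fmt(bbi_corr):>12s}{fmt(bbi_corr):>13s}")
    labels = {"hrv": "% Valid HRV windows", "rr": "% Valid RR windows",
              "spo2": "% Valid SpO2 windows", "steps": "% Valid step windows",
              "bbi": "% Valid BBI windows"}
    for metric in REPORT_METRICS:
        strata = report.pct_valid_windows.get(metric, {})
        lines.append(
            f"{labels[metric]:28s}{fmt(strata.get('rest')):>10s}"
            f"{fmt(strata.get('active')):>12s}{fmt(strata.get('overall')):>13s}"
        )
    return "\n".join(lines) + "\n"
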