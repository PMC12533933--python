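"""Time- and frequency-domain heart rate variability on 5-minute windows.

Time domain: SDNN (sample SD of NN intervals), RMSSD (root mean square of
successive differences), and pNN50 (percent of successive differences whose
magnitude exceeds 50 ms).

Frequency domain: band powers of the NN tachogram over LF (0.04-0.15 Hz) and
HF (0.15-0.40 Hz) and their ratio.  The default spectral estimator is a
Lomb-Scargle periodogram evaluated directly on the unevenly sampled beat
times — no resampling, hence no interpolation bias on irregular beats — and
scaled to a one-sided power spectral density in ms^2/Hz so that band
integrals are variances.  A cubic-spline-resampled Welch estimator is
available as an alternative backend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import lombscargle, welch

from .io_ingest import SampleStream
from .windowing import window_grid

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: Minimum NN beats for a stable 5-minute spectrum (~24 bpm floor).
DEFAULT_MIN_BEATS = 120

#: Resampling rate for the Welch backend (Hz).
WELCH_FS = 4.0


@dataclass
class HrvWindow:
    window_start: float
    n_beats: int
    mean_nn: float = float("nan")
    sdnn: float = float("nan")
    rmssd: float = float("nan")
    pnn50: float = float("nan")
    lf_power: float = float("nan")
    hf_power: float = float("nan")
    lf_hf_ratio: float = float("nan")
    valid: bool = False


def time_domain(nn: np.ndarray) -> tuple[float, float, float, float]:
    """(mean_nn, sdnn, rmssd, pnn50) of one window's NN intervals (ms)."""
    nn = np.asarray(nn, dtype=float)
    if nn.size < 2:
        raise ValueError("need at least 2 NN intervals")
    diffs = np.diff(nn)
    mean_nn = float(np.mean(nn))
    sdnn = float(np.std(nn, ddof=1))
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    pnn50 = float(100.0 * np.count_nonzero(np.abs(diffs) > 50.0) / diffs.size)
    return mean_nn, sdnn, rmssd, pnn50


def _lomb_psd(t: np.ndarray, x: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """One-sided PSD (ms^2/Hz) via Lomb-Scargle on uneven samples.

    The raw periodogram peak for a sinusoid of amplitude A is A^2*N/4; a
    spectral peak of effective width 1/T must integrate to the tone variance
    A^2/2, giving the density scale 2*T/N.
    """
    x = x - np.mean(x)
    if np.allclose(x, 0.0):
        return np.zeros_like(freqs)
    span = t[-1] - t[0]
    p = lombscargle(t, x, 2.0 * np.pi * freqs)
    return p * (2.0 * span / t.size)


def freq_domain(
    beat_times: np.ndarray,
    nn: np.ndarray,
    backend: str = "lombscargle",
) -> tuple[float, float, float]:
    """(lf_power, hf_power, lf_hf_ratio) of one window's tachogram.

    ``beat_times`` are the beat timestamps in seconds; ``nn`` the NN
    intervals in ms.  Powers are band-integrated variance in ms^2; the ratio
    is NaN when HF power is zero.
    """
    t = np.asarray(beat_times, dtype=float)
    x = np.asarray(nn, dtype=float)
    if t.size != x.size or t.size < 4:
        raise ValueError("need >= 4 beats with matching timestamps")
    t = t - t[0]
    span = t[-1]
    if span <= 0:
        raise ValueError("window has zero duration")

    if backend == "lombscargle":
        df = 1.0 / (4.0 * span)
        freqs = np.arange(df, 0.5 + df, df)
        psd = _lomb_psd(t, x, freqs)
    elif backend == "welch":
        grid = np.arange(0.0, span, 1.0 / WELCH_FS)
        resampled = CubicSpline(t, x)(grid)
        nperseg = min(resampled.size, 512)
        freqs, psd = welch(resampled - resampled.mean(), fs=WELCH_FS, nperseg=nperseg)
    else:
        raise ValueError(f"unknown spectral backend {backend!r}")

    def band_power(lo, hi):
        mask = (freqs >= lo) & (freqs < hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    lf = band_power(*LF_BAND)
    hf = band_power(*HF_BAND)
    ratio = lf / hf if hf > 0 else float("nan")
    return lf, hf, ratio


def hrv_windows(
    nn_stream: SampleStream,
    width: int = 300,
    min_beats: int = DEFAULT_MIN_BEATS,
    backend: str = "lombscargle",
    span: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-window HRV table over a cleaned NN stream.

    Windows with fewer than *min_beats* NN intervals are marked invalid and
    carry no metrics; this count feeds the "% valid HRV windows" quality
    figure.
    """
    if nn_stream.metric != "bbi":
        raise ValueError("HRV requires the cleaned beat-to-beat (NN) stream")
    t, x = nn_stream.timestamps, nn_stream.values
    if span is None:
        if t.size == 0:
            raise ValueError("empty NN stream")
        span = (t[0], t[-1])
    rows = []
    for start in window_grid(span[0], span[1], width):
        mask = (t >= start) & (t < start + width)
        n = int(mask.sum())
        win = HrvWindow(window_start=float(start), n_beats=n)
        if n >= max(min_beats, 4):
            win.mean_nn, win.sdnn, win.rmssd, win.pnn50 = time_domain(x[mask])
            win.lf_power, win.hf_power, win.lf_hf_ratio = freq_domain(t[mask], x[mask], backend)
            win.valid = True
        rows.append(win)
    return pd.DataFrame([vars(w) for w in rows])
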