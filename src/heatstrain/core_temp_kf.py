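"""Extended Kalman filter estimation of core body temperature from heart rate.

Minute-resolution heart rate is related to core temperature through a
quadratic observation model m(CT) = a0 + a1*CT + a2*CT**2 (bpm), increasing
over the physiologic range.  Core temperature itself evolves as a random
walk with process-noise SD ``gamma`` per minute.  Each minute the filter
performs:

    time update:         ct- = ct,            v- = v + gamma**2
    linearization:       c   = a1 + 2*a2*ct-
    gain:                k   = v- * c / (c**2 * v- + sigma**2)
    observation update:  ct  = ct- + k * (hr - m(ct-)),  v = (1 - k*c) * v-

Minutes with missing or out-of-range heart rate apply the time update only,
so uncertainty grows honestly across non-wear gaps instead of being papered
over by interpolated heart rate.

The default coefficients follow the field-standard heart-rate-only estimator
developed at USARIEM (initial state 37.0 degC, v0 = 0, gamma = 0.022 degC,
sigma = 18.88 bpm, m(CT) = -7887.1 + 384.4286*CT - 4.5714*CT**2); all are
configuration-exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Heart-rate validity bounds (bpm) — observations outside are treated as missing.
HR_VALID_BPM = (40.0, 200.0)

#: Default sustained-exertion heart-rate threshold (bpm).
DEFAULT_EXERTION_THRESHOLD_BPM = 125.0


@dataclass(frozen=True)
class KfParams:
    """Filter parameters.

    ct0 : initial core temperature (degC)
    v0 : initial state variance (degC^2)
    gamma : process-noise SD per minute (degC)
    sigma : observation-noise SD (bpm)
    a0, a1, a2 : quadratic observation-model coefficients (CT degC -> HR bpm)
    """

    ct0: float = 37.0
    v0: float = 0.0
    gamma: float = 0.022
    sigma: float = 18.88
    a0: float = -7887.1
    a1: float = 384.4286
    a2: float = -4.5714

    def __post_init__(self):
        if self.gamma <= 0 or self.sigma <= 0 or self.v0 < 0:
            raise ValueError("require gamma > 0, sigma > 0, v0 >= 0")
        ct = np.linspace(36.0, 41.0, 51)
        slope = self.a1 + 2.0 * self.a2 * ct
        if np.any(slope <= 0):
            raise ValueError("observation model must be strictly increasing on 36-41 degC")

    def observe(self, ct):
        """Expected heart rate m(CT) in bpm."""
        ct = np.asarray(ct, dtype=float)
        return self.a0 + self.a1 * ct + self.a2 * ct**2

    def invert(self, hr):
        """Core temperature at which the model predicts *hr* (upper branch root)."""
        hr = np.asarray(hr, dtype=float)
        disc = self.a1**2 - 4.0 * self.a2 * (self.a0 - hr)
        if np.any(disc < 0):
            raise ValueError("heart rate outside the observation model's range")
        # a2 < 0: the physiologic root is the smaller of the two.
        return (-self.a1 + np.sqrt(disc)) / (2.0 * self.a2)


def kf_step(prev: tuple[float, float], hr_obs, params: KfParams) -> tuple[float, float]:
    """One filter minute: time update plus, if *hr_obs* is usable, the
    linearized observation update.

    Observations outside the HR validity range are treated as missing (with a
    warning), leaving only the time update; the posterior variance after an
    observation update never exceeds the predicted prior variance.
    """
    ct, v = prev
    if v < 0:
        raise ValueError("state variance must be non-negative")
    ct_pred = ct
    v_pred = v + params.gamma**2
    if hr_obs is None or not np.isfinite(hr_obs):
        return ct_pred, v_pred
    if not (HR_VALID_BPM[0] <= hr_obs <= HR_VALID_BPM[1]):
        logger.warning("HR observation %.1f bpm outside %s; treated as missing", hr_obs, HR_VALID_BPM)
        return ct_pred, v_pred
    c = params.a1 + 2.0 * params.a2 * ct_pred
    k = v_pred * c / (c**2 * v_pred + params.sigma**2)
    ct_new = ct_pred + k * (hr_obs - float(params.observe(ct_pred)))
    v_new = (1.0 - k * c) * v_pred
    return float(ct_new), float(v_new)


def run_estimator(
    times: np.ndarray,
    hr: np.ndarray,
    params: KfParams | None = None,
    init_mode: str = "fixed_37",
    reference_temps: pd.DataFrame | None = None,
    threshold_bpm: float = DEFAULT_EXERTION_THRESHOLD_BPM,
) -> pd.DataFrame:
    """Run the filter over a 1-minute heart-rate series.

    Parameters
    ----------
    times, hr
        Minute timestamps (seconds, ascending) and the 60-s average heart
        rate; NaN marks missing minutes.  Internal minutes absent from
        *times* are filled in as gaps.
    init_mode
        ``"fixed_37"`` starts at params.ct0; ``"first_reference"`` starts at
        the first reference temperature.
    reference_temps
        DataFrame with columns timestamp, temp_c (required for
        ``first_reference``).

    Returns
    -------
    DataFrame with one row per minute: timestamp, hr_bpm, ct_est, ct_var,
    gap, above_threshold.  The first row is the initialization state, before
    any observation update.
    """
    params = params or KfParams()
    times = np.asarray(times, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if times.size == 0:
        raise ValueError("empty heart-rate series")
    if times.shape != hr.shape:
        raise ValueError("times and hr must have equal length")

    grid = np.arange(times[0], times[-1] + 60.0, 60.0)
    hr_grid = np.full(grid.size, np.nan)
    idx = np.round((times - times[0]) / 60.0).astype(int)
    hr_grid[idx] = hr

    if init_mode == "fixed_37":
        ct = params.ct0
    elif init_mode == "first_reference":
        if reference_temps is None or len(reference_temps) == 0:
            raise ValueError("first_reference initialization needs at least one reference temperature")
        ct = float(reference_temps["temp_c"].iloc[0])
    else:
        raise ValueError(f"unknown init_mode {init_mode!r}")
    v = params.v0

    ct_est = np.empty(grid.size)
    ct_var = np.empty(grid.size)
    ct_est[0], ct_var[0] = ct, v  # initialization emitted before any update
    for i in range(1, grid.size):
        obs = hr_grid[i] if np.isfinite(hr_grid[i]) else None
        ct, v = kf_step((ct, v), obs, params)
        ct_est[i], ct_var[i] = ct, v

    usable = np.isfinite(hr_grid) & (hr_grid >= HR_VALID_BPM[0]) & (hr_grid <= HR_VALID_BPM[1])
    return pd.DataFrame(
        {
            "timestamp": grid,
            "hr_bpm": hr_grid,
            "ct_est": ct_est,
            "ct_var": ct_var,
            "gap": ~usable,
            "above_threshold": usable & (hr_grid >= threshold_bpm),
        }
    )


def exertion_summary(trace: pd.DataFrame, threshold_bpm: float = DEFAULT_EXERTION_THRESHOLD_BPM) -> dict:
    """Sustained-exertion figures over an estimator trace.

    Returns max observed HR (bpm), total time at or above the threshold
    (hours, counted in whole minutes), and the maximum estimated core
    temperature (degC).
    """
    hr = trace["hr_bpm"].to_numpy()
    finite = np.isfinite(hr)
    max_hr = float(np.nanmax(hr)) if finite.any() else float("nan")
    minutes_above = int(np.sum(finite & (hr >= threshold_bpm)))
    return {
        "max_hr_bpm": max_hr,
        "time_above_threshold_h": minutes_above / 60.0,
        "max_ect_c": float(trace["ct_est"].max()),
        "threshold_bpm": float(threshold_bpm),
    }


def bias_vs_reference(
    trace: pd.DataFrame,
    reference_temps: pd.DataFrame,
    tolerance_s: float = 300.0,
    skip_first: bool = False,
    return_all: bool = False,
):
    """Mean (estimate - reference) over the reference measurements.

    Each reference is matched to the nearest trace minute within
    *tolerance_s* (spot checks are hand-timed).  Positive bias means the
    filter overestimates.  ``skip_first`` drops the first reference, for
    records whose filter was initialized to it.  With ``return_all`` the
    per-measurement deviations are returned alongside the mean, supporting a
    per-participant averaging scheme at cohort level.
    """
    refs = reference_temps.iloc[1:] if skip_first else reference_temps
    if len(refs) == 0:
        raise ValueError("no reference temperatures to compare against")
    t = trace["timestamp"].to_numpy()
    deviations = []
    for _, row in refs.iterrows():
        i = int(np.argmin(np.abs(t - row["timestamp"])))
        if abs(t[i] - row["timestamp"]) > tolerance_s:
            continue
        deviations.append(float(trace["ct_est"].iloc[i] - row["temp_c"]))
    if not deviations:
        raise ValueError("no reference temperature falls within the trace (post-initialization)")
    mean_bias = float(np.mean(deviations))
    return (mean_bias, np.array(deviations)) if return_all else mean_bias
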