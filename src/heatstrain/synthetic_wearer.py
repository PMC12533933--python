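"""Device-realistic synthetic wearable records with known ground truth.

The generator emulates what a multi-metric optical smartwatch exports during
occupational wear under protective equipment: four streams (step cadence,
respiration rate, SpO2 at 60-s cadence; beat-to-beat intervals per heartbeat)
with physiologic artifacts, non-wear gaps, and sparse reference temperatures
— plus the latent truth (activity intensity, true heart rate, true core
temperature) that the device never sees directly.

Physiology model: true core temperature relaxes first-order (time constant
~25 min) toward a target affine in activity intensity, and heart rate is tied
to core temperature through the same quadratic observation model the
core-temperature filter uses.  The target is obtained by inverting that model
at ``hr_rest + intensity * hr_range``, so estimator recovery on generated
data is well-posed by construction.  Each minute's mean beat-to-beat interval
equals 60000 / heart-rate plus sinusoidal LF/HF variability modulation.

All randomness flows from one seed through deterministically derived
substreams: identical configurations reproduce identical records bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_temp_kf import KfParams
from .io_ingest import SampleStream, WearRecord
from .signal_qc import DEFAULT_RANGES

#: Epoch-second origin of generated records; a multiple of 300 s so generated
#: streams land on whole 5-minute windows.
T0_EPOCH = 1_600_000_200.0

#: Margin (in metric units) kept inside the valid range by clean samples, so
#: injected artifacts are the only out-of-range values.
_CLEAN_MARGIN = {"steps": 2.0, "rr": 0.5, "spo2": 0.0, "bbi": 20.0}


@dataclass
class ScenarioConfig:
    """Study-scenario description; defaults sketch an 8-hour field shift."""

    duration_h: float = 8.0
    seed: int = 0
    #: (start_h, end_h, intensity in [0, 1]) blocks; outside blocks = rest.
    activity_schedule: list = field(default_factory=lambda: [(1.0, 3.0, 0.7), (5.0, 7.0, 0.5)])
    hr_rest: float = 78.0
    hr_range: float = 60.0
    hr_noise_sd: float = 3.0
    #: (lf_amp ms, lf_freq Hz, hf_amp ms, hf_freq Hz) tachogram modulation.
    hrv_mod: tuple = (25.0, 0.10, 35.0, 0.25)
    artifact_rate: float = 0.0
    #: (start_h, end_h) spans during which all four streams are blank.
    nonwear_windows: list = field(default_factory=list)
    spo2_base: float = 97.0
    spo2_drop_active: float = 0.0
    rr_rest: float = 14.0
    rr_active: float = 30.0
    steps_active: float = 20.0  # steps/min at intensity 1
    ct_tau_min: float = 25.0
    participant_id: str = "SYN001"
    device_uuid: str = "synthetic-device"

    def __post_init__(self):
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must be in [0, 1)")
        for spans, what in ((self.activity_schedule, "activity block"), (self.nonwear_windows, "non-wear span")):
            prev_end = None
            for entry in sorted(spans):
                start, end = entry[0], entry[1]
                if not (0.0 <= start < end <= self.duration_h):
                    raise ValueError(f"{what} ({start}, {end}) outside [0, {self.duration_h}] h")
                if prev_end is not None and start < prev_end:
                    raise ValueError(f"overlapping {what}s at {start} h")
                prev_end = end
        for entry in self.activity_schedule:
            if not 0.0 <= entry[2] <= 1.0:
                raise ValueError("activity intensity must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Latent state emitted alongside a generated record."""

    #: per minute: timestamp, intensity, true_ct (degC), true_hr (bpm), worn
    minutes: pd.DataFrame
    #: metric -> indices of injected artifact samples in the emitted stream
    artifact_indices: dict
    config: ScenarioConfig


def _intensity_per_minute(config: ScenarioConfig, n_min: int) -> np.ndarray:
    intensity = np.zeros(n_min)
    minute_h = (np.arange(n_min) + 0.5) / 60.0
    for start, end, level in config.activity_schedule:
        intensity[(minute_h >= start) & (minute_h < end)] = level
    return intensity


def _worn_per_minute(config: ScenarioConfig, n_min: int) -> np.ndarray:
    worn = np.ones(n_min, dtype=bool)
    minute_h = (np.arange(n_min) + 0.5) / 60.0
    for start, end in config.nonwear_windows:
        worn[(minute_h >= start) & (minute_h < end)] = False
    return worn


def true_state(config: ScenarioConfig, kf_params: KfParams | None = None):
    """Minute-resolution latent (intensity, core temperature, heart rate)."""
    kf_params = kf_params or KfParams()
    n_min = int(round(config.duration_h * 60.0))
    intensity = _intensity_per_minute(config, n_min)
    hr_target = config.hr_rest + intensity * config.hr_range
    ct_target = kf_params.invert(hr_target)
    ct = np.empty(n_min)
    ct[0] = float(kf_params.invert(config.hr_rest))
    for i in range(1, n_min):
        ct[i] = ct[i - 1] + (ct_target[i] - ct[i - 1]) / config.ct_tau_min
    true_hr = np.asarray(kf_params.observe(ct), dtype=float)
    return intensity, ct, true_hr


def hr_from_observation_model(
    true_ct: np.ndarray, params: KfParams, noise_sd: float, seed: int
) -> np.ndarray:
    """Minute heart-rate observations drawn from the filter's own model."""
    rng = np.random.default_rng(seed)
    return np.asarray(params.observe(true_ct), dtype=float) + rng.normal(0.0, noise_sd, np.asarray(true_ct).size)


def _inject_artifacts(metric: str, values: np.ndarray, rate: float, rng) -> np.ndarray:
    """Overwrite a random fraction of samples with strictly out-of-range values."""
    if rate <= 0 or values.size == 0:
        return np.array([], dtype=int)
    hit = np.flatnonzero(rng.random(values.size) < rate)
    if hit.size == 0:
        return hit
    lo, hi = DEFAULT_RANGES[metric]
    if metric == "bbi":
        low = rng.uniform(100.0, lo - 10.0, hit.size)
        high = rng.uniform(hi + 10.0, 2500.0, hit.size)
        values[hit] = np.where(rng.random(hit.size) < 0.5, low, high)
    elif metric == "steps":
        values[hit] = rng.uniform(hi + 10.0, 400.0, hit.size)
    elif metric == "rr":
        values[hit] = rng.uniform(hi + 5.0, 120.0, hit.size)
    else:  # spo2
        values[hit] = rng.uniform(20.0, lo - 5.0, hit.size)
    return hit


def generate(config: ScenarioConfig, kf_params: KfParams | None = None):
    """Generate one participant's device record plus its ground truth.

    Returns ``(WearRecord, SyntheticTruth)``.  Artifacts are injected
    uniformly at ``config.artifact_rate`` per sample as values strictly
    outside the validity ranges; non-wear spans blank all four streams.
    """
    kf_params = kf_params or KfParams()
    ss = np.random.SeedSequence(config.seed)
    rng_hr, rng_bbi, rng_steps, rng_rr, rng_spo2, rng_art = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    n_min = int(round(config.duration_h * 60.0))
    intensity, ct, true_hr = true_state(config, kf_params)
    worn_min = _worn_per_minute(config, n_min)
    minute_t = T0_EPOCH + 60.0 * np.arange(n_min)

    # observed minute heart rate drives the emitted beat stream
    hr_obs = true_hr + rng_hr.normal(0.0, config.hr_noise_sd, n_min)
    hr_obs = np.clip(hr_obs, 45.0, 190.0)

    lf_amp, lf_freq, hf_amp, hf_freq = config.hrv_mod
    bbi_lo = DEFAULT_RANGES["bbi"][0] + _CLEAN_MARGIN["bbi"]
    bbi_hi = DEFAULT_RANGES["bbi"][1] - _CLEAN_MARGIN["bbi"]
    beat_t, beat_v = [], []
    t = 0.0
    end_s = n_min * 60.0
    while t < end_s:
        i = min(int(t // 60.0), n_min - 1)
        nn = 60000.0 / hr_obs[i]
        nn += lf_amp * np.sin(2.0 * np.pi * lf_freq * t)
        nn += hf_amp * np.sin(2.0 * np.pi * hf_freq * t)
        nn += rng_bbi.normal(0.0, 4.0)
        nn = float(np.clip(nn, bbi_lo, bbi_hi))
        if worn_min[i]:
            beat_t.append(T0_EPOCH + t)
            beat_v.append(nn)
        t += nn / 1000.0

    steps = np.where(
        intensity > 0,
        np.clip(np.round(intensity * config.steps_active + rng_steps.normal(0.0, 1.0, n_min)), 0, 218),
        0.0,
    )
    rr = np.clip(
        config.rr_rest + intensity * (config.rr_active - config.rr_rest) + rng_rr.normal(0.0, 1.0, n_min),
        DEFAULT_RANGES["rr"][0] + _CLEAN_MARGIN["rr"],
        DEFAULT_RANGES["rr"][1] - _CLEAN_MARGIN["rr"],
    )
    spo2 = np.clip(config.spo2_base + rng_spo2.normal(0.0, 0.8, n_min), 88.0, 100.0)
    spo2_keep = worn_min & ~(
        (intensity > 0) & (rng_spo2.random(n_min) < config.spo2_drop_active)
    )

    streams = {
        "bbi": (np.asarray(beat_t), np.asarray(beat_v)),
        "steps": (minute_t[worn_min], steps[worn_min]),
        "rr": (minute_t[worn_min], rr[worn_min]),
        "spo2": (minute_t[spo2_keep], spo2[spo2_keep]),
    }
    artifact_indices = {}
    record_streams = {}
    for metric, (ts, vs) in streams.items():
        vs = np.asarray(vs, dtype=float).copy()
        artifact_indices[metric] = _inject_artifacts(metric, vs, config.artifact_rate, rng_art)
        record_streams[metric] = SampleStream(metric, ts, vs)

    record = WearRecord(config.participant_id, config.device_uuid, record_streams)
    truth = SyntheticTruth(
        minutes=pd.DataFrame(
            {
                "timestamp": minute_t,
                "intensity": intensity,
                "true_ct": ct,
                "true_hr": true_hr,
                "worn": worn_min,
            }
        ),
        artifact_indices=artifact_indices,
        config=config,
    )
    return record, truth


def reference_temps_from_truth(
    truth: SyntheticTruth, every_min: int = 30, noise_sd_c: float = 0.2, seed: int = 0
) -> pd.DataFrame:
    """Sparse spot-check temperatures: truth plus tympanic-scale noise."""
    rng = np.random.default_rng(seed)
    rows = truth.minutes.iloc[::every_min]
    return pd.DataFrame(
        {
            "timestamp": rows["timestamp"].to_numpy(),
            "temp_c": rows["true_ct"].to_numpy() + rng.normal(0.0, noise_sd_c, len(rows)),
        }
    )


PRESETS = ("multiday_fieldwork", "recruit_training_3p5h", "inactive_control")


def preset(name: str, seed: int = 0) -> ScenarioConfig:
    """Named scenarios shaped like the two field deployments.

    ``multiday_fieldwork`` — 4.25 days of continuous wear with daily work
    blocks, sleep, and short aligned non-wear gaps (e.g. washing).
    ``recruit_training_3p5h`` — a single 3.5-hour high-intensity session with
    a mid-session water break at roughly the halfway point.
    ``inactive_control`` — a 3.5-hour low-activity session (mean step rate
    about 4.5 steps/min) with the loose-fit artifact rate at the top of the
    observed band.
    """
    if name == "multiday_fieldwork":
        days = 4.25
        schedule, nonwear = [], []
        for d in range(4):
            schedule += [(d * 24 + 9.0, d * 24 + 11.0, 0.75), (d * 24 + 13.0, d * 24 + 15.5, 0.87)]
            nonwear.append((d * 24 + 7.0, d * 24 + 7.5))
        return ScenarioConfig(
            duration_h=days * 24.0,
            seed=seed,
            activity_schedule=schedule,
            nonwear_windows=nonwear,
            artifact_rate=0.073,
            spo2_drop_active=0.05,
            participant_id="SYN-MULTIDAY",
        )
    if name == "recruit_training_3p5h":
        return ScenarioConfig(
            duration_h=3.5,
            seed=seed,
            activity_schedule=[(0.0, 1.65, 0.8), (1.85, 3.5, 0.8)],
            artifact_rate=0.065,
            spo2_drop_active=0.26,
            participant_id="SYN-RECRUIT",
        )
    if name == "inactive_control":
        return ScenarioConfig(
            duration_h=3.5,
            seed=seed,
            activity_schedule=[(0.25, 3.4, 0.25)],
            hr_range=30.0,
            artifact_rate=0.093,
            participant_id="SYN-CONTROL",
        )
    raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")


def with_seed(config: ScenarioConfig, seed: int) -> ScenarioConfig:
    return replace(config, seed=seed)
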