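"""Run configuration: defaults plus YAML overrides.

Every tunable the pipeline exposes lives in one nested mapping so a single
YAML file can reproduce a run.  Unknown keys are rejected — silent typos in a
monitoring configuration are worse than a hard error.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .core_temp_kf import DEFAULT_EXERTION_THRESHOLD_BPM, KfParams
from .hrv import DEFAULT_MIN_BEATS
from .signal_qc import DEFAULT_ECTOPIC_THRESHOLD, DEFAULT_RANGES
from .wear_compliance import DEFAULT_MIN_HRV_BEATS, DEFAULT_MIN_SAMPLES


def default_config() -> dict:
    return {
        "qc": {
            "ranges": {m: {"lo": lo, "hi": hi} for m, (lo, hi) in DEFAULT_RANGES.items()},
            "ectopic_threshold": DEFAULT_ECTOPIC_THRESHOLD,
        },
        "compliance": {
            "min_samples": DEFAULT_MIN_SAMPLES,
            "min_hrv_beats": DEFAULT_MIN_HRV_BEATS,
            "over_worn_only": True,
        },
        "ecbt": {
            "ct0": 37.0,
            "v0": 0.0,
            "gamma": 0.022,
            "sigma": 18.88,
            "a0": -7887.1,
            "a1": 384.4286,
            "a2": -4.5714,
            "init_mode": "fixed_37",
            "threshold_bpm": DEFAULT_EXERTION_THRESHOLD_BPM,
        },
        "hrv": {
            "min_beats": DEFAULT_MIN_BEATS,
            "backend": "lombscargle",
        },
        "report": {
            "decimals": 1,
        },
    }


def _merge(base: dict, override: dict, path: str = "") -> dict:
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config key {here!r} must be a mapping")
            _merge(base[key], value, here)
        else:
            base[key] = value
    return base


def load_config(path=None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    cfg = default_config()
    if path is not None:
        text = Path(path).read_text()
        override = yaml.safe_load(text) or {}
        if not isinstance(override, dict):
            raise ValueError(f"{path}: top level must be a mapping")
        _merge(cfg, override)
    return cfg


def kf_params_from(cfg: dict) -> KfParams:
    e = cfg["ecbt"]
    return KfParams(
        ct0=e["ct0"], v0=e["v0"], gamma=e["gamma"], sigma=e["sigma"],
        a0=e["a0"], a1=e["a1"], a2=e["a2"],
    )


def ranges_from(cfg: dict) -> dict:
    return {m: (r["lo"], r["hi"]) for m, r in cfg["qc"]["ranges"].items()}
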