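"""Configuration loading and validation.

One shared YAML/JSON schema covers all pipeline stages.  Loading injects
defaults section by section, rejects unknown keys by name, and runs the
same invariant checks the in-memory types enforce (a bad value fails at
load time, not mid-pipeline).  Time is always minutes on the
gastrulation-anchored clock; positions are %EL with anterior = 100.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .circuit import AxisGrid
from .errors import ConfigurationError
from .ms2 import TrackingConfig
from .perturb import CriterionThresholds
from .synth import SynthMovieConfig
from .timeline import IlluminationScenario, default_battery

DEFAULTS: dict = {
    "grid": {"n_bins": 200, "bin_width": 0.5, "embryo_length": 500.0},
    "simulate": {"t_start": -90.0, "t_end": 0.0, "dt": 0.01,
                 "save_every": 1.0},
    "scenarios": {"battery": ["1", "2", "3", "4", "5", "6"],
                  "windows": {},           # id -> [[start, end], ...]
                  "score_scenario": "5"},
    "thresholds": {"shift_el": 1.0, "level_reduction_frac": 0.10},
    "tracking": {"intensity_threshold": 100.0, "spot_size_n": 3,
                 "max_displacement_px": 5.0, "contrast_threshold": 50.0,
                 "min_duration_s": 160.0, "duration_convention": "count"},
    "movie": {"width": 256, "height": 128, "n_frames": 24,
              "frame_interval_s": 40.0, "n_nuclei": 12,
              "spot_probability": 0.85, "persistence_mean_min": 7.1,
              "persistence_sd_min": 3.2, "spot_amplitude": 800.0,
              "spot_sigma_px": 1.2, "noise_sd": 10.0,
              "poisson_noise": False, "drift_px_per_frame": 0.3,
              "min_separation_px": 16.0, "ap_el_range": [100.0, 40.0]},
    "gradient": {"n_nuclei": 500, "noise_sd": 0.05, "amplitude": 1000.0,
                 "length_scale": 80.0, "offset": 0.0},
    "profile": {"bin_width_um": 5.0, "with_offset": True},
    "ensemble": {"n": 21, "jitter": 0.15, "min_criteria": 3,
                 "z_denominator": "sqrt_n"},
    "chip": {"input_fraction_percent": 2.0},
}


def _merge_section(name: str, defaults: dict, user: dict) -> dict:
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in section '{name}': {sorted(unknown)}")
    return {**defaults, **user}


def load_config(path: str | Path | None = None) -> dict:
    """Load, default-fill, and validate a pipeline configuration.

    ``None`` or an empty file yields the full default configuration.
    Raises :class:`ConfigurationError` naming the offending section/key
    on unknown keys or invariant violations.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("top-level config must be a mapping")
    unknown = set(raw) - set(DEFAULTS)
    if unknown:
        raise ConfigurationError(f"unknown top-level section(s): {sorted(unknown)}")
    cfg = {name: _merge_section(name, section, raw.get(name, {}))
           for name, section in DEFAULTS.items()}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Run the domain-type invariants over a merged configuration."""
    try:
        grid_from_config(cfg)
        tracking_from_config(cfg)
        movie_from_config(cfg, seed=0)
        scenarios_from_config(cfg)
        thresholds_from_config(cfg)
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(str(exc)) from exc
    sim = cfg["simulate"]
    if not (sim["t_start"] < sim["t_end"] <= 0):
        raise ConfigurationError("simulate: require t_start < t_end <= 0")
    if sim["dt"] <= 0 or sim["save_every"] <= 0:
        raise ConfigurationError("simulate: dt and save_every must be positive")
    ens = cfg["ensemble"]
    if ens["n"] < 1 or ens["jitter"] < 0:
        raise ConfigurationError("ensemble: n >= 1 and jitter >= 0 required")
    if ens["z_denominator"] not in ("sqrt_n", "n"):
        raise ConfigurationError("ensemble: z_denominator must be sqrt_n or n")


# -- typed accessors --------------------------------------------------------


def grid_from_config(cfg: dict) -> AxisGrid:
    return AxisGrid(**cfg["grid"])


def tracking_from_config(cfg: dict) -> TrackingConfig:
    return TrackingConfig(**cfg["tracking"])


def movie_from_config(cfg: dict, seed: int) -> SynthMovieConfig:
    kw = dict(cfg["movie"])
    kw["ap_el_range"] = tuple(kw["ap_el_range"])
    return SynthMovieConfig(seed=seed, **kw)


def thresholds_from_config(cfg: dict) -> CriterionThresholds:
    return CriterionThresholds(**cfg["thresholds"])


def scenarios_from_config(cfg: dict) -> list[IlluminationScenario]:
    """Resolve the scenario battery: named defaults plus custom windows."""
    stock = {s.id: s for s in default_battery()}
    custom = {sid: IlluminationScenario(id=sid, windows=tuple(map(tuple, wins)))
              for sid, wins in cfg["scenarios"]["windows"].items()}
    battery = []
    for sid in cfg["scenarios"]["battery"]:
        sid = str(sid)
        if sid in custom:
            battery.append(custom[sid])
        elif sid in stock:
            battery.append(stock[sid])
        else:
            raise ConfigurationError(f"unknown scenario id '{sid}'")
    return battery


def config_hash(cfg: dict) -> str:
    """Stable hash of a merged configuration (for run manifests)."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
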