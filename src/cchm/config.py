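"""Run configuration: schema-checked plain-text (YAML) config with full defaults.

Every run is reproducible from its config echo plus seeds; unknown keys are
rejected with the offending key path so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .breta import BretaParams
from .holo_sim import DriftProcess, NoiseModel, VirtualMicroscope, make_phase_object
from .signal_model import MisalignmentState, OpticsConfig, SourceModel

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "build_microscope"]


class ConfigError(ValueError):
    """Schema violation; the message names the offending key path."""


_DEFAULTS: Dict[str, Dict[str, Any]] = {
    "source": {
        "wavelength_nm": 650.0,
        "fwhm_nm": 10.0,
        "spectral_shape": "gaussian",
        "alpha": 2.5,
        "na_s": 0.30,
        "n": 1.0,
    },
    "optics": {
        "na": 0.30,
        "magnification": 10.0,
        "fc": None,  # None -> bin-aligned diagonal carrier, ~6 px/fringe
        "ni": 512,
        "nj": 512,
        "pixel_pitch_um": 6.0,
    },
    "actuators": {
        "o2_min_step_um": 0.05,
        "o2_travel_um": 250.0,
        "m2_min_step_um": 0.05,
        "m2_travel_um": 400.0,
    },
    "noise": {
        "read_noise_frac": 0.01,
        "shot_noise": False,
    },
    "state": {"xf": 0.0, "yf": 0.0, "dl": 0.0},
    "drift": {
        "ramp_um_per_tick": [0.05, 0.0, 0.15],
        "walk_std_um": [0.01, 0.01, 0.02],
    },
    "breta": {
        f.name: f.default for f in dataclasses.fields(BretaParams)
    },
    "seeds": {"simulation": 0, "misalignment": 0, "noise": 0},
    "output": {"out_dir": "."},
}


@dataclass
class RunConfig:
    """Materialized configuration: typed objects plus the raw echo dict."""

    source: SourceModel
    optics: OpticsConfig
    actuators: Dict[str, float]
    noise: NoiseModel
    state: MisalignmentState
    drift: DriftProcess
    breta: BretaParams
    seeds: Dict[str, int]
    output: Dict[str, str]
    echo: Dict[str, Any] = field(default_factory=dict)


def _merge(section: str, defaults: Dict[str, Any], user: Dict[str, Any]) -> Dict[str, Any]:
    out = copy.deepcopy(defaults)
    for key, val in (user or {}).items():
        if key not in defaults:
            raise ConfigError(f"unknown config key: {section}.{key}")
        out[key] = val
    return out


def _materialize(raw: Dict[str, Any]) -> RunConfig:
    for section in raw:
        if section not in _DEFAULTS:
            raise ConfigError(f"unknown config section: {section}")
    merged = {
        section: _merge(section, defaults, raw.get(section, {}))
        for section, defaults in _DEFAULTS.items()
    }

    src_kw = merged["source"]
    opt_kw = dict(merged["optics"])
    if src_kw["na_s"] > opt_kw["na"]:
        raise ConfigError(
            "source.na_s must not exceed optics.na "
            f"({src_kw['na_s']} > {opt_kw['na']})"
        )
    try:
        source = SourceModel(**src_kw)
        if opt_kw["fc"] is None:
            optics = OpticsConfig.bin_aligned(
                n=opt_kw["ni"],
                dx_object_um=opt_kw["pixel_pitch_um"] / opt_kw["magnification"],
                magnification=opt_kw["magnification"],
                na=opt_kw["na"],
            )
        else:
            opt_kw["fc"] = tuple(opt_kw["fc"])
            optics = OpticsConfig(**opt_kw)
        noise = NoiseModel(**merged["noise"])
        state = MisalignmentState(**merged["state"])
        drift = DriftProcess(
            ramp_um_per_tick=tuple(merged["drift"]["ramp_um_per_tick"]),
            walk_std_um=tuple(merged["drift"]["walk_std_um"]),
            seed=int(merged["seeds"]["simulation"]),
        )
        breta = BretaParams(**merged["breta"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    return RunConfig(
        source=source,
        optics=optics,
        actuators=dict(merged["actuators"]),
        noise=noise,
        state=state,
        drift=drift,
        breta=breta,
        seeds={k: int(v) for k, v in merged["seeds"].items()},
        output=dict(merged["output"]),
        echo=merged,
    )


def load_config(path) -> RunConfig:
    """Load, schema-check, and materialize a YAML run configuration."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return _materialize(raw)


def from_dict(raw: Optional[Dict[str, Any]] = None) -> RunConfig:
    """Materialize a config from an (optionally partial) dict."""
    return _materialize(raw or {})


def save_config(cfg: RunConfig, path) -> None:
    """Write the fully materialized config; load_config round-trips it."""
    Path(path).write_text(yaml.safe_dump(cfg.echo, sort_keys=True))


def build_microscope(cfg: RunConfig, phase_object_kind: str = "flat",
                     seed: Optional[int] = None,
                     state: Optional[MisalignmentState] = None) -> VirtualMicroscope:
    """Instantiate a virtual microscope from a run configuration."""
    optics = cfg.optics
    obj = make_phase_object(
        phase_object_kind, (optics.ni, optics.nj), optics.dx_object_um,
        seed=cfg.seeds["simulation"],
    )
    return VirtualMicroscope(
        source=cfg.source,
        optics=optics,
        state=(state or cfg.state).copy(),
        phase_object=obj,
        noise=cfg.noise,
        o2_min_step_um=cfg.actuators["o2_min_step_um"],
        o2_travel_um=cfg.actuators["o2_travel_um"],
        m2_min_step_um=cfg.actuators["m2_min_step_um"],
        m2_travel_um=cfg.actuators["m2_travel_um"],
        seed=cfg.seeds["noise"] if seed is None else seed,
    )
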