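"""YAML run configuration: schema validation and SI conversion.

A run configuration is a YAML document with the sections

    geometry, flow, particle, fluid, field, idt, gates, simulation, io

Every physical quantity is written with an explicit unit string
("0.08 ul/s", "135 MHz", "5 um") and converted to SI on load by the
:mod:`acoustosort.units` grammar — the configuration file is the only
place non-SI units appear.  Unknown sections or keys are rejected
outright rather than ignored, and validation happens before any
computation.  A SHA-256 hash of the canonical config is recorded in
reports so a run can be regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .acoustics import AcousticField, FluidSpec, IDTSpec, ParticleSpec
from .gating import Gate
from .sorter import ChannelGeometry, FlowConfig
from .units import UnitError, parse_quantity

__all__ = ["RunConfig", "ConfigError", "load_config", "config_hash"]


class ConfigError(ValueError):
    """A malformed or physically invalid run configuration."""


_SECTIONS = {"geometry", "flow", "particle", "fluid", "field", "idt",
             "gates", "simulation", "io"}

# section -> {key: default unit for bare numbers (None = dimensionless/text)}
_KEYS: dict[str, dict[str, str | None]] = {
    "geometry": {
        "deformation_channel_side": "um", "sorting_region_width": "um",
        "sorting_region_length": "um", "channel_height": "um",
        "bifurcation_offset": "um", "focal_zone_length": "um",
        "roi_to_sr_distance": "um", "sorting_region_volume": "nl",
    },
    "flow": {"sample_flow": "ul/s", "sheath_flow": "ul/s",
             "mean_velocity": "m/s"},
    "particle": {"diameter": "um", "density": "kg/m^3",
                 "compressibility": "1/Pa", "radiation_factor": None},
    "fluid": {"density": "kg/m^3", "compressibility": "1/Pa",
              "sound_speed": "m/s", "viscosity": "Pa s"},
    "field": {"mode": None, "frequency": "MHz", "wavelength": "um",
              "pressure_amplitude": "Pa", "energy_density": "J/m^3",
              "pulse_duration": "ms"},
    "idt": {"substrate_sound_speed": "m/s", "finger_periodicity": "um",
            "aperture": "um", "focal_length": "um", "design": None},
    "gates": {},     # list of gate mappings, validated separately
    "simulation": {"duration": "s", "concentration": "1/ml",
                   "mixture": None, "seed": None,
                   "coincidence_policy": None, "delay": "ms",
                   "actuation_success_prob": None,
                   "asf_displacement": "um"},
    "io": {"out_dir": None, "events_csv": None, "frames_tiff": None,
           "report_json": None},
}

_GATE_KEYS = {"label", "area_range", "deformation_max", "brightness_range",
              "area_ratio_max", "polygon"}


def _convert_section(name: str, data: dict) -> dict:
    allowed = _KEYS[name]
    out = {}
    for key, value in data.items():
        if key not in allowed:
            raise ConfigError(f"unknown key {key!r} in section {name!r} "
                              f"(allowed: {sorted(allowed)})")
        unit = allowed[key]
        if unit is None or isinstance(value, (dict, list)) or value is None:
            out[key] = value
        else:
            try:
                out[key] = parse_quantity(value, unit)
            except UnitError as exc:
                raise ConfigError(f"{name}.{key}: {exc}") from exc
    return out


def _build_gate(mapping: dict) -> Gate:
    unknown = set(mapping) - _GATE_KEYS
    if unknown:
        raise ConfigError(f"unknown gate keys {sorted(unknown)}")
    kwargs = dict(mapping)
    for rng_key in ("area_range", "brightness_range"):
        if kwargs.get(rng_key) is not None:
            kwargs[rng_key] = tuple(kwargs[rng_key])
    if kwargs.get("polygon") is not None:
        kwargs["polygon"] = tuple(tuple(v) for v in kwargs["polygon"])
    try:
        return Gate(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid gate: {exc}") from exc


@dataclass
class RunConfig:
    """A fully validated run configuration, quantities in SI."""

    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    flow: FlowConfig = field(default_factory=lambda: FlowConfig(0.01e-9, 0.07e-9))
    particle: ParticleSpec | None = None
    fluid: FluidSpec = field(default_factory=FluidSpec)
    acoustic_field: AcousticField | None = None
    idt: IDTSpec | None = None
    gates: tuple[Gate, ...] = ()
    simulation: dict = field(default_factory=dict)
    io: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @property
    def hash(self) -> str:
        return config_hash(self.raw)


def config_hash(raw: dict) -> str:
    canon = json.dumps(raw, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(source) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``source`` is a path, a file object or an already-parsed mapping.
    Raises :class:`ConfigError` on unknown sections/keys, bad units or
    physically invalid values.
    """
    if isinstance(source, dict):
        raw = source
    elif hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ConfigError(f"unknown configuration sections {sorted(unknown)}")

    cfg = RunConfig(raw=raw)
    try:
        if "geometry" in raw:
            cfg.geometry = ChannelGeometry(**_convert_section("geometry", raw["geometry"]))
        if "flow" in raw:
            cfg.flow = FlowConfig(**_convert_section("flow", raw["flow"]))
        if "particle" in raw:
            cfg.particle = ParticleSpec(**_convert_section("particle", raw["particle"]))
        if "fluid" in raw:
            cfg.fluid = FluidSpec(**_convert_section("fluid", raw["fluid"]))
        if "field" in raw:
            cfg.acoustic_field = AcousticField(**_convert_section("field", raw["field"]))
        if "idt" in raw:
            cfg.idt = IDTSpec(**_convert_section("idt", raw["idt"]))
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc

    gates = raw.get("gates", [])
    if not isinstance(gates, list):
        raise ConfigError("'gates' must be a list of gate mappings")
    cfg.gates = tuple(_build_gate(g) for g in gates)

    if "simulation" in raw:
        sim = _convert_section("simulation", raw["simulation"])
        policy = sim.get("coincidence_policy")
        if policy is not None and policy not in ("co-sort", "abort"):
            raise ConfigError("coincidence_policy must be 'co-sort' or 'abort'")
        mixture = sim.get("mixture")
        if mixture is not None:
            if not isinstance(mixture, dict) or not mixture:
                raise ConfigError("simulation.mixture must be a non-empty mapping")
            total = sum(mixture.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigError(f"mixture weights must sum to 1, got {total}")
        cfg.simulation = sim
    if "io" in raw:
        cfg.io = _convert_section("io", raw["io"])
    return cfg
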