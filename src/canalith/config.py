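"""Configuration files, schema validation, and output writing.

Configs are YAML or JSON with the sections ``canal``, ``materials``,
``scaling``, ``maneuver``, ``noise`` (optional), ``protocol`` and a top
level ``seed``.  Angles are in degrees, lengths in mm/um at this surface
(matching how bench parameters are usually quoted); everything is
converted to SI on load.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigError
from .geometry import CanalGeometry
from .kinematics import ManeuverSpec
from .operator import OperatorNoiseSpec
from .scaling import MaterialSpec, ScalingSpec

_CANAL_KEYS = {
    "major_radius_mm": (False, 16.0),
    "duct_radius_mm": (False, 0.75),
    "duct_span_deg": (False, 240.0),
    "upright_ampulla_elevation_deg": (False, 32.0),
}
_MATERIAL_KEYS = {
    "fluid_kinematic_viscosity_m2_s": (True, None),
    "fluid_density_kg_m3": (True, None),
    "particle_diameter_um": (True, None),
    "particle_density_kg_m3": (True, None),
    "regime": (False, "scaled_model"),
}
_SCALING_KEYS = {
    "geometric_factor": (False, 5.0),
    "reference_endolymph_density_kg_m3": (False, 1000.0),
    "reference_otoconia_density_kg_m3": (False, 2700.0),
}
_MANEUVER_KEYS = {
    "extension_angle_deg": (True, None),
    "maneuver_velocity_deg_s": (True, None),
    "resting_time_s": (True, None),
    "final_observation_s": (False, 60.0),
    "pivot_offset_m": (False, 0.0),
    "ramp_time_s": (False, 0.0),
}
_NOISE_KEYS = {
    "stop_angle_sd_deg": (False, 2.0),
    "velocity_fraction_sd": (False, 0.10),
    "resting_time_sd_s": (False, 0.5),
    "ramp_time_s": (False, 0.15),
    "seed": (False, 0),
    "stop_clearance_deg": (False, None),
}
_PROTOCOL_KEYS = {
    "drag_correction": (False, None),
    "scan_start_s": (False, 5.0),
    "scan_step_s": (False, 1.0),
    "scan_max_s": (False, 300.0),
    "refine_to_s": (False, 0.1),
    "k_consecutive": (False, 3),
    "max_replicates": (False, 12),
    "calibration": (False, None),
}
_CALIBRATION_KEYS = {
    "particle_diameter_um": (False, 250.0),
    "extension_angle_deg": (False, 30.0),
    "maneuver_velocity_deg_s": (False, 90.0),
    "target_critical_time_s": (False, 9.0),
}
_TOP_KEYS = {"canal", "materials", "scaling", "maneuver", "noise", "protocol", "seed"}


@dataclass(frozen=True)
class ProtocolSettings:
    """Scan and calibration parameters of the experimental protocol."""

    drag_correction: float | None = None
    scan_start_s: float = 5.0
    scan_step_s: float = 1.0
    scan_max_s: float = 300.0
    refine_to_s: float = 0.1
    k_consecutive: int = 3
    max_replicates: int = 12
    calibration: dict = field(
        default_factory=lambda: dict(
            particle_diameter_um=250.0,
            extension_angle_deg=30.0,
            maneuver_velocity_deg_s=90.0,
            target_critical_time_s=9.0,
        )
    )

    @property
    def calibration_cell(self) -> tuple[float, float, float]:
        c = self.calibration
        return (
            c["particle_diameter_um"] * 1e-6,
            c["extension_angle_deg"],
            c["maneuver_velocity_deg_s"],
        )


@dataclass(frozen=True)
class RunConfig:
    """Fully validated run configuration, in SI units."""

    canal: CanalGeometry
    materials: MaterialSpec
    scaling: ScalingSpec
    maneuver: ManeuverSpec
    protocol: ProtocolSettings
    noise: OperatorNoiseSpec | None = None
    seed: int = 0


def _check_section(name: str, raw: dict | None, schema: dict) -> dict:
    raw = {} if raw is None else dict(raw)
    if not isinstance(raw, dict):
        raise ConfigError(f"section '{name}' must be a mapping")
    unknown = set(raw) - set(schema)
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{name}'; "
            f"allowed: {sorted(schema)}"
        )
    out = {}
    for key, (required, default) in schema.items():
        if key in raw:
            out[key] = raw[key]
        elif required:
            raise ConfigError(f"missing required key '{key}' in section '{name}'")
        else:
            out[key] = default
    return out


def config_from_dict(data: dict) -> RunConfig:
    """Build and validate a :class:`RunConfig` from a plain mapping."""
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(
            f"unknown top-level key(s) {sorted(unknown)}; allowed: {sorted(_TOP_KEYS)}"
        )
    if "materials" not in data:
        raise ConfigError("missing required section 'materials'")
    if "maneuver" not in data:
        raise ConfigError("missing required section 'maneuver'")
    canal_d = _check_section("canal", data.get("canal"), _CANAL_KEYS)
    mat_d = _check_section("materials", data["materials"], _MATERIAL_KEYS)
    scal_d = _check_section("scaling", data.get("scaling"), _SCALING_KEYS)
    man_d = _check_section("maneuver", data["maneuver"], _MANEUVER_KEYS)
    prot_d = _check_section("protocol", data.get("protocol"), _PROTOCOL_KEYS)
    if prot_d["calibration"] is not None:
        prot_d["calibration"] = _check_section(
            "protocol.calibration", prot_d["calibration"], _CALIBRATION_KEYS
        )
    else:
        prot_d["calibration"] = {k: v for k, (_, v) in _CALIBRATION_KEYS.items()}
    noise = None
    if data.get("noise") is not None:
        noise_d = _check_section("noise", data["noise"], _NOISE_KEYS)
        noise = OperatorNoiseSpec(**noise_d)
    return RunConfig(
        canal=CanalGeometry(
            major_radius=canal_d["major_radius_mm"] * 1e-3,
            duct_radius=canal_d["duct_radius_mm"] * 1e-3,
            duct_span_deg=canal_d["duct_span_deg"],
            upright_ampulla_elevation_deg=canal_d["upright_ampulla_elevation_deg"],
        ),
        materials=MaterialSpec(
            fluid_kinematic_viscosity=mat_d["fluid_kinematic_viscosity_m2_s"],
            fluid_density=mat_d["fluid_density_kg_m3"],
            particle_diameter=mat_d["particle_diameter_um"] * 1e-6,
            particle_density=mat_d["particle_density_kg_m3"],
            regime=mat_d["regime"],
        ),
        scaling=ScalingSpec(
            geometric_factor=scal_d["geometric_factor"],
            reference_endolymph_density=scal_d["reference_endolymph_density_kg_m3"],
            reference_otoconia_density=scal_d["reference_otoconia_density_kg_m3"],
        ),
        maneuver=ManeuverSpec(**man_d),
        protocol=ProtocolSettings(**prot_d),
        noise=noise,
        seed=int(data.get("seed", 0)),
    )


def config_to_dict(cfg: RunConfig) -> dict:
    """Inverse of :func:`config_from_dict` (surface units restored)."""
    out: dict = {
        "canal": {
            "major_radius_mm": cfg.canal.major_radius * 1e3,
            "duct_radius_mm": cfg.canal.duct_radius * 1e3,
            "duct_span_deg": cfg.canal.duct_span_deg,
            "upright_ampulla_elevation_deg": cfg.canal.upright_ampulla_elevation_deg,
        },
        "materials": {
            "fluid_kinematic_viscosity_m2_s": cfg.materials.fluid_kinematic_viscosity,
            "fluid_density_kg_m3": cfg.materials.fluid_density,
            "particle_diameter_um": cfg.materials.particle_diameter * 1e6,
            "particle_density_kg_m3": cfg.materials.particle_density,
            "regime": cfg.materials.regime,
        },
        "scaling": {
            "geometric_factor": cfg.scaling.geometric_factor,
            "reference_endolymph_density_kg_m3": cfg.scaling.reference_endolymph_density,
            "reference_otoconia_density_kg_m3": cfg.scaling.reference_otoconia_density,
        },
        "maneuver": asdict(cfg.maneuver),
        "protocol": {
            k: v for k, v in asdict(cfg.protocol).items()
        },
        "seed": cfg.seed,
    }
    if cfg.noise is not None:
        out["noise"] = asdict(cfg.noise)
    return out


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return config_from_dict(data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML (or JSON by extension)."""
    path = Path(path)
    data = config_to_dict(cfg)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 hash of the configuration content (provenance tag)."""
    canonical = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def bundled_config(name: str = "bench_model") -> RunConfig:
    """Load one of the configs shipped with the package.

    ``bench_model`` reproduces the bench model's geometrical and physical
    parameters (scaled regime, 250 um particle).
    """
    ref = resources.files("canalith").joinpath(f"data/{name}.yaml")
    with resources.as_file(ref) as p:
        return load_config(p)


def run_metadata(cfg: RunConfig) -> dict:
    """Provenance block attached to every JSON output."""
    from . import __version__

    return {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
    }
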