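"""Flat key-value run configuration with units embedded in key names.

The config file format is deliberately simple — ``key = value`` lines with
``#`` comments — and every dimensioned key carries its unit in the name
(``gap_mm``, ``potential_kV``, ``spacing_um``) so unit bugs are visible at
the boundary. Internally everything converts to SI.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from cellspray.device import DeviceGeometry, OperatingPotential
from cellspray.ehd import FluidProperties, OperatingConditions

#: the study's operating point and the solver defaults
DEFAULT_CONFIG: dict[str, float | str] = {
    "mode": "planar",
    "spacing_um": 75.0,
    "needle_inner_diameter_mm": 0.838,
    "needle_outer_diameter_mm": 1.27,
    "gap_mm": 70.0,
    "plate_half_width_mm": 30.0,
    "plate_thickness_mm": 1.5,
    "needle_protrusion_mm": 10.0,
    "domain_half_width_mm": 60.0,
    "domain_margin_above_mm": 10.0,
    "potential_kV": 15.0,
    "potential_low_kV": 10.0,
    "plate_potential_kV": 0.0,
    "flow_ul_min": 200.0,
    "density_kg_m3": 1000.0,
    "surface_tension_N_m": 0.07,
    "mode_threshold": 1.0,
    "frame_rate_fps": 7000.0,
    "video_duration_s": 5.0,
    "seed": 0,
}


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration."""


def default_config() -> dict[str, float | str]:
    return dict(DEFAULT_CONFIG)


def load_config(path: str | Path, merge_defaults: bool = True) -> dict:
    """Parse a flat key-value config file.

    Unknown keys are refused (named in the error); with ``merge_defaults``
    the parsed values overlay :data:`DEFAULT_CONFIG`.
    """
    path = Path(path)
    parsed: dict[str, float | str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key not in DEFAULT_CONFIG:
            raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
        try:
            parsed[key] = float(value)
        except ValueError:
            parsed[key] = value
    if merge_defaults:
        out = default_config()
        out.update(parsed)
        return out
    return parsed


def save_config(config: Mapping[str, float | str], path: str | Path) -> None:
    lines = [f"{key} = {value}" for key, value in config.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def require(config: Mapping, key: str):
    if key not in config:
        raise ConfigError(f"missing config key {key!r}")
    return config[key]


def geometry_from_config(config: Mapping) -> DeviceGeometry:
    mm = 1e-3
    return DeviceGeometry(
        needle_inner_diameter=require(config, "needle_inner_diameter_mm") * mm,
        needle_outer_diameter=require(config, "needle_outer_diameter_mm") * mm,
        gap=require(config, "gap_mm") * mm,
        plate_half_width=require(config, "plate_half_width_mm") * mm,
        plate_thickness=require(config, "plate_thickness_mm") * mm,
        needle_protrusion=require(config, "needle_protrusion_mm") * mm,
        domain_half_width=require(config, "domain_half_width_mm") * mm,
        domain_margin_above=require(config, "domain_margin_above_mm") * mm,
    )


def potential_from_config(config: Mapping, key: str = "potential_kV") -> OperatingPotential:
    return OperatingPotential(
        applied_potential=require(config, key) * 1e3,
        plate_potential=require(config, "plate_potential_kV") * 1e3,
    )


def fluid_from_config(config: Mapping) -> FluidProperties:
    return FluidProperties(
        density=require(config, "density_kg_m3"),
        surface_tension=require(config, "surface_tension_N_m"),
    )


def conditions_from_config(
    config: Mapping, potential_key: str = "potential_kV"
) -> OperatingConditions:
    return OperatingConditions(
        applied_potential=require(config, potential_key) * 1e3,
        flow_rate=require(config, "flow_ul_min") * 1e-9 / 60.0,
        geometry=geometry_from_config(config),
    )


def spacing_from_config(config: Mapping) -> float:
    return require(config, "spacing_um") * 1e-6
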