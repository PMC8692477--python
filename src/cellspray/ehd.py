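"""Electrohydrodynamic force scales, spray-mode classification and cell
exposure metrics for the needle-plate electrosprayer.

A meniscus of diameter D at the tip of a charged capillary (bore D_i, outer
diameter D_o) carrying flow Q under applied potential phi experiences, to
order of magnitude:

* electric pull            F_e  ~ eps0 * phi**2
* weight                   F_g  ~ rho * D_o**3 * g
* injected momentum flux   Pdot ~ rho * Q**2 / D_i**2
* restoring surface tension F_gamma ~ D_o * gamma

When the electric pull dominates surface tension the device leaves the
dripping regime and operates in micro-dripping: droplets detach periodically
from an elongated meniscus with diameters well below the nozzle outer
diameter (0.05-0.85 D_o). Pdot is a momentum-flux scale, not a force on any
one body; it is reported alongside the forces without asserting a closed
balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from cellspray.device import DeviceGeometry
from cellspray.field import VectorFieldMap, FREE

VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
STANDARD_GRAVITY = 9.80665  # m/s^2

#: micro-dripping droplet diameter window as fractions of the outer diameter
MICRO_DRIPPING_BOUNDS = (0.05, 0.85)


@dataclass(frozen=True)
class FluidProperties:
    """Bulk liquid properties. Defaults are water-like; the cell-laden
    pullulan/gelatin solution's true values are not published, so both are
    configuration-exposed."""

    density: float = 1000.0  # kg/m^3
    surface_tension: float = 0.07  # N/m

    def __post_init__(self) -> None:
        if self.density <= 0 or self.surface_tension <= 0:
            raise ValueError("density and surface_tension must be > 0")


@dataclass(frozen=True)
class OperatingConditions:
    """Potential (V), volumetric flow (m^3/s) and geometry of one run."""

    applied_potential: float
    flow_rate: float
    geometry: DeviceGeometry = dc_field(default_factory=DeviceGeometry)
    meniscus_diameter: float | None = None  # defaults to the outer diameter

    def __post_init__(self) -> None:
        if self.applied_potential <= 0:
            raise ValueError("applied_potential must be > 0")
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be > 0")

    @property
    def meniscus(self) -> float:
        if self.meniscus_diameter is not None:
            return self.meniscus_diameter
        return self.geometry.needle_outer_diameter


@dataclass(frozen=True)
class ForceScaleReport:
    """The four meniscus force scales (N) and their surface-tension ratios."""

    f_electric: float
    f_gravity: float
    p_inertial: float
    f_surface_tension: float

    @property
    def electric_to_surface_tension(self) -> float:
        return self.f_electric / self.f_surface_tension

    @property
    def ratios(self) -> dict[str, float]:
        ft = self.f_surface_tension
        return {
            "f_electric": self.f_electric / ft,
            "f_gravity": self.f_gravity / ft,
            "p_inertial": self.p_inertial / ft,
            "f_surface_tension": 1.0,
        }

    def to_dict(self) -> dict[str, float]:
        return {
            "f_electric_N": self.f_electric,
            "f_gravity_N": self.f_gravity,
            "p_inertial_N": self.p_inertial,
            "f_surface_tension_N": self.f_surface_tension,
            "electric_to_surface_tension": self.electric_to_surface_tension,
        }


@dataclass(frozen=True)
class ModeClassification:
    mode: str  # dripping | micro-dripping | oscillating micro-dripping
    rationale: str
    droplet_diameter_bounds: tuple[float, float] | None


@dataclass(frozen=True)
class ExposureReport:
    """What a cell transiting the needle experiences."""

    mean_exit_velocity: float  # m/s
    needle_residence_time: float  # s
    peak_field_on_path: float  # V/m
    peak_field_location: tuple[float, float]  # (r, z) m
    field_at_exit_center: float  # V/m


def force_scales(
    fluid: FluidProperties, op: OperatingConditions
) -> ForceScaleReport:
    """Evaluate the four order-of-magnitude force scales exactly as written."""
    geom = op.geometry
    f_e = VACUUM_PERMITTIVITY * op.applied_potential**2
    f_g = fluid.density * geom.needle_outer_diameter**3 * STANDARD_GRAVITY
    p_i = fluid.density * op.flow_rate**2 / geom.needle_inner_diameter**2
    f_t = geom.needle_outer_diameter * fluid.surface_tension
    return ForceScaleReport(
        f_electric=f_e, f_gravity=f_g, p_inertial=p_i, f_surface_tension=f_t
    )


def classify_mode(
    report: ForceScaleReport,
    geometry: DeviceGeometry | None = None,
    threshold: float = 1.0,
    oscillating_threshold: float | None = None,
) -> ModeClassification:
    """Classify the spraying regime from the electric/surface-tension ratio.

    Micro-dripping when the ratio meets ``threshold`` (default 1: electric
    pull at least on par with surface tension), dripping below it, and
    oscillating micro-dripping above the optional upper threshold (disabled
    by default — the study never reaches it).
    """
    ratio = report.electric_to_surface_tension
    if oscillating_threshold is not None and ratio >= oscillating_threshold:
        mode = "oscillating micro-dripping"
    elif ratio >= threshold:
        mode = "micro-dripping"
    else:
        mode = "dripping"
    rationale = (
        f"F_electric / F_surface_tension = {ratio:.3g} "
        f"(threshold {threshold:g}"
        + (
            f", oscillating threshold {oscillating_threshold:g})"
            if oscillating_threshold is not None
            else ")"
        )
    )
    bounds = None
    if mode != "dripping" and geometry is not None:
        bounds = droplet_diameter_bounds(geometry)
    return ModeClassification(
        mode=mode, rationale=rationale, droplet_diameter_bounds=bounds
    )


def droplet_diameter_bounds(geometry: DeviceGeometry) -> tuple[float, float]:
    """Micro-dripping droplet diameter window [0.05, 0.85] x outer diameter (m)."""
    lo, hi = MICRO_DRIPPING_BOUNDS
    d_o = geometry.needle_outer_diameter
    return (lo * d_o, hi * d_o)


def exposure_report(
    op: OperatingConditions,
    field: VectorFieldMap,
    wetted_length: float | None = None,
) -> ExposureReport:
    """Transit metrics through the needle plus the field seen at the exit.

    Mean exit velocity is plug flow through the bore, Q / (pi r_i^2); the
    residence time uses the wetted length (defaulting to the exposed needle
    length) over that velocity. The peak field is sampled over the bore-exit
    region: free nodes with r <= D_i/2 between the tip plane and one bore
    diameter below it.
    """
    geom = op.geometry
    grid = field.grid
    if grid.geometry is not None and grid.geometry != geom:
        raise ValueError(
            "field map was solved for a different device geometry than the "
            "operating conditions reference"
        )
    r_bore = geom.needle_inner_diameter / 2
    area = np.pi * r_bore**2
    velocity = op.flow_rate / area
    if wetted_length is None:
        wetted_length = geom.needle_protrusion
    residence = wetted_length * area / op.flow_rate

    j0 = grid.j_tip
    z_lo = grid.z[j0]
    z_hi = z_lo + geom.needle_inner_diameter
    sel_r = grid.r <= r_bore + grid.spacing / 2
    sel_z = (grid.z >= z_lo) & (grid.z <= z_hi)
    region = np.ix_(sel_r, sel_z)
    mag = field.magnitude[region]
    free = (grid.conductor_mask[region] == FREE) & np.isfinite(mag)
    if not free.any():
        raise ValueError("no free nodes in the bore-exit region")
    mag = np.where(free, mag, -np.inf)
    flat = int(np.argmax(mag))
    ir, iz = np.unravel_index(flat, mag.shape)
    peak = float(mag[ir, iz])
    location = (float(grid.r[sel_r][ir]), float(grid.z[sel_z][iz]))
    exit_center = float(field.magnitude[0, j0])
    return ExposureReport(
        mean_exit_velocity=velocity,
        needle_residence_time=residence,
        peak_field_on_path=peak,
        peak_field_location=location,
        field_at_exit_center=exit_center,
    )
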