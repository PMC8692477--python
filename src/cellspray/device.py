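"""Device geometry and operating potential for the needle-plate electrosprayer.

All lengths are SI metres and potentials volts. The defaults describe the
study device: an 18G stainless-steel capillary (0.838 mm bore, 1.27 mm outer
diameter) suspended 70 mm above a grounded 60 x 60 x 1.5 mm aluminium plate.
The simulation box extents and the exposed needle length are solver choices,
not measured quantities; see ``docs/methods.md`` for how the defaults were
fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


@dataclass(frozen=True)
class DeviceGeometry:
    """Electrode layout defining the boundary conditions of the field solve.

    Parameters
    ----------
    needle_inner_diameter, needle_outer_diameter
        Bore and outer diameter of the capillary needle (m).
    gap
        Needle tip to plate distance (m).
    plate_half_width, plate_thickness
        Half-width and thickness of the grounded collector plate (m).
    needle_protrusion
        Exposed needle length above the tip plane included in the model (m).
    domain_half_width
        Lateral half-extent of the simulation box (m).
    domain_margin_above
        Box margin above the needle entry point (m).
    """

    needle_inner_diameter: float = 0.838e-3
    needle_outer_diameter: float = 1.27e-3
    gap: float = 70e-3
    plate_half_width: float = 30e-3
    plate_thickness: float = 1.5e-3
    needle_protrusion: float = 10e-3
    domain_half_width: float = 60e-3
    domain_margin_above: float = 10e-3

    def __post_init__(self) -> None:
        positive = [
            "needle_inner_diameter",
            "needle_outer_diameter",
            "gap",
            "plate_half_width",
            "plate_thickness",
            "needle_protrusion",
            "domain_half_width",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.domain_margin_above < 0:
            raise ValueError("domain_margin_above must be >= 0")
        if self.needle_inner_diameter >= self.needle_outer_diameter:
            raise ValueError(
                "needle_inner_diameter must be smaller than needle_outer_diameter "
                f"({self.needle_inner_diameter} >= {self.needle_outer_diameter})"
            )
        if self.needle_outer_diameter / 2 >= self.domain_half_width:
            raise ValueError("needle does not fit laterally inside the domain")
        if self.plate_half_width > self.domain_half_width:
            warnings.warn(
                "plate is wider than the domain and will be clipped at the "
                "lateral boundary",
                stacklevel=2,
            )

    @property
    def domain_height(self) -> float:
        """Total box height: margin + protrusion + gap + plate slab (m)."""
        return (
            self.domain_margin_above
            + self.needle_protrusion
            + self.gap
            + self.plate_thickness
        )

    @property
    def z_top(self) -> float:
        """z of the upper open boundary; z = 0 at the needle tip plane."""
        return -(self.domain_margin_above + self.needle_protrusion)

    @property
    def z_bottom(self) -> float:
        """z of the lower boundary (bottom face of the plate)."""
        return self.gap + self.plate_thickness


@dataclass(frozen=True)
class OperatingPotential:
    """DC potentials applied to the electrodes (V): needle hot, plate grounded."""

    applied_potential: float
    plate_potential: float = 0.0

    def __post_init__(self) -> None:
        if self.applied_potential == self.plate_potential:
            raise ValueError("applied_potential must differ from plate_potential")
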