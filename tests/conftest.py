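"""Shared fixtures.

``small_geometry`` is a scaled-up-needle, short-gap device whose grids stay
a few thousand nodes so solver behaviour (linearity, profiles, convergence
audits) can be exercised quickly; ``device_pair`` solves the real study
device at both operating potentials on the default grid once per session
for the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from cellspray import (
    DeviceGeometry,
    compute_field,
    solve_device,
    tip_field_report,
)


@pytest.fixture(scope="session")
def small_geometry() -> DeviceGeometry:
    """Widened-needle short-gap device: coarse grids stay valid (bore still
    spans >= 8 nodes at 200 um spacing) and solves take milliseconds."""
    return DeviceGeometry(
        needle_inner_diameter=1.6e-3,
        needle_outer_diameter=2.4e-3,
        gap=12e-3,
        plate_half_width=10e-3,
        plate_thickness=0.6e-3,
        needle_protrusion=4e-3,
        domain_half_width=10e-3,
        domain_margin_above=3e-3,
    )


@pytest.fixture(scope="session")
def small_field_pair(small_geometry):
    """(15 kV, 10 kV) field maps of the small device on one 200 um grid."""
    solutions = solve_device(small_geometry, [15e3, 10e3], spacing=200e-6)
    return [compute_field(s) for s in solutions]


@pytest.fixture(scope="session")
def device_pair():
    """The study device solved at 15 and 10 kV on the default grid; returns
    (geometry, [report_15kV, report_10kV])."""
    geometry = DeviceGeometry()
    solutions = solve_device(geometry, [15e3, 10e3])
    reports = [tip_field_report(compute_field(s), geometry) for s in solutions]
    return geometry, reports
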