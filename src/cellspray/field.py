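"""Finite-difference electrostatics of the needle-plate electrospray device.

The potential phi solves Poisson's equation over a rectangular box containing
the needle and the grounded plate as Dirichlet conductors, discretized on a
uniform grid with the standard 5-point stencil. Two formulations are
available:

``planar``
    2-D Cartesian cross-section. Only the half-plane x >= 0 is stored; a
    Neumann mirror at x = 0 makes it exactly equivalent to the full symmetric
    domain. This is the default formulation (see ``docs/methods.md``).
``axisymmetric``
    Cylindrical (r, z) Laplacian with the regularity condition at r = 0.

Open box boundaries carry homogeneous Neumann conditions (zero normal field),
implemented by mirror ghost nodes. The electric field is E = -grad(phi),
differenced centrally in the interior and one-sidedly into adjacent
conductor surfaces (which carries the Dirichlet boundary data into the
surface-field estimate).

Coordinate convention: ``z = 0`` at the needle tip plane, increasing toward
the plate; ``r`` (or x) = 0 on the needle axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from cellspray.device import DeviceGeometry, OperatingPotential

VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

# conductor_mask codes
FREE = 0
NEEDLE = 1
PLATE = 2

#: default relative-residual tolerance of the linear solve
DEFAULT_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Iterative solve failed; carries the last relative residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class SolverGrid:
    """Uniform finite-difference grid with rasterized conductors.

    ``conductor_mask`` is (n_r, n_z) with codes FREE/NEEDLE/PLATE;
    ``dirichlet_values`` maps conductor codes to their fixed potentials (V).
    """

    mode: str
    spacing: float
    r: np.ndarray
    z: np.ndarray
    conductor_mask: np.ndarray
    dirichlet_values: dict[int, float]
    geometry: DeviceGeometry | None = None

    @property
    def n_r(self) -> int:
        return len(self.r)

    @property
    def n_z(self) -> int:
        return len(self.z)

    @property
    def j_tip(self) -> int:
        """Index of the needle tip plane (z = 0)."""
        return int(np.argmin(np.abs(self.z)))

    @property
    def j_plate(self) -> int:
        """Index of the first grid row occupied by the plate (its top face)."""
        rows = np.nonzero((self.conductor_mask == PLATE).any(axis=0))[0]
        if rows.size == 0:
            raise ValueError("grid has no plate conductor")
        return int(rows[0])

    def dirichlet_map(self) -> np.ndarray:
        """Per-node Dirichlet value (0 on free nodes)."""
        values = np.zeros_like(self.conductor_mask, dtype=float)
        for code, v in self.dirichlet_values.items():
            values[self.conductor_mask == code] = v
        return values

    def full_mask(self) -> np.ndarray:
        """Mask mirrored about the axis: the full-width x in [-W, W] view."""
        return np.vstack([self.conductor_mask[:0:-1], self.conductor_mask])

    def same_discretization(self, other: "SolverGrid") -> bool:
        return (
            self.mode == other.mode
            and self.spacing == other.spacing
            and self.conductor_mask.shape == other.conductor_mask.shape
            and np.array_equal(self.conductor_mask, other.conductor_mask)
        )


def build_grid(
    geometry: DeviceGeometry,
    potential: OperatingPotential,
    spacing: float = 75e-6,
    mode: str = "planar",
) -> SolverGrid:
    """Rasterize the device onto a uniform grid with Dirichlet conductors.

    The bore must span at least 8 nodes (spacing <= inner diameter / 8);
    coarser grids are refused so tip-plane sampling stays meaningful.
    """
    if mode not in ("planar", "axisymmetric"):
        raise ValueError(f"mode must be 'planar' or 'axisymmetric', got {mode!r}")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    max_spacing = geometry.needle_inner_diameter / 8
    if spacing > max_spacing:
        raise ValueError(
            f"spacing {spacing:.6g} m too coarse: the bore must span >= 8 nodes, "
            f"so spacing must be <= {max_spacing:.6g} m"
        )

    h = spacing
    n_r = int(round(geometry.domain_half_width / h)) + 1
    n_z = int(round(geometry.domain_height / h)) + 1
    r = np.arange(n_r) * h
    z = geometry.z_top + np.arange(n_z) * h

    r_in = geometry.needle_inner_diameter / 2
    r_out = geometry.needle_outer_diameter / 2
    R, Z = np.meshgrid(r, z, indexing="ij")

    # half-spacing halo so a surface lying between nodes still rasterizes
    needle = (
        (R >= r_in - h / 2)
        & (R <= r_out + h / 2)
        & (Z >= -geometry.needle_protrusion - h / 2)
        & (Z <= h / 2)
    )
    plate = (Z >= geometry.gap - h / 2) & (R <= geometry.plate_half_width + h / 2)

    mask = np.zeros((n_r, n_z), dtype=np.int8)
    mask[needle] = NEEDLE
    mask[plate] = PLATE

    return SolverGrid(
        mode=mode,
        spacing=h,
        r=r,
        z=z,
        conductor_mask=mask,
        dirichlet_values={
            NEEDLE: potential.applied_potential,
            PLATE: potential.plate_potential,
        },
        geometry=geometry,
    )


def parallel_plate_grid(
    gap: float,
    applied_potential: float,
    spacing: float,
    half_width: float | None = None,
    mode: str = "planar",
    plate_potential: float = 0.0,
) -> SolverGrid:
    """Two-electrode capacitor grid (no needle): top plane hot, bottom grounded.

    The closed-form interior field |E| = V / d makes this the standard
    solver limit check; it is also the 'uniform field' reference for the
    profile and tip-report edge cases.
    """
    if half_width is None:
        half_width = gap / 2
    n_r = int(round(half_width / spacing)) + 1
    n_z = int(round(gap / spacing)) + 1
    mask = np.zeros((n_r, n_z), dtype=np.int8)
    mask[:, 0] = NEEDLE
    mask[:, -1] = PLATE
    # z = 0 on the first free row below the hot electrode, matching the
    # tip-plane convention of the device grid
    return SolverGrid(
        mode=mode,
        spacing=spacing,
        r=np.arange(n_r) * spacing,
        z=(np.arange(n_z) - 1.0) * spacing,
        conductor_mask=mask,
        dirichlet_values={NEEDLE: applied_potential, PLATE: plate_potential},
        geometry=None,
    )


@dataclass
class ScalarPotentialMap:
    """Solved potential (V) per node with the final relative residual."""

    grid: SolverGrid
    values: np.ndarray
    residual: float


@dataclass
class VectorFieldMap:
    """E = -grad(phi) per node (V/m); NaN on conductor nodes."""

    grid: SolverGrid
    e_r: np.ndarray
    e_z: np.ndarray
    magnitude: np.ndarray


@dataclass
class AxisProfile:
    """|E| sampled along one device axis.

    ``axis_label`` is ``"Y"`` (needle tip toward plate, on-axis) or ``"X"``
    (transverse across the tip plane). Positions are metres from the tip
    plane (Y) or from the axis (X). ``monotone_fraction`` (Y only) is the
    fraction of the gap covered by the longest non-increasing run ending at
    the plate; ``monotone_decay`` flags runs covering >= 90% of the gap.
    """

    positions: np.ndarray
    magnitudes: np.ndarray
    axis_label: str
    monotone_fraction: float | None = None
    monotone_decay: bool | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position_m": self.positions, "E_V_per_m": self.magnitudes}
        )


@dataclass
class TipFieldReport:
    """Field metrics around the needle tip (V/m).

    * ``e_tip_axis`` — peak |E| on the tip-to-plate axis (the on-axis field
      rises over the first few hundred micrometres below the bore opening
      before decaying toward the plate; the peak is the value quoted for
      'the field at the tip').
    * ``e_center`` — |E| at the axis node in the tip plane (bore-opening
      center).
    * ``e_inner_edge`` — |E| at the free tip-plane node nearest the bore
      edge r = D_i/2; mesh-registered, see ``docs/methods.md``.
    * ``e_near_plate`` — on-axis |E| one spacing above the plate.
    * ``e_mid_gap`` — on-axis |E| halfway down the gap (grid-convergence
      metric).
    """

    e_tip_axis: float
    e_center: float
    e_inner_edge: float
    e_near_plate: float
    e_mid_gap: float
    edge_to_center_ratio: float
    applied_potential: float = dc_field(default=float("nan"))
    spacing: float = dc_field(default=float("nan"))
    mode: str = dc_field(default="")
    grid_shape: tuple[int, int] = dc_field(default=(0, 0))

    METRICS = (
        "e_tip_axis",
        "e_center",
        "e_inner_edge",
        "e_near_plate",
        "e_mid_gap",
    )

    def metrics(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.METRICS}

    def to_dict(self) -> dict[str, float | str]:
        out: dict[str, float | str] = dict(self.metrics())
        out["edge_to_center_ratio"] = self.edge_to_center_ratio
        out["applied_potential_V"] = self.applied_potential
        out["spacing_m"] = self.spacing
        out["mode"] = self.mode
        return out


# ---------------------------------------------------------------------------
# stencil assembly and linear solves
# ---------------------------------------------------------------------------


def _stencil_coefficients(grid: SolverGrid) -> tuple[np.ndarray, ...]:
    """Neighbour weights (cW, cE, cS, cN) and centre weight c0 per node.

    Planar: all neighbour weights 1, c0 = 4. Axisymmetric: the cylindrical
    Laplacian gives (1 -+ h/2r) radial weights; at r = 0 the regularity
    condition yields a 4*phi(h) - 6*phi(0) radial stencil.
    """
    n_r, n_z = grid.n_r, grid.n_z
    ones = np.ones((n_r, n_z))
    if grid.mode == "planar":
        return ones, ones.copy(), ones.copy(), ones.copy(), 4.0 * ones
    h = grid.spacing
    r = grid.r[:, None]
    with np.errstate(divide="ignore"):
        cW = np.where(r > 0, 1 - h / (2 * np.maximum(r, 1e-300)), 0.0) * ones
        cE = np.where(r > 0, 1 + h / (2 * np.maximum(r, 1e-300)), 4.0) * ones
    c0 = np.where(r > 0, 4.0, 6.0) * ones
    return cW, cE, ones.copy(), ones.copy(), c0


def stencil_system(
    grid: SolverGrid, charge_density: np.ndarray | None = None
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Full linear system A phi = b over all nodes (Dirichlet rows identity).

    Open boundaries use mirror ghosts (the out-of-domain neighbour index is
    reflected back inside), which is the homogeneous Neumann condition.
    Exposed so small grids can be cross-checked against a dense solve of the
    identical stencil.
    """
    n_r, n_z = grid.n_r, grid.n_z
    N = n_r * n_z
    idx = np.arange(N).reshape(n_r, n_z)
    mask = grid.conductor_mask
    free = (mask == FREE).ravel()
    dirichlet = grid.dirichlet_map().ravel()

    cW, cE, cS, cN, c0 = _stencil_coefficients(grid)
    coeffs = {(-1, 0): cW, (1, 0): cE, (0, -1): cS, (0, 1): cN}

    ii, jj = np.meshgrid(np.arange(n_r), np.arange(n_z), indexing="ij")
    ii = ii.ravel()
    jj = jj.ravel()

    rows, cols, data = [], [], []
    b = np.zeros(N)
    if charge_density is not None:
        rho = np.asarray(charge_density, dtype=float)
        if rho.shape != mask.shape:
            raise ValueError(
                f"charge_density shape {rho.shape} != grid shape {mask.shape}"
            )
        b[free] = -(grid.spacing**2) * rho.ravel()[free] / VACUUM_PERMITTIVITY

    for (di, dj), c in coeffs.items():
        c = c.ravel()
        ni, nj = ii + di, jj + dj
        out = (ni < 0) | (ni >= n_r) | (nj < 0) | (nj >= n_z)
        # mirror ghost: reflect the out-of-domain neighbour back inside
        ni = np.where(out, np.clip(ii - di, 0, n_r - 1), np.clip(ni, 0, n_r - 1))
        nj = np.where(out, np.clip(jj - dj, 0, n_z - 1), np.clip(nj, 0, n_z - 1))
        nidx = idx[ni, nj]
        keep = free & (c != 0)
        rows.append(idx.ravel()[keep])
        cols.append(nidx[keep])
        data.append(c[keep])

    fr = idx.ravel()[free]
    rows.append(fr)
    cols.append(fr)
    data.append(-c0.ravel()[free])
    dr = idx.ravel()[~free]
    rows.append(dr)
    cols.append(dr)
    data.append(np.ones(dr.size))
    b[dr] = dirichlet[dr]

    A = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    )
    return A, b


class FactorizedPoisson:
    """Sparse LU factorization of the free-node stencil, reusable across
    right-hand sides (the matrix depends on geometry only, not on the
    electrode potentials)."""

    def __init__(self, grid: SolverGrid, charge_density: np.ndarray | None = None):
        self.grid = grid
        self._charge_density = charge_density
        A, b0 = stencil_system(grid, charge_density)
        self._free = (grid.conductor_mask == FREE).ravel()
        self._Aff = A[self._free][:, self._free].tocsc()
        # Dirichlet coupling: b_f depends linearly on conductor values
        self._Afd = A[self._free][:, ~self._free].tocsc()
        self._rho_rhs = b0[self._free].copy()
        if charge_density is None:
            self._rho_rhs[:] = 0.0
        self._lu = spla.splu(self._Aff)

    def solve(self, dirichlet_values: dict[int, float]) -> ScalarPotentialMap:
        grid = self.grid
        dvals = np.zeros_like(grid.conductor_mask, dtype=float)
        for code, v in dirichlet_values.items():
            dvals[grid.conductor_mask == code] = v
        xd = dvals.ravel()[~self._free]
        bf = self._rho_rhs - self._Afd @ xd
        xf = self._lu.solve(bf)
        resid_vec = self._Aff @ xf - bf
        scale = max(float(np.linalg.norm(bf)), 1e-300)
        residual = float(np.linalg.norm(resid_vec)) / scale
        values = dvals.ravel().copy()
        values[self._free] = xf
        out_grid = SolverGrid(
            mode=grid.mode,
            spacing=grid.spacing,
            r=grid.r,
            z=grid.z,
            conductor_mask=grid.conductor_mask,
            dirichlet_values=dict(dirichlet_values),
            geometry=grid.geometry,
        )
        return ScalarPotentialMap(
            grid=out_grid,
            values=values.reshape(grid.n_r, grid.n_z),
            residual=residual,
        )


def _solve_sor(
    grid: SolverGrid,
    charge_density: np.ndarray | None,
    tol: float,
    max_sweeps: int,
    omega: float,
) -> ScalarPotentialMap:
    """Red-black successive over-relaxation on the structured grid."""
    mask = grid.conductor_mask
    free = mask == FREE
    cW, cE, cS, cN, c0 = _stencil_coefficients(grid)
    phi = grid.dirichlet_map()
    rhs = np.zeros_like(phi)
    if charge_density is not None:
        rhs[free] = (
            -(grid.spacing**2)
            * np.asarray(charge_density, dtype=float)[free]
            / VACUUM_PERMITTIVITY
        )

    ii, jj = np.meshgrid(np.arange(grid.n_r), np.arange(grid.n_z), indexing="ij")
    red = free & ((ii + jj) % 2 == 0)
    black = free & ((ii + jj) % 2 == 1)

    def neighbour_sum(p: np.ndarray) -> np.ndarray:
        pp = np.pad(p, 1, mode="reflect")
        return (
            cW * pp[:-2, 1:-1]
            + cE * pp[2:, 1:-1]
            + cS * pp[1:-1, :-2]
            + cN * pp[1:-1, 2:]
        )

    def rel_residual(p: np.ndarray) -> float:
        r = neighbour_sum(p) - c0 * p - rhs
        num = float(np.linalg.norm(r[free]))
        den = max(float(np.linalg.norm((c0 * p + rhs)[free])), 1e-300)
        return num / den

    residual = rel_residual(phi)
    for sweep in range(1, max_sweeps + 1):
        for colour in (red, black):
            gs = (neighbour_sum(phi) - rhs) / c0
            phi[colour] += omega * (gs[colour] - phi[colour])
        if sweep % 50 == 0 or sweep == max_sweeps:
            residual = rel_residual(phi)
            if residual <= tol:
                break
    else:  # pragma: no cover - loop always breaks or exhausts
        pass
    if residual > tol:
        raise ConvergenceError(
            f"SOR did not reach tol={tol:g} within {max_sweeps} sweeps "
            f"(last residual {residual:.3e})",
            residual,
        )
    return ScalarPotentialMap(grid=grid, values=phi, residual=residual)


def solve_poisson(
    grid: SolverGrid,
    charge_density: np.ndarray | None = None,
    method: str = "direct",
    tol: float = DEFAULT_TOL,
    max_sweeps: int = 100_000,
    omega: float = 1.9,
) -> ScalarPotentialMap:
    """Solve the discretized Poisson problem on ``grid``.

    ``method="direct"`` (default) uses a sparse LU factorization;
    ``method="sor"`` runs red-black successive over-relaxation to the same
    relative-residual tolerance and raises :class:`ConvergenceError` (with
    the last residual attached) if the sweep cap is hit.
    """
    if method == "direct":
        sol = FactorizedPoisson(grid, charge_density).solve(grid.dirichlet_values)
        if sol.residual > tol:
            raise ConvergenceError(
                f"direct solve residual {sol.residual:.3e} exceeds tol {tol:g}",
                sol.residual,
            )
        return sol
    if method == "sor":
        return _solve_sor(grid, charge_density, tol, max_sweeps, omega)
    raise ValueError(f"unknown method {method!r}")


def solve_device(
    geometry: DeviceGeometry,
    applied_potentials: Sequence[float],
    spacing: float = 75e-6,
    mode: str = "planar",
    plate_potential: float = 0.0,
) -> list[ScalarPotentialMap]:
    """Solve the device at several applied potentials on one shared grid.

    The stencil is factorized once and re-used for every potential, so a
    10/15 kV pair costs one factorization plus two triangular solves.
    """
    if not applied_potentials:
        raise ValueError("applied_potentials must be non-empty")
    grid = build_grid(
        geometry, OperatingPotential(applied_potentials[0], plate_potential),
        spacing=spacing, mode=mode,
    )
    factor = FactorizedPoisson(grid)
    return [
        factor.solve({NEEDLE: v, PLATE: plate_potential})
        for v in applied_potentials
    ]


# ---------------------------------------------------------------------------
# field extraction and reports
# ---------------------------------------------------------------------------


def compute_field(potential: ScalarPotentialMap) -> VectorFieldMap:
    """E = -grad(phi): central differences in the interior, one-sided into an
    adjacent conductor surface (using its Dirichlet value), mirror (zero
    normal derivative) on open boundaries. Conductor nodes carry NaN."""
    grid = potential.grid
    phi = potential.values
    h = grid.spacing
    cond = grid.conductor_mask != FREE

    pp = np.pad(phi, 1, mode="reflect")
    cp = np.pad(cond, 1, mode="constant", constant_values=False)

    def component(axis: int) -> np.ndarray:
        if axis == 0:
            p_minus, p_plus = pp[:-2, 1:-1], pp[2:, 1:-1]
            c_minus, c_plus = cp[:-2, 1:-1], cp[2:, 1:-1]
        else:
            p_minus, p_plus = pp[1:-1, :-2], pp[1:-1, 2:]
            c_minus, c_plus = cp[1:-1, :-2], cp[1:-1, 2:]
        grad = (p_plus - p_minus) / (2 * h)
        one_plus = c_plus & ~c_minus
        one_minus = c_minus & ~c_plus
        grad = np.where(one_plus, (p_plus - phi) / h, grad)
        grad = np.where(one_minus, (phi - p_minus) / h, grad)
        return -grad

    e_r = component(0)
    e_z = component(1)
    e_r[cond] = np.nan
    e_z[cond] = np.nan
    return VectorFieldMap(
        grid=grid, e_r=e_r, e_z=e_z, magnitude=np.hypot(e_r, e_z)
    )


def axial_profile(field: VectorFieldMap) -> AxisProfile:
    """|E| along the axis from the tip plane to the plate (the 'Y axis')."""
    grid = field.grid
    j0, j1 = grid.j_tip, grid.j_plate
    js = np.arange(j0, j1)
    keep = grid.conductor_mask[0, js] == FREE
    js = js[keep]
    if js.size == 0:
        raise ValueError("no free on-axis nodes between tip and plate")
    positions = grid.z[js]
    magnitudes = field.magnitude[0, js]

    # longest non-increasing suffix (0.1% slack for discretization wiggle)
    k = len(magnitudes) - 1
    while k > 0 and magnitudes[k - 1] >= magnitudes[k] * (1 - 1e-3):
        k -= 1
    span = positions[-1] - positions[k]
    gap = positions[-1] - positions[0]
    frac = float(span / gap) if gap > 0 else 0.0
    return AxisProfile(
        positions=positions,
        magnitudes=magnitudes,
        axis_label="Y",
        monotone_fraction=frac,
        monotone_decay=frac >= 0.9,
    )


def transverse_tip_profile(field: VectorFieldMap) -> AxisProfile:
    """|E| across the tip plane from the axis to the bore edge (the 'X axis')."""
    grid = field.grid
    j0 = grid.j_tip
    row = grid.conductor_mask[:, j0]
    r_out = (
        grid.geometry.needle_outer_diameter / 2
        if grid.geometry is not None
        else grid.r[-1]
    )
    inside = np.nonzero((row != FREE) | (grid.r > r_out + grid.spacing / 2))[0]
    stop = int(inside[0]) if inside.size else grid.n_r
    if stop == 0:
        raise ValueError("no free nodes on the tip-plane transverse axis")
    return AxisProfile(
        positions=grid.r[:stop],
        magnitudes=field.magnitude[:stop, j0],
        axis_label="X",
    )


def tip_field_report(
    field: VectorFieldMap, geometry: DeviceGeometry | None = None
) -> TipFieldReport:
    """Sample the tip-region field metrics (conventions in the class docs)."""
    grid = field.grid
    if geometry is None:
        geometry = grid.geometry
    j0, j1 = grid.j_tip, grid.j_plate
    mag = field.magnitude

    profile = axial_profile(field)
    e_tip_axis = float(np.max(profile.magnitudes))
    e_center = float(mag[0, j0])

    if geometry is not None:
        r_edge = geometry.needle_inner_diameter / 2
        free_row = np.nonzero(grid.conductor_mask[:, j0] == FREE)[0]
        i_edge = int(free_row[np.argmin(np.abs(grid.r[free_row] - r_edge))])
        e_inner_edge = float(mag[i_edge, j0])
    else:
        e_inner_edge = e_center

    e_near_plate = float(mag[0, j1 - 1])
    z_mid = (grid.z[j0] + grid.z[j1]) / 2
    j_mid = int(np.argmin(np.abs(grid.z - z_mid)))
    e_mid_gap = float(mag[0, j_mid])

    needle_vals = [
        v for c, v in grid.dirichlet_values.items() if c == NEEDLE
    ]
    applied = needle_vals[0] if needle_vals else float("nan")
    return TipFieldReport(
        e_tip_axis=e_tip_axis,
        e_center=e_center,
        e_inner_edge=e_inner_edge,
        e_near_plate=e_near_plate,
        e_mid_gap=e_mid_gap,
        edge_to_center_ratio=e_inner_edge / e_center if e_center else float("nan"),
        applied_potential=applied,
        spacing=grid.spacing,
        mode=grid.mode,
        grid_shape=(grid.n_r, grid.n_z),
    )


def device_tip_report(
    geometry: DeviceGeometry,
    applied_potential: float,
    spacing: float = 75e-6,
    mode: str = "planar",
) -> TipFieldReport:
    """Convenience: build, solve, differentiate and report in one call."""
    (sol,) = solve_device(geometry, [applied_potential], spacing=spacing, mode=mode)
    return tip_field_report(compute_field(sol), geometry)


def refine_and_converge(
    geometry: DeviceGeometry,
    potential: OperatingPotential,
    spacings: Sequence[float],
    mode: str = "planar",
    tol: float = 0.02,
) -> pd.DataFrame:
    """Grid-dependence audit: tip metrics per spacing plus successive changes.

    Returns one row per spacing with each metric, its relative change from
    the previous (coarser) level, a ``converged`` flag (last change <= tol)
    and a ``diverging`` flag (strictly growing changes — expected for the
    mesh-registered edge value near the conductor corner, and reported
    rather than hidden).
    """
    spacings = list(spacings)
    if len(spacings) < 2:
        raise ValueError("need at least two spacings for a convergence study")
    if any(b >= a for a, b in zip(spacings, spacings[1:])):
        raise ValueError("spacings must be strictly decreasing")

    rows = []
    for h in spacings:
        report = device_tip_report(
            geometry, potential.applied_potential, spacing=h, mode=mode
        )
        rows.append({"spacing_m": h, **report.metrics()})
    table = pd.DataFrame(rows)

    for name in TipFieldReport.METRICS:
        vals = table[name].to_numpy()
        change = np.full(len(vals), np.nan)
        change[1:] = np.abs(np.diff(vals)) / np.abs(vals[:-1])
        table[f"{name}_rel_change"] = change
        table[f"{name}_converged"] = False
        table.loc[table.index[-1], f"{name}_converged"] = bool(
            change[-1] <= tol
        )
        diverging = len(vals) >= 3 and bool(
            np.all(np.diff(change[1:]) > 0)
        )
        table[f"{name}_diverging"] = diverging
    return table


def scale_linearity_check(
    report_a: TipFieldReport, report_b: TipFieldReport
) -> pd.DataFrame:
    """Percent change of every metric between two potentials on one grid.

    Laplace's equation is linear, so the measured change of every metric
    must equal the analytic prediction 100*(1 - V_b/V_a); the returned table
    carries both plus the deviation, and ``within_0p1pct`` flags agreement
    to 0.1 percentage points.
    """
    same = (
        report_a.mode == report_b.mode
        and report_a.spacing == report_b.spacing
        and report_a.grid_shape == report_b.grid_shape
    )
    if not same:
        raise ValueError(
            "reports come from different grids: "
            f"{report_a.mode}/{report_a.spacing}/{report_a.grid_shape} vs "
            f"{report_b.mode}/{report_b.spacing}/{report_b.grid_shape}"
        )
    predicted = 100.0 * (
        1.0 - report_b.applied_potential / report_a.applied_potential
    )
    rows = []
    for name in TipFieldReport.METRICS:
        va, vb = getattr(report_a, name), getattr(report_b, name)
        measured = 100.0 * (1.0 - vb / va)
        rows.append(
            {
                "metric": name,
                "measured_pct_change": measured,
                "predicted_pct_change": predicted,
                "deviation_pct_points": abs(measured - predicted),
                "within_0p1pct": abs(measured - predicted) <= 0.1,
            }
        )
    return pd.DataFrame(rows)
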