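# Methods

## Electrostatic model

The device is modelled as two perfect conductors in free space: the steel
capillary needle (bore 0.838 mm, outer diameter 1.27 mm, held at the applied
potential) and the grounded collector plate (60 mm wide, 1.5 mm thick) a
70 mm gap below the tip. The potential solves Laplace's equation (Poisson's
with zero charge density; a per-node charge density can be supplied) with
Dirichlet values on the conductors and homogeneous Neumann (zero normal
field) conditions on the open box boundaries, implemented as mirror ghost
nodes. Discretization is the standard 5-point stencil on a uniform grid.

Two formulations are provided:

* **planar** (default): 2-D Cartesian cross-section. Only the half-plane
  x ≥ 0 is stored; the Neumann mirror at x = 0 makes it exactly equivalent
  to the full symmetric domain at half the cost. The full-width view is
  available for export via `SolverGrid.full_mask()`.
* **axisymmetric**: cylindrical (r, z) Laplacian
  (1/r)∂_r(r∂_rφ) + ∂²_zφ, with radial weights 1 ± h/2r and the r = 0
  regularity stencil 4φ(h) + φ(0, z±h) − 6φ(0). The stencil is exact for
  polynomials like φ = r²z, which the test suite exploits as a
  manufactured-solution oracle.

### Why planar is the default

The original device simulation's formulation, mesh and needle length are
not published — only the resulting field values are. We solved the device
both ways and compared against those printed values (on-axis tip
1.11 MV/m, bore-center 804 kV/m, inner-edge 1.68 MV/m at 15 kV). The
axisymmetric solve concentrates the field far more strongly at a thin
annular tip (bore-center ≈ 2.3 MV/m, ~2.8× the printed value), while the
planar solve with the defaults below reproduces all printed tip-region
values within ~10% and their internal ratios (edge/center ≈ 2,
tip/center ≈ 1.4). The planar formulation is therefore the package default
as the model that matches the published field maps; the axisymmetric mode
remains available and fully tested for users modelling a rotationally
symmetric device faithfully. The default extents are: needle protrusion
10 mm, lateral half-extent 60 mm (the plate width), 10 mm margin above the
needle entry. The grid-convergence audit (`refine_and_converge`) quantifies
how each reported metric moves under refinement so the mesh dependence is
visible rather than hidden.

### Sampling conventions

Field values near the conductor corner are mesh-registered, so the sampling
rules are fixed and documented:

* **bore center** (`e_center`): |E| at the axis node in the needle-tip
  plane (the bore opening).
* **tip on axis** (`e_tip_axis`): the peak of |E| along the on-axis
  tip→plate profile. The on-axis field rises over the first few hundred
  micrometres below the bore opening (the opening is partially shielded by
  the surrounding metal at the same potential) before decaying toward the
  plate; the peak is the value quoted for "the field at the tip".
* **inner edge** (`e_inner_edge`): |E| at the free tip-plane node nearest
  r = D_i/2 (0.419 mm). This sits one node from the 90° metal corner, where
  the continuum field is singular; the audit flags it as non-converging
  under refinement by design.
* **near plate**: on-axis node one spacing above the plate. **mid gap**:
  on-axis node halfway down the gap, used as the smooth convergence metric.

Gradients are central differences in the interior and first-order one-sided
differences *into* an adjacent conductor surface, which folds the Dirichlet
boundary value into the surface-field estimate (for a linear potential this
is exact; the parallel-plate test pins it at V/d to 0.5%). Conductor nodes
carry NaN in field maps.

### Linear algebra

The free-node system is factorized once with sparse LU (SuperLU) and reused
across right-hand sides, so solving the device at 15 and 10 kV costs one
factorization plus two triangular solves (~16 s and ~2 GB at the default
75 μm spacing, a 801 × 1221 grid). A red-black SOR fallback (ω = 1.9,
relative-residual tolerance 1e-8, 100,000-sweep cap, failure carries the
last residual) covers environments where a direct factorization is
unwanted; the two paths agree to 1e-12 on shared grids. Correctness
anchors: dense solves of the identical stencil on small grids (1e-10),
the discrete maximum principle under random Dirichlet boundaries, exact
potential-scaling linearity, and the parallel-plate and manufactured
solutions above.

Default spacing is 75 μm — the finest level at which the
factorization stays comfortably inside a few GB of memory while the bore
still spans 11 nodes; the build refuses grids with fewer than 8 nodes
across the bore.

## Electrohydrodynamic scales

The four meniscus force scales are evaluated exactly as order-of-magnitude
expressions: F_e = ε₀φ², F_g = ρD_o³g, Ṗ = ρQ²/D_i², F_γ = D_oγ. Ṗ is a
momentum-flux scale, not a force on a single body, and is reported without
asserting a closed force balance. The regime rule — micro-dripping when
F_e/F_γ ≥ 1 (threshold configurable, optional upper threshold for
oscillating micro-dripping) — is the simplest dimensionally consistent
criterion; both study operating points (ratios ≈ 22 and ≈ 10 at 15 and
10 kV) classify as micro-dripping under it, matching the observed regime.
Droplet diameters in this regime are bounded by [0.05, 0.85]·D_o.

Fluid properties of the cell-laden pullulan/gelatin solution are not
published; defaults are water-like (ρ = 1000 kg/m³, γ = 0.07 N/m) and
config-exposed. Exposure metrics assume plug flow through the bore; the
wetted length for residence time defaults to the exposed needle length and
is overridable.

## Image quantification

The study measured spheroids manually with a freehand tool; automation
requires an explicit rule, chosen for determinism and auditability: Otsu
threshold on the (dark-object) image, morphological closing (radius 2 for
spheroids, none for droplets), connected components, border-touching
objects discarded. Droplets below 120 μm equivalent diameter are excluded
as satellite/debris outliers. Spheroids are counted when area ≥ 3000 μm²;
the 2500–3000 μm² borderline window is admitted when circularity
4πA/P² ≥ 0.4 — an operational proxy for the observer's "rounded mass"
judgment — and every candidate record carries its raw measurements so the
rule can be re-applied with other thresholds. Perimeters use the Crofton
estimator, whose bias stays small for few-pixel objects. Calibration comes
from the 500 μm scale bar (longest dark horizontal run in the bottom image
strip); areas are pixel counts × pixel_size².

## Assay statistics

Viability is 100 × mean(OD_sample)/mean(OD_control). ΔΔCt uses
ΔCt = Ct_target − Ct_reference per sample (GAPDH reference by default) and
fold = 2^(−ΔΔCt). The DEG rule reads |fold change| > 1.5 symmetrically on
the ratio scale: up when fold ≥ 1.5, down when fold ≤ 1/1.5, each with
strict p < 0.05; the boundary is inclusive on the fold threshold and
exclusive on p, and both thresholds are exposed. The assay-wavelength field
(605 vs 650 nm appears inconsistently in the source protocols) is metadata
only and never enters computation. Group comparisons are thin wrappers over
scipy/statsmodels (t-test, one/two-way ANOVA, Tukey HSD) and are not a
contribution of this package.

## Synthetic data

Generators emulate: high-speed frames (1024 × 512 px portrait at 4 μm/px,
anti-aliased dark discs on a bright background, diameters uniform on
200–300 μm, optional sub-120 μm outliers and one daughter droplet per
mother, Gaussian pixel noise σ = 0.02); spheroid dishes (2 μm/px,
log-normal areas with median 5000 μm² and σ_log = 0.4, slight ellipticity,
sub-2500 μm² debris, a rendered scale bar flush against the border so
segmentation drops it, and a per-day growth factor of 1.15 for day-course
emulation from a day-2 baseline); OD tables planting 90% / 70% viability at
the low/high potential with 3% CV; Ct tables with exact planted fold
changes (noise-free by default); and DEG tables planting the chondrogenesis
panel (ACAN 8.7×, SOX9 6×, collagens up and down) inside a 20-gene
chondrocyte-development term with 17 up / 3 down members, over 2000 genes
with N(0, 0.25) null log2 fold changes and uniform null p-values.

What passing round-trip tests establish: the measurement code recovers
known geometry and planted effects under these idealized conditions
(non-overlapping objects, uniform illumination, known calibration, simple
noise). What they do not establish: performance on real micrographs with
uneven illumination, touching or out-of-focus objects, meniscus artifacts,
or real RNA-seq variance structure — the generators make no attempt at
physically based rendering or read-level simulation.

## Known limitations

* No space charge, droplet charging, Taylor-cone shape or fluid–field
  coupling: the electrostatics are those of the empty (or fixed-charge)
  device.
* The inner-edge field is a corner-singularity sample and should be read as
  "the field one mesh node from the edge at the default spacing", not a
  converged continuum value.
* The planar default is a model-identification choice against published
  field values, not a statement that the physical device lacks rotational
  symmetry.
* Segmentation thresholds are global (Otsu); images with strong gradients
  need preprocessing upstream of this package.
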