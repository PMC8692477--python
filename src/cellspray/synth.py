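"""Synthetic inputs with controllable ground truth for every pipeline stage.

The generators emulate the study's raw data so all quantification stages are
testable without wet-lab inputs: 512 x 1024 px high-speed frames of dark
polydisperse droplets (200-300 um, optional sub-120 um outliers and one
secondary daughter droplet per mother), brightfield spheroid images with a
rendered 500 um scale bar, and OD / Ct / per-gene fold-change tables with
planted effects. The default DEG panel plants the study's chondrogenesis
markers (ACAN 8.7x, SOX9 6x at the high-potential contrast, with up- and
down-regulated collagens) plus a 20-gene chondrocyte-development term with
17 up / 3 down members.

Noise models are deliberately the simplest adequate ones: additive Gaussian
pixel noise on constant backgrounds, Gaussian noise on log2 fold change,
uniform null p-values. Everything is deterministic under a fixed seed, and
every generator returns its ground truth beside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from cellspray.imaging import ImageFrame


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------


def _render_ellipse(
    pixels: np.ndarray,
    center_rc: tuple[float, float],
    radii_px: tuple[float, float],
    angle: float,
    foreground: float,
) -> None:
    """Anti-aliased dark ellipse: per-pixel coverage from the normalized
    elliptical distance, blended over whatever is already in the image."""
    a, b = radii_px
    r0, c0 = center_rc
    pad = int(np.ceil(max(a, b))) + 2
    rows = np.arange(
        max(0, int(r0) - pad), min(pixels.shape[0], int(r0) + pad + 1)
    )
    cols = np.arange(
        max(0, int(c0) - pad), min(pixels.shape[1], int(c0) + pad + 1)
    )
    if rows.size == 0 or cols.size == 0:
        return
    R, C = np.meshgrid(rows - r0, cols - c0, indexing="ij")
    ca, sa = np.cos(angle), np.sin(angle)
    x = C * ca + R * sa
    y = -C * sa + R * ca
    dist = np.sqrt((x / a) ** 2 + (y / b) ** 2)
    coverage = np.clip((1.0 - dist) * min(a, b) + 0.5, 0.0, 1.0)
    patch = pixels[np.ix_(rows, cols)]
    pixels[np.ix_(rows, cols)] = patch + coverage * (foreground - patch)


def _place_disjoint(
    rng: np.random.Generator,
    shape: tuple[int, int],
    radius_px: float,
    placed: list[tuple[float, float, float]],
    margin_px: float,
    max_retries: int,
    clearance: float = 1.25,
) -> tuple[float, float]:
    """Random center keeping ``clearance`` x radii separation from others."""
    lo_r = margin_px + radius_px
    hi_r = shape[0] - margin_px - radius_px
    lo_c = margin_px + radius_px
    hi_c = shape[1] - margin_px - radius_px
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("object too large for the frame")
    for _ in range(max_retries):
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        if all(
            np.hypot(r - rr, c - cc) > clearance * (radius_px + rad)
            for rr, cc, rad in placed
        ):
            placed.append((r, c, radius_px))
            return r, c
    raise ValueError(
        f"could not place an object of radius {radius_px:.1f} px after "
        f"{max_retries} retries"
    )


# ---------------------------------------------------------------------------
# high-speed droplet frames
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DropletFrameConfig:
    """Study conditions: portrait 512 x 1024 px frames, droplets drawn
    uniformly from 200-300 um; outliers below 120 um and daughter droplets
    are off by default and switchable on."""

    n_frames: int = 10
    shape: tuple[int, int] = (1024, 512)  # (rows, cols)
    pixel_size: float = 4.0  # um/px
    droplets_per_frame: int = 3
    diameter_range: tuple[float, float] = (200.0, 300.0)  # um
    outlier_fraction: float = 0.0  # probability a droplet is a small outlier
    outlier_diameter_range: tuple[float, float] = (60.0, 110.0)  # um
    daughters: bool = False  # one secondary daughter droplet per mother
    daughter_diameter_range: tuple[float, float] = (30.0, 80.0)  # um
    background: float = 0.85
    foreground: float = 0.15
    noise_sigma: float = 0.02
    margin_px: int = 8
    max_retries: int = 500
    frame_rate: float = 7000.0  # fps, sets frame timestamps


def synth_droplet_frames(
    config: DropletFrameConfig | None = None,
    seed: int = 0,
    **overrides,
) -> tuple[list[ImageFrame], pd.DataFrame]:
    """Generate high-speed frames plus the planted-droplet ground truth.

    Returns ``(frames, truth)`` where ``truth`` has one row per planted
    object: frame, row_px, col_px, diameter_um, kind (droplet / outlier /
    daughter).
    """
    if config is None:
        config = DropletFrameConfig()
    if overrides:
        config = replace(config, **overrides)
    rng = _rng(seed)
    frames: list[ImageFrame] = []
    rows = []
    for k in range(config.n_frames):
        pixels = np.full(config.shape, config.background, dtype=float)
        placed: list[tuple[float, float, float]] = []
        for _ in range(config.droplets_per_frame):
            if config.outlier_fraction > 0 and rng.random() < config.outlier_fraction:
                kind = "outlier"
                diameter = rng.uniform(*config.outlier_diameter_range)
            else:
                kind = "droplet"
                diameter = rng.uniform(*config.diameter_range)
            radius_px = diameter / 2 / config.pixel_size
            r, c = _place_disjoint(
                rng, config.shape, radius_px, placed,
                config.margin_px, config.max_retries,
            )
            _render_ellipse(
                pixels, (r, c), (radius_px, radius_px), 0.0, config.foreground
            )
            rows.append(
                {"frame": k, "row_px": r, "col_px": c,
                 "diameter_um": diameter, "kind": kind}
            )
            if config.daughters and kind == "droplet":
                d_diam = rng.uniform(*config.daughter_diameter_range)
                d_rad = d_diam / 2 / config.pixel_size
                dr, dc = _place_disjoint(
                    rng, config.shape, d_rad, placed,
                    config.margin_px, config.max_retries,
                )
                _render_ellipse(
                    pixels, (dr, dc), (d_rad, d_rad), 0.0, config.foreground
                )
                rows.append(
                    {"frame": k, "row_px": dr, "col_px": dc,
                     "diameter_um": d_diam, "kind": "daughter"}
                )
        if config.noise_sigma > 0:
            pixels += rng.normal(0.0, config.noise_sigma, size=pixels.shape)
        frames.append(
            ImageFrame(
                pixels=np.clip(pixels, 0.0, 1.0),
                pixel_size=config.pixel_size,
                timestamp=k / config.frame_rate,
            )
        )
    truth = pd.DataFrame(
        rows, columns=["frame", "row_px", "col_px", "diameter_um", "kind"]
    )
    return frames, truth


# ---------------------------------------------------------------------------
# brightfield spheroid images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpheroidImageConfig:
    """Brightfield-like dish image: quasi-circular spheroids (log-normal
    areas, median 5000 um^2), sub-2500 um^2 cell debris, and a 500 um scale
    bar rendered flush against the bottom border."""

    shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 2.0  # um/px
    n_spheroids: int = 10
    area_median: float = 5000.0  # um^2, log-normal median
    area_sigma: float = 0.4  # sigma of log(area)
    aspect_range: tuple[float, float] = (0.8, 1.0)  # minor/major axis ratio
    n_debris: int = 20
    debris_area_range: tuple[float, float] = (100.0, 1500.0)  # um^2
    growth_per_day: float = 1.15  # daily multiplicative area growth
    baseline_day: int = 2  # day at which planted areas equal their draw
    scale_bar_um: float = 500.0
    scale_bar_thickness_px: int = 6
    background: float = 0.9
    foreground: float = 0.35
    noise_sigma: float = 0.02
    margin_px: int = 12
    max_retries: int = 500


def synth_spheroid_image(
    config: SpheroidImageConfig | None = None,
    seed: int = 0,
    day: int | None = None,
    areas: list[float] | None = None,
    **overrides,
) -> tuple[ImageFrame, pd.DataFrame]:
    """Generate a spheroid dish image plus ground-truth records.

    ``areas`` (um^2) overrides the log-normal draw; ``day`` scales planted
    areas by growth_per_day**(day - baseline_day) to emulate the day-2 to
    day-14 time course. The truth table lists every planted object with its
    analytic ellipse area and kind (spheroid / debris).
    """
    if config is None:
        config = SpheroidImageConfig()
    if overrides:
        config = replace(config, **overrides)
    rng = _rng(seed)
    pixels = np.full(config.shape, config.background, dtype=float)
    ps = config.pixel_size

    if areas is None:
        drawn = config.area_median * np.exp(
            rng.normal(0.0, config.area_sigma, size=config.n_spheroids)
        )
    else:
        drawn = np.asarray(areas, dtype=float)
    if day is not None:
        drawn = drawn * config.growth_per_day ** (day - config.baseline_day)

    placed: list[tuple[float, float, float]] = []
    rows = []
    for area in drawn:
        aspect = rng.uniform(*config.aspect_range)
        # ellipse with pi*a*b*ps^2 = area and b = aspect*a
        a_px = np.sqrt(area / (np.pi * aspect)) / ps
        b_px = aspect * a_px
        angle = rng.uniform(0, np.pi)
        r, c = _place_disjoint(
            rng, config.shape, a_px, placed, config.margin_px, config.max_retries
        )
        _render_ellipse(pixels, (r, c), (a_px, b_px), angle, config.foreground)
        rows.append(
            {"row_px": r, "col_px": c, "area_um2": float(np.pi * a_px * b_px * ps**2),
             "kind": "spheroid"}
        )
    for _ in range(config.n_debris):
        area = rng.uniform(*config.debris_area_range)
        rad = np.sqrt(area / np.pi) / ps
        r, c = _place_disjoint(
            rng, config.shape, rad, placed, config.margin_px, config.max_retries
        )
        _render_ellipse(pixels, (r, c), (rad, rad), 0.0, config.foreground)
        rows.append(
            {"row_px": r, "col_px": c, "area_um2": float(np.pi * rad**2 * ps**2),
             "kind": "debris"}
        )

    # scale bar flush to the bottom border so segmentation drops it
    bar_px = int(round(config.scale_bar_um / ps))
    if bar_px >= config.shape[1]:
        raise ValueError("scale bar longer than the image width")
    c0 = config.shape[1] - bar_px - 2 * config.margin_px
    pixels[-config.scale_bar_thickness_px :, c0 : c0 + bar_px] = 0.02

    if config.noise_sigma > 0:
        pixels += rng.normal(0.0, config.noise_sigma, size=pixels.shape)
    image = ImageFrame(
        pixels=np.clip(pixels, 0.0, 1.0),
        pixel_size=ps,
        timestamp=float(day) if day is not None else None,
    )
    truth = pd.DataFrame(rows, columns=["row_px", "col_px", "area_um2", "kind"])
    return image, truth


# ---------------------------------------------------------------------------
# assay tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OdTableConfig:
    """LDH-style OD readings: per-group true viability relative to control
    (defaults plant the study's 90% / 70% outcomes at 10 / 15 kV)."""

    control_mean: float = 0.80  # a.u.
    group_viability: Mapping[str, float] = field(
        default_factory=lambda: {"control": 1.0, "10kV": 0.90, "15kV": 0.70}
    )
    n_replicates: int = 3
    noise_cv: float = 0.03  # coefficient of variation per replicate
    wavelength_nm: float = 605.0


def synth_od_table(
    config: OdTableConfig | None = None, seed: int = 0, **overrides
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OD table plus ground truth (group, true viability fraction)."""
    if config is None:
        config = OdTableConfig()
    if overrides:
        config = replace(config, **overrides)
    rng = _rng(seed)
    rows = []
    for group, viability in config.group_viability.items():
        mean = config.control_mean * viability
        for rep in range(1, config.n_replicates + 1):
            od = mean * (1.0 + rng.normal(0.0, config.noise_cv))
            rows.append(
                {"group": group, "replicate": rep, "od": max(od, 0.0),
                 "wavelength_nm": config.wavelength_nm}
            )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [{"group": g, "true_viability": v} for g, v in config.group_viability.items()]
    )
    return table, truth


@dataclass(frozen=True)
class CtTableConfig:
    """qPCR Ct values with planted fold changes per (sample, gene) relative
    to the calibrator sample, normalized to the reference gene."""

    reference_gene: str = "GAPDH"
    calibrator_sample: str = "control"
    samples: tuple[str, ...] = ("control", "10kV", "15kV")
    planted_fold: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("15kV", "ACAN"): 8.7,
            ("10kV", "ACAN"): 4.4,
            ("15kV", "SOX9"): 6.0,
            ("10kV", "SOX9"): 3.0,
        }
    )
    reference_ct: float = 18.0
    baseline_ct: float = 26.0  # calibrator-sample Ct of every target gene
    noise_sigma: float = 0.0  # Ct noise; default exact for construction tests


def synth_ct_table(
    config: CtTableConfig | None = None, seed: int = 0, **overrides
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table plus ground truth of planted fold changes."""
    if config is None:
        config = CtTableConfig()
    if overrides:
        config = replace(config, **overrides)
    rng = _rng(seed)
    genes = sorted({gene for _, gene in config.planted_fold})
    rows = []
    for sample in config.samples:
        rows.append(
            {"sample": sample, "gene": config.reference_gene,
             "ct": config.reference_ct + rng.normal(0, config.noise_sigma)}
        )
        for gene in genes:
            fold = config.planted_fold.get((sample, gene), 1.0)
            ct = config.baseline_ct - np.log2(fold)
            rows.append(
                {"sample": sample, "gene": gene,
                 "ct": ct + rng.normal(0, config.noise_sigma)}
            )
    table = pd.DataFrame(rows, columns=["sample", "gene", "ct"])
    truth = pd.DataFrame(
        [{"sample": s, "gene": g, "true_fold": f}
         for (s, g), f in config.planted_fold.items()]
    )
    return table, truth


_CHONDRO_TERM = "CHONDROCYTE_DEVELOPMENT"


def _default_deg_panel() -> dict[str, float]:
    """Planted effects at the high-potential contrast: the study's marker
    panel plus filler members of the chondrocyte-development term (17 up,
    3 down out of 20)."""
    panel = {
        "ACAN": 8.7,
        "SOX9": 6.0,
        "COL2A1": 3.5,
        "COL9A1": 2.8,
        "COL11A1": 2.2,
        "COL1A1": 0.40,
        "COL5A1": 0.45,
        "COL15A1": 0.50,
    }
    for k in range(12):  # remaining up members of the 20-gene term
        panel[f"CHDEV{k + 1}"] = 2.0 + 0.25 * k
    return panel


def _default_go_terms() -> dict[str, list[str]]:
    members = ["ACAN", "SOX9", "COL2A1", "COL9A1", "COL11A1"] + [
        f"CHDEV{k + 1}" for k in range(12)
    ] + ["COL1A1", "COL5A1", "COL15A1"]
    return {_CHONDRO_TERM: members}


@dataclass(frozen=True)
class DegTableConfig:
    """Per-gene fold-change / p-value table with planted regulation.

    Null genes draw log2 fold change ~ N(0, null_log2_sigma) and p ~ U(0,1);
    planted genes draw log2 fold around their planted value and, with
    probability ``power``, a p-value below the threshold.
    """

    n_genes: int = 2000
    planted_fold: Mapping[str, float] = field(default_factory=_default_deg_panel)
    go_terms: Mapping[str, list[str]] = field(default_factory=_default_go_terms)
    null_log2_sigma: float = 0.25
    effect_log2_sigma: float = 0.10
    power: float = 1.0
    p_threshold: float = 0.05


def synth_deg_table(
    config: DegTableConfig | None = None, seed: int = 0, **overrides
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """DEG table, ground truth and GO-term memberships.

    Returns ``(table, truth, go_terms)``; truth has gene, true_fold and
    regulated in {up, down, null}.
    """
    if config is None:
        config = DegTableConfig()
    if overrides:
        config = replace(config, **overrides)
    rng = _rng(seed)
    rows = []
    truth_rows = []
    for gene, fold in config.planted_fold.items():
        log2fc = np.log2(fold) + rng.normal(0.0, config.effect_log2_sigma)
        if rng.random() < config.power:
            p = 10.0 ** rng.uniform(-8.0, np.log10(config.p_threshold) - 0.3)
        else:
            p = rng.uniform(config.p_threshold, 1.0)
        rows.append({"gene": gene, "fold_change": 2.0**log2fc, "p_value": p})
        truth_rows.append(
            {"gene": gene, "true_fold": fold,
             "regulated": "up" if fold > 1 else "down"}
        )
    n_null = config.n_genes - len(config.planted_fold)
    if n_null < 0:
        raise ValueError("n_genes smaller than the planted panel")
    for k in range(n_null):
        gene = f"NULL{k + 1}"
        log2fc = rng.normal(0.0, config.null_log2_sigma)
        rows.append(
            {"gene": gene, "fold_change": 2.0**log2fc,
             "p_value": rng.uniform(0.0, 1.0)}
        )
        truth_rows.append({"gene": gene, "true_fold": 1.0, "regulated": "null"})
    table = pd.DataFrame(rows, columns=["gene", "fold_change", "p_value"])
    truth = pd.DataFrame(truth_rows, columns=["gene", "true_fold", "regulated"])
    return table, truth, dict(config.go_terms)
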