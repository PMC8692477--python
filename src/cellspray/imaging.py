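"""Quantification of high-speed droplet frames and brightfield spheroid images.

Both image classes show dark objects on a bright background. Measurement
follows the study's rules: droplet equivalent diameters from thresholded
connected components with a 120 um floor (smaller objects are satellite/
debris outliers), and spheroid areas calibrated through the 500 um scale
bar, counting rounded masses above ~3000 um^2 with a borderline window at
2500-3000 um^2 admitted only when sufficiently round.

Segmentation is deterministic: Otsu threshold, morphological closing,
connected components. Objects touching the image border are discarded (they
are partially out of frame, and the rendered scale bar sits flush against
the border).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk
from skimage.segmentation import clear_border


@dataclass
class ImageFrame:
    """One grayscale image with optional spatial calibration.

    ``pixel_size`` is um/px (None for an uncalibrated image); ``timestamp``
    is seconds for high-speed frames or a day index for spheroid images.
    """

    pixels: np.ndarray
    pixel_size: float | None = None
    timestamp: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0 when given")


@dataclass(frozen=True)
class AcquisitionParams:
    frame_rate: float  # fps
    duration: float  # s
    frame_interval: float  # s
    n_frames: int


@dataclass(frozen=True)
class DropletDetection:
    frame_index: int
    centroid: tuple[float, float]  # (row, col) px
    diameter: float  # um
    area: float  # um^2


@dataclass(frozen=True)
class SpheroidRecord:
    label: int
    area: float  # um^2
    centroid: tuple[float, float]  # (row, col) px
    circularity: float  # 4*pi*A/P^2
    included: bool


def acquisition_params(frame_rate: float, duration: float) -> AcquisitionParams:
    """Frame interval and frame count of a recording (7000 fps x 5 s -> 35,000)."""
    if frame_rate <= 0 or duration <= 0:
        raise ValueError("frame_rate and duration must be > 0")
    return AcquisitionParams(
        frame_rate=frame_rate,
        duration=duration,
        frame_interval=1.0 / frame_rate,
        n_frames=int(round(frame_rate * duration)),
    )


def scale_from_bar(bar_length_px: float, bar_length_um: float = 500.0) -> float:
    """Pixel size (um/px) from a scale bar of known physical length."""
    if bar_length_px <= 0 or bar_length_um <= 0:
        raise ValueError("bar lengths must be > 0")
    return bar_length_um / bar_length_px


def measure_scale_bar(
    pixels: np.ndarray,
    search_fraction: float = 0.25,
    darkness: float = 0.15,
) -> float:
    """Length in px of the scale bar: the longest dark horizontal run in the
    bottom ``search_fraction`` of the image."""
    pixels = np.asarray(pixels, dtype=float)
    n_rows = pixels.shape[0]
    strip = pixels[int(n_rows * (1 - search_fraction)) :]
    lo, hi = float(strip.min()), float(strip.max())
    thr = lo + darkness * (hi - lo) if hi > lo else lo
    dark = strip <= thr
    best = 0
    for row in dark:
        if not row.any():
            continue
        padded = np.concatenate(([0], row.view(np.int8), [0]))
        edges = np.flatnonzero(np.diff(padded))
        runs = edges[1::2] - edges[0::2]
        best = max(best, int(runs.max()))
    if best == 0:
        raise ValueError("no scale bar found in the search strip")
    return float(best)


def _dark_objects(
    pixels: np.ndarray, threshold: float | str, closing_radius: int = 0
) -> np.ndarray:
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError("threshold must be a number or 'auto'")
        if np.ptp(pixels) == 0:
            return np.zeros_like(pixels, dtype=int)
        threshold = threshold_otsu(pixels)
    binary = pixels < threshold
    if closing_radius > 0:
        binary = closing(binary, disk(closing_radius))
    return label(clear_border(binary))


def detect_droplets(
    frame: ImageFrame,
    threshold: float | str = "auto",
    min_diameter: float = 120.0,
    frame_index: int = 0,
) -> list[DropletDetection]:
    """Dark circular droplets in a calibrated high-speed frame.

    Otsu (or fixed) threshold, connected components, border-touching objects
    discarded, objects below ``min_diameter`` (um) discarded. A blank frame
    yields an empty list.
    """
    if frame.pixel_size is None:
        raise ValueError("frame must be calibrated (pixel_size in um/px)")
    ps = frame.pixel_size
    labelled = _dark_objects(frame.pixels, threshold)
    out = []
    for prop in regionprops(labelled):
        area_um2 = prop.area * ps**2
        diameter = 2.0 * np.sqrt(area_um2 / np.pi)
        if diameter < min_diameter:
            continue
        out.append(
            DropletDetection(
                frame_index=frame_index,
                centroid=tuple(prop.centroid),
                diameter=float(diameter),
                area=float(area_um2),
            )
        )
    return out


@dataclass(frozen=True)
class DropletStats:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    polydispersity: float  # sd / mean
    sd_defined: bool  # False when n < 2 (sd reported as 0)


def droplet_diameter_stats(
    detections: Iterable[DropletDetection],
) -> DropletStats:
    """Sample statistics of detected droplet diameters (um)."""
    diameters = np.array([d.diameter for d in detections], dtype=float)
    n = diameters.size
    if n == 0:
        return DropletStats(0, float("nan"), float("nan"), float("nan"),
                            float("nan"), float("nan"), False)
    mean = float(diameters.mean())
    sd_defined = n >= 2
    sd = float(diameters.std(ddof=1)) if sd_defined else 0.0
    return DropletStats(
        n=int(n),
        mean=mean,
        sd=sd,
        min=float(diameters.min()),
        max=float(diameters.max()),
        polydispersity=sd / mean if mean else float("nan"),
        sd_defined=sd_defined,
    )


def segment_spheroids(
    image: ImageFrame,
    min_area: float = 3000.0,
    borderline_min: float = 2500.0,
    circularity_min: float = 0.4,
    threshold: float | str = "auto",
    closing_radius: int = 2,
) -> list[SpheroidRecord]:
    """Candidate spheroids in a calibrated brightfield image.

    Every connected dark object is returned with its raw measurements; the
    ``included`` flag applies the area rule: area >= ``min_area`` um^2, or a
    borderline object in [``borderline_min``, ``min_area``) that is round
    enough (circularity >= ``circularity_min`` — the automated proxy for the
    observer call on borderline condensations).
    """
    if image.pixel_size is None:
        raise ValueError("image must be calibrated (pixel_size in um/px)")
    ps = image.pixel_size
    labelled = _dark_objects(image.pixels, threshold, closing_radius)
    records = []
    for prop in regionprops(labelled):
        area_um2 = prop.area * ps**2
        # Crofton estimate: bias stays small down to few-pixel objects
        perimeter = prop.perimeter_crofton * ps
        circularity = (
            4.0 * np.pi * area_um2 / perimeter**2 if perimeter > 0 else 0.0
        )
        included = area_um2 >= min_area or (
            borderline_min <= area_um2 < min_area
            and circularity >= circularity_min
        )
        records.append(
            SpheroidRecord(
                label=int(prop.label),
                area=float(area_um2),
                centroid=tuple(prop.centroid),
                circularity=float(circularity),
                included=bool(included),
            )
        )
    return records


def records_to_frame(
    records: Sequence[SpheroidRecord],
    dish: str | None = None,
    day: int | None = None,
) -> pd.DataFrame:
    rows = [
        {
            "label": r.label,
            "area_um2": r.area,
            "circularity": r.circularity,
            "row_px": r.centroid[0],
            "col_px": r.centroid[1],
            "included": r.included,
        }
        for r in records
    ]
    frame = pd.DataFrame(
        rows,
        columns=["label", "area_um2", "circularity", "row_px", "col_px", "included"],
    )
    if dish is not None:
        frame.insert(0, "dish", dish)
    if day is not None:
        frame.insert(0, "day", day)
    return frame


def detections_to_frame(detections: Sequence[DropletDetection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "frame": d.frame_index,
                "row_px": d.centroid[0],
                "col_px": d.centroid[1],
                "diameter_um": d.diameter,
                "area_um2": d.area,
            }
            for d in detections
        ],
        columns=["frame", "row_px", "col_px", "diameter_um", "area_um2"],
    )


def spheroid_area_summary(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-dish and per-day totals of included spheroid areas.

    ``records`` needs columns ``dish``, ``day``, ``area_um2``, ``included``.
    Returns ``(per_dish, per_day)``: totals/means/counts per (day, dish),
    then the day-level mean of per-dish totals — the study's 'average total
    spheroid area per dish' time course.
    """
    required = {"dish", "day", "area_um2", "included"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table is missing columns: {sorted(missing)}")
    if len(records) == 0:
        raise ValueError("records table is empty")
    inc = records[records["included"]]
    keys = records[["day", "dish"]].drop_duplicates()
    grouped = (
        inc.groupby(["day", "dish"])["area_um2"]
        .agg(total_area_um2="sum", mean_area_um2="mean", n_spheroids="count")
        .reset_index()
    )
    per_dish = keys.merge(grouped, on=["day", "dish"], how="left")
    per_dish["total_area_um2"] = per_dish["total_area_um2"].fillna(0.0)
    per_dish["n_spheroids"] = per_dish["n_spheroids"].fillna(0).astype(int)
    per_day = (
        per_dish.groupby("day")
        .agg(
            mean_total_area_per_dish_um2=("total_area_um2", "mean"),
            n_dishes=("dish", "nunique"),
            total_spheroids=("n_spheroids", "sum"),
        )
        .reset_index()
    )
    return per_dish, per_day
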