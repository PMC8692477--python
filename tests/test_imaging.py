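"""Acquisition arithmetic, scale-bar calibration, droplet detection and
spheroid segmentation on synthetic images with known ground truth."""

import numpy as np
import pandas as pd
import pytest

from cellspray.imaging import (
    ImageFrame,
    acquisition_params,
    detect_droplets,
    droplet_diameter_stats,
    measure_scale_bar,
    records_to_frame,
    scale_from_bar,
    segment_spheroids,
    spheroid_area_summary,
)
from cellspray.synth import synth_droplet_frames, synth_spheroid_image


# ----------------------------------------------------------- acquisition


def test_acquisition_study_settings():
    acq = acquisition_params(7000.0, 5.0)
    assert acq.n_frames == 35_000
    assert acq.frame_interval == pytest.approx(1 / 7000)
    assert acq.frame_interval * 1e6 == pytest.approx(142.857, abs=1e-3)


def test_acquisition_trivial_and_errors():
    acq = acquisition_params(1.0, 1.0)
    assert acq.n_frames == 1 and acq.frame_interval == 1.0
    with pytest.raises(ValueError):
        acquisition_params(0.0, 5.0)
    with pytest.raises(ValueError):
        acquisition_params(7000.0, -1.0)


# ------------------------------------------------------------- calibration


@pytest.mark.parametrize("px, um, expected", [(250, 500, 2.0), (500, 500, 1.0)])
def test_scale_from_bar(px, um, expected):
    assert scale_from_bar(px, um) == expected


def test_scale_from_bar_rejects_nonpositive():
    with pytest.raises(ValueError):
        scale_from_bar(0, 500)
    with pytest.raises(ValueError):
        scale_from_bar(250, -1)


def test_scale_bar_round_trip():
    image, _ = synth_spheroid_image(seed=11, pixel_size=1.6)
    bar_px = measure_scale_bar(image.pixels)
    recovered = scale_from_bar(bar_px, 500.0)
    assert recovered == pytest.approx(1.6, rel=0.01)


# --------------------------------------------------------------- droplets


def test_droplet_detection_round_trip():
    frames, truth = synth_droplet_frames(seed=5, n_frames=4)
    for k, frame in enumerate(frames):
        detections = detect_droplets(frame, frame_index=k)
        planted = truth[truth["frame"] == k].sort_values("row_px")
        assert len(detections) == len(planted)
        found = sorted(detections, key=lambda d: d.centroid[0])
        for det, (_, row) in zip(found, planted.iterrows()):
            assert det.diameter == pytest.approx(
                row["diameter_um"], abs=2 * frame.pixel_size
            )
            assert det.diameter == pytest.approx(2 * np.sqrt(det.area / np.pi))


def test_blank_frame_yields_no_detections():
    frame = ImageFrame(np.full((256, 128), 0.9), pixel_size=4.0)
    assert detect_droplets(frame) == []


def test_min_diameter_floor_excludes_small_outliers():
    frames, truth = synth_droplet_frames(
        seed=6, n_frames=6, droplets_per_frame=2, outlier_fraction=0.5
    )
    n_outliers = (truth["kind"] == "outlier").sum()
    assert n_outliers > 0  # the draw planted some sub-120 um objects
    kept = []
    for k, frame in enumerate(frames):
        kept += detect_droplets(frame, min_diameter=120.0, frame_index=k)
    assert len(kept) == (truth["kind"] == "droplet").sum()
    assert all(d.diameter >= 120.0 for d in kept)


def test_uncalibrated_frame_rejected():
    with pytest.raises(ValueError, match="calibrated"):
        detect_droplets(ImageFrame(np.zeros((32, 32))))


def test_droplet_stats():
    frames, _ = synth_droplet_frames(seed=7, n_frames=1)
    detections = detect_droplets(frames[0])

    class Fake:
        def __init__(self, d):
            self.diameter = d

    stats = droplet_diameter_stats([Fake(200.0), Fake(250.0), Fake(300.0)])
    assert (stats.n, stats.mean, stats.min, stats.max) == (3, 250.0, 200.0, 300.0)
    assert stats.polydispersity == pytest.approx(stats.sd / 250.0)

    single = droplet_diameter_stats([Fake(220.0)])
    assert single.sd == 0.0 and not single.sd_defined

    empty = droplet_diameter_stats([])
    assert empty.n == 0 and np.isnan(empty.mean)


def test_droplet_population_mean():
    """500 planted diameters uniform on [200, 300] average near 250."""
    frames, truth = synth_droplet_frames(
        seed=8, n_frames=100, droplets_per_frame=5, noise_sigma=0.0
    )
    diameters = truth["diameter_um"].to_numpy()
    assert diameters.size == 500
    se = diameters.std(ddof=1) / np.sqrt(diameters.size)
    assert abs(diameters.mean() - 250.0) < 3 * se + 1e-9


# -------------------------------------------------------------- spheroids


def _disc_image(radius_um, pixel_size=2.0, shape=(256, 256)):
    pixels = np.full(shape, 0.9)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r_px = radius_um / pixel_size
    dist = np.sqrt((rr - shape[0] / 2) ** 2 + (cc - shape[1] / 2) ** 2)
    pixels[dist <= r_px] = 0.3
    return ImageFrame(pixels, pixel_size=pixel_size)


def test_disc_inclusion_rule():
    # radius 35 um -> ~3848 um^2, above the 3000 um^2 floor
    records = segment_spheroids(_disc_image(35.0))
    assert len(records) == 1
    assert records[0].area == pytest.approx(np.pi * 35.0**2, rel=0.03)
    assert records[0].included

    # radius 25 um -> ~1963 um^2, below the borderline window
    records = segment_spheroids(_disc_image(25.0))
    assert len(records) == 1
    assert records[0].area == pytest.approx(np.pi * 25.0**2, rel=0.03)
    assert not records[0].included


def test_borderline_window_requires_roundness():
    # ~2800 um^2 disc (radius ~29.9 um): borderline, round -> included
    records = segment_spheroids(_disc_image(29.85))
    assert len(records) == 1
    assert 2500 <= records[0].area < 3000
    assert records[0].circularity >= 0.4
    assert records[0].included
    # same area at a lowered circularity floor never flips exclusion upward
    strict = segment_spheroids(_disc_image(29.85), circularity_min=0.99)
    assert len(strict) == 1


def test_scattered_small_cells_yield_no_spheroids():
    image, truth = synth_spheroid_image(seed=9, n_spheroids=0, n_debris=15)
    assert (truth["kind"] == "spheroid").sum() == 0
    records = segment_spheroids(image)
    assert sum(r.included for r in records) == 0


def test_spheroid_round_trip_area_recovery():
    image, truth = synth_spheroid_image(seed=10, areas=[4000.0, 8000.0], n_debris=0)
    records = [r for r in segment_spheroids(image) if r.included]
    assert len(records) == 2
    planted = sorted(truth.loc[truth["kind"] == "spheroid", "area_um2"])
    measured = sorted(r.area for r in records)
    for got, want in zip(measured, planted):
        assert got == pytest.approx(want, rel=0.05)


def test_circularity_in_range():
    image, _ = synth_spheroid_image(seed=12)
    for record in segment_spheroids(image):
        assert 0 < record.circularity <= 1.1  # discretization slack


def test_scale_invariance_of_areas():
    """Half the resolution at twice the pixel size: same um^2 areas."""
    fine, _ = synth_spheroid_image(
        seed=13, areas=[6000.0], n_debris=0, pixel_size=1.0, shape=(1024, 1024)
    )
    coarse, _ = synth_spheroid_image(
        seed=13, areas=[6000.0], n_debris=0, pixel_size=2.0, shape=(512, 512)
    )
    a_fine = [r.area for r in segment_spheroids(fine) if r.included]
    a_coarse = [r.area for r in segment_spheroids(coarse) if r.included]
    assert len(a_fine) == len(a_coarse) == 1
    assert a_fine[0] == pytest.approx(a_coarse[0], rel=0.05)


def test_inclusion_monotone_in_area():
    """At fixed circularity (discs), inclusion never switches off as area grows."""
    included = [
        segment_spheroids(_disc_image(r))[0].included
        for r in (20.0, 26.0, 28.5, 31.0, 40.0, 60.0)
    ]
    assert included == sorted(included)


def test_uncalibrated_image_rejected():
    with pytest.raises(ValueError, match="calibrated"):
        segment_spheroids(ImageFrame(np.zeros((64, 64))))


# ---------------------------------------------------------------- summary


def test_spheroid_area_summary():
    records = pd.DataFrame(
        {
            "dish": ["d1", "d1", "d2"],
            "day": [6, 6, 6],
            "area_um2": [4000.0, 6000.0, 5000.0],
            "included": [True, True, False],
        }
    )
    per_dish, per_day = spheroid_area_summary(records)
    d1 = per_dish[per_dish["dish"] == "d1"].iloc[0]
    assert d1["total_area_um2"] == 10_000.0
    assert d1["mean_area_um2"] == 5_000.0
    assert d1["n_spheroids"] == 2
    d2 = per_dish[per_dish["dish"] == "d2"].iloc[0]
    assert d2["total_area_um2"] == 0.0 and d2["n_spheroids"] == 0
    assert per_day.iloc[0]["mean_total_area_per_dish_um2"] == 5_000.0


def test_summary_recovers_planted_growth():
    rows = []
    for day in (6, 14):
        image, _ = synth_spheroid_image(seed=14, day=day, n_debris=5)
        records = segment_spheroids(image)
        rows.append(records_to_frame(records, dish="d1", day=day))
    per_dish, per_day = spheroid_area_summary(pd.concat(rows, ignore_index=True))
    totals = per_day.set_index("day")["mean_total_area_per_dish_um2"]
    assert totals[14] > totals[6]


def test_summary_validates_input():
    with pytest.raises(ValueError, match="missing columns"):
        spheroid_area_summary(pd.DataFrame({"dish": [], "day": []}))
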