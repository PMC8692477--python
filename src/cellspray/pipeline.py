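"""End-to-end pipeline: reproduce the study's computational outputs from a
single configuration — field solves at both operating potentials, the
linearity audit, the meniscus force-scale table and mode call, acquisition
arithmetic, and synthetic-data demonstrations of every quantification stage.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

import cellspray
from cellspray import config as cfg
from cellspray.assays import delta_delta_ct, deg_filter, go_term_summary, viability_percent
from cellspray.device import OperatingPotential
from cellspray.ehd import classify_mode, droplet_diameter_bounds, exposure_report, force_scales
from cellspray.field import (
    compute_field,
    axial_profile,
    scale_linearity_check,
    solve_device,
    tip_field_report,
    transverse_tip_profile,
)
from cellspray.imaging import (
    acquisition_params,
    detect_droplets,
    detections_to_frame,
    droplet_diameter_stats,
    measure_scale_bar,
    records_to_frame,
    scale_from_bar,
    segment_spheroids,
)
from cellspray.synth import (
    synth_ct_table,
    synth_deg_table,
    synth_droplet_frames,
    synth_od_table,
    synth_spheroid_image,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records which."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    tool_version: str
    stages: list[dict] = dc_field(default_factory=list)
    outputs: list[str] = dc_field(default_factory=list)

    def record(self, name: str, status: str, seconds: float, outputs: list[str],
               error: str | None = None) -> None:
        self.stages.append(
            {"name": name, "status": status, "wall_seconds": round(seconds, 3),
             "outputs": outputs, **({"error": error} if error else {})}
        )
        self.outputs.extend(outputs)

    @property
    def ok(self) -> bool:
        return all(s["status"] == "ok" for s in self.stages)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "seed": self.seed,
             "tool_version": self.tool_version, "stages": self.stages,
             "outputs": self.outputs},
            indent=2, sort_keys=True,
        )


def _save_field_maps(out: Path, tag: str, solution, field_map) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    pot_csv = out / f"potential_{tag}.csv"
    np.savetxt(pot_csv, solution.values, delimiter=",")
    paths.append(str(pot_csv))
    mag_csv = out / f"field_magnitude_{tag}.csv"
    np.savetxt(mag_csv, field_map.magnitude, delimiter=",")
    paths.append(str(mag_csv))

    grid = solution.grid
    extent = [grid.z[0] * 1e3, grid.z[-1] * 1e3, 0.0, grid.r[-1] * 1e3]
    for name, data, unit in [
        ("potential", solution.values / 1e3, "kV"),
        ("field", field_map.magnitude / 1e6, "MV/m"),
    ]:
        fig, ax = plt.subplots(figsize=(7, 3))
        im = ax.imshow(data, origin="lower", aspect="auto", extent=extent)
        ax.set_xlabel("z from needle tip (mm)")
        ax.set_ylabel("r (mm)")
        fig.colorbar(im, ax=ax, label=unit)
        png = out / f"{name}_{tag}.png"
        fig.savefig(png, dpi=110)
        plt.close(fig)
        paths.append(str(png))
    return paths


def run_study_pipeline(
    config: Mapping | None = None,
    out_dir: str | Path = "cellspray_out",
    seed: int | None = None,
) -> RunManifest:
    """Run every computational stage and write artifacts plus a manifest.

    Deterministic for a fixed config and seed. Raises
    :class:`PipelineError` after writing the manifest if any stage failed.
    """
    config = dict(cfg.default_config() if config is None else config)
    for key in cfg.DEFAULT_CONFIG:
        cfg.require(config, key)
    if seed is None:
        seed = int(config["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, seed=seed, tool_version=cellspray.__version__)

    geometry = cfg.geometry_from_config(config)
    spacing = cfg.spacing_from_config(config)
    mode = str(config["mode"])
    v_hi = float(config["potential_kV"]) * 1e3
    v_lo = float(config["potential_low_kV"]) * 1e3

    reports = {}
    field_hi = None

    # --- stage: field solves at both potentials -------------------------
    t0 = time.time()
    try:
        solutions = solve_device(geometry, [v_hi, v_lo], spacing=spacing, mode=mode)
        paths = []
        for sol, v in zip(solutions, (v_hi, v_lo)):
            tag = f"{v / 1e3:g}kV"
            fmap = compute_field(sol)
            if v == v_hi:
                field_hi = fmap
            reports[v] = tip_field_report(fmap, geometry)
            paths += _save_field_maps(out, tag, sol, fmap)
            for profile in (axial_profile(fmap), transverse_tip_profile(fmap)):
                p = out / f"profile_{profile.axis_label}_{tag}.csv"
                profile.to_frame().to_csv(p, index=False)
                paths.append(str(p))
        rep_csv = out / "tip_field_reports.csv"
        pd.DataFrame([r.to_dict() for r in reports.values()]).to_csv(
            rep_csv, index=False
        )
        paths.append(str(rep_csv))
        manifest.record("field_solves", "ok", time.time() - t0, paths)
    except Exception as exc:
        manifest.record("field_solves", "failed", time.time() - t0, [], repr(exc))

    # --- stage: linearity audit -----------------------------------------
    t0 = time.time()
    try:
        table = scale_linearity_check(reports[v_hi], reports[v_lo])
        p = out / "linearity_check.csv"
        table.to_csv(p, index=False)
        manifest.record("linearity_check", "ok", time.time() - t0, [str(p)])
    except Exception as exc:
        manifest.record("linearity_check", "failed", time.time() - t0, [], repr(exc))

    # --- stage: EHD force scales and exposure ---------------------------
    t0 = time.time()
    try:
        fluid = cfg.fluid_from_config(config)
        rows = []
        for key in ("potential_kV", "potential_low_kV"):
            op = cfg.conditions_from_config(config, key)
            scales = force_scales(fluid, op)
            mode_call = classify_mode(
                scales, geometry, threshold=float(config["mode_threshold"])
            )
            row = {"potential_kV": float(config[key]), **scales.to_dict(),
                   "mode": mode_call.mode}
            if field_hi is not None and key == "potential_kV":
                exposure = exposure_report(op, field_hi)
                row.update(
                    mean_exit_velocity_m_s=exposure.mean_exit_velocity,
                    needle_residence_time_s=exposure.needle_residence_time,
                    peak_field_on_path_V_m=exposure.peak_field_on_path,
                    field_at_exit_center_V_m=exposure.field_at_exit_center,
                )
            rows.append(row)
        bounds = droplet_diameter_bounds(geometry)
        ehd = {
            "table": rows,
            "droplet_diameter_bounds_um": [b * 1e6 for b in bounds],
        }
        p = out / "ehd_report.json"
        p.write_text(json.dumps(ehd, indent=2))
        manifest.record("ehd_report", "ok", time.time() - t0, [str(p)])
    except Exception as exc:
        manifest.record("ehd_report", "failed", time.time() - t0, [], repr(exc))

    # --- stage: acquisition arithmetic ----------------------------------
    t0 = time.time()
    try:
        acq = acquisition_params(
            float(config["frame_rate_fps"]), float(config["video_duration_s"])
        )
        p = out / "acquisition.json"
        p.write_text(
            json.dumps(
                {"frame_rate_fps": acq.frame_rate, "duration_s": acq.duration,
                 "frame_interval_us": acq.frame_interval * 1e6,
                 "n_frames": acq.n_frames},
                indent=2,
            )
        )
        manifest.record("acquisition", "ok", time.time() - t0, [str(p)])
    except Exception as exc:
        manifest.record("acquisition", "failed", time.time() - t0, [], repr(exc))

    # --- stage: synthetic quantification demos --------------------------
    t0 = time.time()
    try:
        paths = []
        frames, truth = synth_droplet_frames(seed=seed, n_frames=3)
        detections = []
        for k, frame in enumerate(frames):
            detections += detect_droplets(frame, frame_index=k)
        stats = droplet_diameter_stats(detections)
        p = out / "droplet_detections.csv"
        detections_to_frame(detections).to_csv(p, index=False)
        paths.append(str(p))
        p = out / "droplet_truth.csv"
        truth.to_csv(p, index=False)
        paths.append(str(p))

        image, sp_truth = synth_spheroid_image(seed=seed + 1)
        bar_px = measure_scale_bar(image.pixels)
        pixel_size = scale_from_bar(bar_px)
        records = segment_spheroids(image)
        p = out / "spheroid_records.csv"
        records_to_frame(records, dish="demo", day=14).to_csv(p, index=False)
        paths.append(str(p))

        od, od_truth = synth_od_table(seed=seed + 2)
        p = out / "od_table.csv"
        od.to_csv(p, index=False)
        paths.append(str(p))
        viability = {
            group: viability_percent(
                od.loc[od["group"] == group, "od"],
                od.loc[od["group"] == "control", "od"],
            )
            for group in od["group"].unique()
        }

        ct, ct_truth = synth_ct_table(seed=seed + 3)
        p = out / "ct_table.csv"
        ct.to_csv(p, index=False)
        paths.append(str(p))
        acan_fold = delta_delta_ct(ct, "ACAN", "15kV", "control")

        deg, deg_truth, go_terms = synth_deg_table(seed=seed + 4)
        p = out / "deg_table.csv"
        deg.to_csv(p, index=False)
        paths.append(str(p))
        up, down = deg_filter(deg)
        term = next(iter(go_terms))
        go = go_term_summary(deg, term, go_terms[term])

        summary = {
            "droplet_stats": {
                "n": stats.n, "mean_um": stats.mean, "sd_um": stats.sd,
                "min_um": stats.min, "max_um": stats.max,
                "polydispersity": stats.polydispersity,
            },
            "spheroids": {
                "pixel_size_um_per_px": pixel_size,
                "n_candidates": len(records),
                "n_included": int(sum(r.included for r in records)),
            },
            "viability_percent": viability,
            "acan_fold_change_15kV": acan_fold,
            "deg_counts": {"up": len(up), "down": len(down)},
            "go_summary": {
                "term": go.term, "n_members": go.n_members,
                "n_up": go.n_up, "n_down": go.n_down,
                "n_unchanged": go.n_unchanged,
            },
        }
        p = out / "quantification_summary.json"
        p.write_text(json.dumps(summary, indent=2))
        paths.append(str(p))
        manifest.record("synthetic_quantification", "ok", time.time() - t0, paths)
    except Exception as exc:
        manifest.record(
            "synthetic_quantification", "failed", time.time() - t0, [], repr(exc)
        )

    manifest_path = out / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    if not manifest.ok:
        failed = [s["name"] for s in manifest.stages if s["status"] != "ok"]
        raise PipelineError(f"stages failed: {failed} (see {manifest_path})")
    return manifest
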