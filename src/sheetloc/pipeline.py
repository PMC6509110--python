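"""End-to-end pipeline: simulate -> localize -> drift -> deskew -> render -> FRC -> NPC.

Every stage logs its parameters and record counts; seeds come from the config
so a run is deterministic.  A stage failure aborts with the stage name while
partial outputs written by earlier stages remain on disk.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
import tifffile

from . import calibration as cal
from . import frc as frc_mod
from . import io as io_mod
from . import localize as loc_mod
from . import npc as npc_mod
from . import optics
from . import postprocess as post
from . import simulate as sim

__all__ = ["run_pipeline", "PipelineError", "default_calibration"]

log = logging.getLogger("sheetloc")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_calibration(z_half_range_nm: float = 600.0) -> cal.AstigCalibration:
    """A representative astigmatic calibration for simulation work.

    In-focus width 150 nm, foci split +/-250 nm, 400 nm defocus depth — the
    scale a weak cylindrical-lens astigmatism produces at this magnification.
    """
    return cal.AstigCalibration(
        x=cal.AxisDefocus(150.0, -250.0, 400.0),
        y=cal.AxisDefocus(150.0, 250.0, 400.0),
        z_range_nm=(-z_half_range_nm, z_half_range_nm),
    )


def _setup_logging(out_dir: str, verbose: bool) -> None:
    log.setLevel(logging.DEBUG if verbose else logging.INFO)
    log.handlers = [logging.StreamHandler()]
    fh = logging.FileHandler(os.path.join(out_dir, "pipeline.log"), mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


def run_pipeline(config: dict, out_dir: str | None = None, verbose: bool = False) -> dict:
    """Execute the configured pipeline and write artifacts to ``out_dir``.

    Returns a dict of in-memory results (tables, traces, curves, npc output).
    """
    cfg = io_mod.validate_config(config)
    out_dir = out_dir or cfg["paths"]["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    _setup_logging(out_dir, verbose)
    results: dict = {}

    camera = sim.CameraModel(**cfg["camera"])
    spec = optics.BesselBeamSpec(
        cfg["optics"]["wavelength_nm"], cfg["optics"]["na_inner"], cfg["optics"]["na_outer"]
    )
    fwhm = optics.sheet_thickness_fwhm(spec)
    geom = sim.AcquisitionGeometry(
        sheet_angle_deg=cfg["optics"]["scan_angle_deg"],
        scan_step_nm=cfg["geometry"]["scan_step_nm"],
        n_planes=cfg["geometry"]["n_planes"],
        exposure_s=cfg["geometry"]["exposure_s"],
        sheet_fwhm_nm=fwhm,
        sidelobe_fraction=cfg["geometry"]["sidelobe_fraction"],
        img_shape=tuple(cfg["geometry"]["img_shape"]),
    )
    log.info(
        "configuration: pixel=%.0f nm, sheet angle=%.1f deg, sheet FWHM=%.0f nm, "
        "npc bin=%.0f nm, area window=%s px^2, roi=%d, n_top=%d, frc threshold=%.4f",
        camera.pixel_size_nm, geom.sheet_angle_deg, fwhm,
        cfg["npc"]["bin_pixel_nm"], cfg["npc"]["area_bounds_px"],
        cfg["npc"]["roi_size_px"], cfg["npc"]["n_top"], cfg["frc"]["threshold"],
    )

    calib_path = cfg["calibration"]["path"]
    calib = cal.load_calibration(calib_path) if calib_path else default_calibration()

    stage = "simulate"
    try:
        if cfg["simulate"]["enabled"]:
            seed = int(cfg["seeds"]["simulate"])
            kind = cfg["simulate"]["kind"]
            truth = sim.make_ground_truth(kind, cfg["simulate"]["structure_params"], seed)
            if cfg["simulate"]["fiducials"]:
                fids = sim.make_ground_truth(
                    "fiducial", {"n": cfg["simulate"]["fiducials"]}, seed + 1
                )
                truth = sim.EmitterSet.concatenate([truth, fids])
            stacks, events = sim.simulate_series(
                truth,
                sim.BlinkingModel(**cfg["blinking"]),
                camera,
                geom,
                calib,
                seed,
                n_volumes=cfg["simulate"]["n_volumes"],
                background_photons=cfg["simulate"]["background_photons"],
                drift_per_frame_nm=tuple(cfg["simulate"]["drift_per_frame_nm"]),
            )
            for v in range(stacks.shape[0]):
                io_mod.write_stack(stacks[v], os.path.join(out_dir, f"stack_vol{v:04d}.tif"))
            events.to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)
            results["stacks"], results["truth_events"] = stacks, events
            log.info("simulate: %d emitters, %d volumes, %d truth events",
                     len(truth), stacks.shape[0], len(events))
        else:
            stacks = None

        stage = "localize"
        if stacks is not None:
            params = loc_mod.DetectionParams(
                filter_scale_px=cfg["detection"]["filter_scale_px"],
                threshold_k=cfg["detection"]["threshold_k"],
                roi_half_px=cfg["detection"]["roi_half_px"],
                max_uncertainty_xy_nm=cfg["detection"]["max_uncertainty_xy_nm"],
                sigma_bounds_nm=tuple(cfg["detection"]["sigma_bounds_nm"]),
                uncertainty_model=cfg["detection"]["uncertainty_model"],
            )
            tables = []
            for v in range(stacks.shape[0]):
                tables.append(
                    loc_mod.localize_stack(
                        stacks[v], calib, camera, params,
                        volume=v, frame_offset=v * geom.n_planes,
                    )
                )
            table = pd.concat(tables, ignore_index=True)
            table = loc_mod.filter_localizations(
                table,
                max_uncertainty_xy_nm=params.max_uncertainty_xy_nm,
                sigma_bounds_nm=params.sigma_bounds_nm,
                require_valid_z=True,
            ).reset_index(drop=True)
            io_mod.write_localizations(table, os.path.join(out_dir, "localizations.csv"))
            results["localizations"] = table
            log.info("localize: %d events kept", len(table))
        else:
            table = results.get("localizations")

        stage = "drift"
        if table is not None and len(table) and cfg["drift"]["method"]:
            try:
                if cfg["drift"]["method"] == "fiducial":
                    trace = post.track_fiducials(
                        table,
                        link_radius_nm=cfg["drift"]["link_radius_nm"],
                        smoothing_window=cfg["drift"]["smoothing_window"],
                    )
                else:
                    trace = post.estimate_drift_xcorr(
                        table, cfg["drift"]["block_frames"], cfg["drift"]["render_pixel_nm"]
                    )
                table = post.apply_drift(table, trace)
                results["drift_trace"] = trace
                log.info("drift (%s): trace span x=%.1f nm y=%.1f nm",
                         trace.method, np.ptp(trace.dx), np.ptp(trace.dy))
            except ValueError as exc:
                log.warning("drift correction skipped: %s", exc)

        stage = "deskew"
        if table is not None and len(table):
            table = post.deskew(table, geom.sheet_angle_deg, geom.scan_step_nm)
            io_mod.write_localizations(
                table, os.path.join(out_dir, "localizations_deskewed.csv")
            )
            results["table"] = table

        stage = "render"
        if table is not None and len(table):
            img = post.render_density(
                table,
                cfg["render"]["pixel_nm"],
                mode="2d",
                sigma_source=cfg["render"]["sigma_source"],
                fixed_sigma_nm=cfg["render"]["fixed_sigma_nm"],
            )
            tifffile.imwrite(os.path.join(out_dir, "density.tif"), img.astype(np.float32))
            results["density"] = img
            log.info("render: %dx%d px at %.0f nm", *img.shape, cfg["render"]["pixel_nm"])

        stage = "frc"
        if table is not None and len(table) >= frc_mod.MIN_EVENTS:
            curve = frc_mod.frc_curve(
                table,
                cfg["frc"]["render_pixel_nm"],
                cfg["frc"]["n_splits"],
                seed=int(cfg["seeds"]["frc"]),
            )
            res, bound = frc_mod.frc_resolution(curve)
            pd.DataFrame(
                {
                    "frequency_nm_inv": curve.spatial_frequency_nm_inv,
                    "correlation": curve.correlation,
                }
            ).to_csv(os.path.join(out_dir, "frc_curve.csv"), index=False)
            results["frc_resolution_nm"] = res
            log.info("frc: resolution %.1f nm%s", res, " (bound)" if bound else "")

        stage = "npc"
        if cfg["npc"]["enabled"] and table is not None and len(table):
            npc_params = npc_mod.NpcParams(
                bin_pixel_nm=cfg["npc"]["bin_pixel_nm"],
                area_bounds_px=tuple(cfg["npc"]["area_bounds_px"]),
                dilation_size_px=cfg["npc"]["dilation_size_px"],
                roi_size_px=cfg["npc"]["roi_size_px"],
                n_top=cfg["npc"]["n_top"],
                kde_grid_nm=cfg["npc"]["kde_grid_nm"],
                kde_bandwidth_rule=cfg["npc"]["kde_bandwidth_rule"],
            )
            npc_result = npc_mod.average_pipeline(table, npc_params)
            npc_result["summary"].to_csv(os.path.join(out_dir, "npc_fits.csv"), index=False)
            if npc_result["overlay"] is not None:
                tifffile.imwrite(
                    os.path.join(out_dir, "npc_overlay.tif"),
                    npc_result["overlay"].astype(np.float32),
                )
            results["npc"] = npc_result
            log.info("npc: %d candidates, diameter %.1f nm",
                     len(npc_result["candidates"]), npc_result["diameter_nm"])
    except PipelineError:
        raise
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
    return results
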