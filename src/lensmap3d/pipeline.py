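"""End-to-end pipeline: detect -> map -> zones (-> roi), with manifests.

Stages hand data to each other through plain files (TIFF stacks, CSV
point tables, JSON frames) so each stage can be re-run and inspected in
isolation; a manifest records every effective parameter, package
versions, the seed and input checksums, making runs reproducible
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detection import DetectionParams, detect_nuclei
from .geometry import LensFrame, align_to_canonical, build_frame, spherical_coordinates
from .roi import ROISpec, roi_density
from .stackio import read_points, read_stack, write_points, write_stack
from .synthetic import (
    SynthConfig,
    boundary_landmarks,
    mature_config,
    render_stack,
    sample_epithelium,
    young_config,
)
from .zones import local_density_map, theta_density_profile, zone_segmentation

__all__ = ["map_points", "run_pipeline", "preset_config", "StageError"]

log = logging.getLogger(__name__)

PRESETS = {"mature": mature_config, "young": young_config}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def preset_config(name: str, seed: int = 0, **overrides) -> SynthConfig:
    """Look up a synthetic preset by name."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise StageError(f"synth: unknown preset {name!r} (have {sorted(PRESETS)})")
    return factory(seed=seed, **overrides)


def map_points(
    points: pd.DataFrame,
    landmarks,
    refine: bool = True,
    ap_tol_frac: float = 0.1,
):
    """Mapping stage: fit the lens frame and assign spherical angles.

    Returns ``(mapped_table, frame)``; the table gains filled
    ``theta_deg``/``phi_deg`` columns (coordinates are left in the
    input frame; the rigid transform lives in the returned
    :class:`~lensmap3d.geometry.LensFrame`).
    """
    xyz = points[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    frame = build_frame(xyz, landmarks, refine=refine, ap_tol_frac=ap_tol_frac)
    canonical = align_to_canonical(xyz, frame)
    theta, phi = spherical_coordinates(canonical, frame.r_max, frame.r_min)
    mapped = points.copy()
    mapped["theta_deg"] = theta
    mapped["phi_deg"] = phi
    return mapped, frame


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _plot_profile(profile, seg, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    c = profile.centers_deg
    ax.step(c, profile.density, where="mid", color="0.7", label="raw")
    ax.plot(c, profile.smoothed, color="C0", label="smoothed")
    for angle, name in (
        (seg.theta_min_angle, "density min"),
        (seg.theta_max_angle, "density max"),
        (seg.theta_mr_start, "GZ/MR"),
    ):
        ax.axvline(angle, ls="--", lw=0.8, color="C3")
        ax.text(angle, ax.get_ylim()[1] * 0.95, name, rotation=90, va="top", fontsize=7)
    ax.set_xlabel("theta (deg from anterior pole)")
    ax.set_ylabel("density (cells / 1000 um^2)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(
    outdir,
    stack_path=None,
    preset: str | None = None,
    config: SynthConfig | None = None,
    landmarks=None,
    seed: int = 0,
    render: bool = False,
    detection: DetectionParams | None = None,
    roi: ROISpec | None = None,
    bin_width: float = 5.0,
    smooth_window: int = 3,
    drop_fraction: float = 0.42,
    spacing_override_nm=None,
    make_plots: bool = True,
) -> dict:
    """Run detect -> map -> zones (-> roi) and write all outputs.

    Either ``stack_path`` (a real TIFF, requires ``landmarks``) or a
    synthetic ``preset``/``config`` must be given.  In synthetic mode
    the ground-truth point cloud is used directly unless ``render`` is
    true, in which case a stack is rendered and the detector runs on
    it; landmarks default to exact picks on the planted GZ/MR boundary.

    Returns a dict of output paths plus the in-memory results; writes
    ``manifest.json`` last so its presence marks a completed run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    manifest: dict = {
        "package": "lensmap3d",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "parameters": {
            "bin_width": bin_width,
            "smooth_window": smooth_window,
            "drop_fraction": drop_fraction,
            "render": render,
        },
        "inputs": {},
        "stages": {},
    }
    detection = detection or DetectionParams()
    manifest["parameters"]["detection"] = dataclasses.asdict(detection)
    if roi is not None:
        manifest["parameters"]["roi"] = dataclasses.asdict(roi)

    try:
        # ---- input stage -------------------------------------------------
        if stack_path is not None:
            stack_path = Path(stack_path)
            if landmarks is None:
                raise StageError("map: landmarks required for a real stack")
            grid = read_stack(stack_path, spacing_override_nm=spacing_override_nm)
            manifest["inputs"]["stack"] = {
                "path": str(stack_path),
                "sha256": _sha256(stack_path),
                "shape": list(grid.shape),
                "spacing_nm": list(grid.spacing_nm),
            }
            nuclei = detect_nuclei(grid, detection)
            truth = None
        elif preset is not None or config is not None:
            cfg = config if config is not None else preset_config(preset, seed=seed)
            if config is not None and seed:
                cfg = dataclasses.replace(cfg, seed=seed)
            manifest["parameters"]["synth"] = dataclasses.asdict(cfg)
            truth = sample_epithelium(cfg)
            write_points(truth.points, outdir / "truth.csv")
            manifest["stages"]["synth"] = {"n_cells": int(len(truth.points))}
            if landmarks is None:
                landmarks = boundary_landmarks(cfg)
            if render:
                grid, offset = render_stack(truth)
                write_stack(grid, outdir / "stack.tif")
                manifest["stages"]["render"] = {
                    "shape": list(grid.shape),
                    "offset_um": [float(v) for v in offset],
                }
                landmarks = np.asarray(landmarks, dtype=float) - offset
                nuclei = detect_nuclei(grid, detection)
            else:
                nuclei = truth.points.copy()
        else:
            raise StageError("input: provide stack_path or a synthetic preset/config")
        landmarks = np.asarray(landmarks, dtype=float).reshape(3, 3)
        write_points(nuclei, outdir / "nuclei.csv")
        manifest["stages"]["detect"] = {"n_nuclei": int(len(nuclei))}

        # ---- map stage ---------------------------------------------------
        try:
            mapped, frame = map_points(nuclei, landmarks)
        except ValueError as exc:
            raise StageError(f"map: {exc}") from exc
        manifest["stages"]["map"] = {
            "r_max": frame.r_max,
            "r_min": frame.r_min,
            "aspect_ratio": frame.aspect_ratio,
            "landmarks": landmarks.tolist(),
        }
        frame.to_json(outdir / "frame.json")

        # ---- zones stage -------------------------------------------------
        try:
            profile = theta_density_profile(
                mapped, frame, bin_width=bin_width, smooth_window=smooth_window
            )
            seg = zone_segmentation(profile, mapped, drop_fraction=drop_fraction)
            density = local_density_map(mapped, frame)
        except ValueError as exc:
            raise StageError(f"zones: {exc}") from exc
        mapped["zone"] = seg.zones
        write_points(mapped, outdir / "mapped.csv")
        profile.to_frame().to_csv(outdir / "profile.csv", index=False)
        seg.summary().to_csv(outdir / "zones.csv", index=False)
        density.to_csv(outdir / "local_density.csv", index=False)
        manifest["stages"]["zones"] = {
            "theta_min_angle": seg.theta_min_angle,
            "theta_max_angle": seg.theta_max_angle,
            "theta_mr_start": seg.theta_mr_start,
            "theta_edge": seg.theta_edge,
            "percent": seg.percent,
            "counts": seg.counts,
            "warnings": seg.warnings,
        }
        if make_plots:
            _plot_profile(profile, seg, outdir / "profile.png")

        # ---- roi stage (optional) ---------------------------------------
        roi_profile = None
        if roi is not None:
            try:
                roi_profile = roi_density(mapped, roi)
            except ValueError as exc:
                raise StageError(f"roi: {exc}") from exc
            roi_profile.table.to_csv(outdir / "roi.csv", index=False)
            manifest["stages"]["roi"] = {"D_um": roi_profile.D}
    except Exception:
        failed_marker.write_text("pipeline failed; partial outputs retained\n")
        raise

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "outdir": outdir,
        "manifest": manifest,
        "nuclei": nuclei,
        "mapped": mapped,
        "frame": frame,
        "profile": profile,
        "segmentation": seg,
        "local_density": density,
        "roi": roi_profile,
        "truth": truth,
    }
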