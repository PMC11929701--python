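"""End-to-end pipeline and the Monte-Carlo phantom study runner.

``run_case_pipeline`` chains the intraoperative steps on one synthetic case:
per-frame segmentation with the confidence and region-size filters, boundary
extraction, tracked-frame reconstruction, voxel downsampling, normal
estimation, bifurcation-feature extraction on both clouds, principal-axes
initialization, feature-point ICP, and target localization.

``run_phantom_study`` repeats this over seeded cases and reports per-case
registration residual (RMS-A), transform errors against the hidden ground
truth, and target localization error (TLE), mirroring the structure of a
physical phantom accuracy study (per-experiment rows, per-metric summary).
``run_registration_residual_study`` is the cloud-level residual experiment:
one surface sampling observed twice with independent surface jitter under a
hidden transform.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import phantom, reconstruct, register, segment, target_fuse
from .geometry import (RigidTransform, random_rigid_transform,
                       rotation_error_deg, translation_error_mm)
from .phantom import PhantomCase
from .reconstruct import VesselPointCloud

logger = logging.getLogger(__name__)

#: study conditions (also the documented defaults of the phantom generator)
DEFAULT_CONFIG = {
    "phantom": {
        "tree": {"depth": 3, "root_radius": 3.0, "root_length": 30.0,
                 "branch_angle_range": [20.0, 45.0]},
        "max_rotation_deg": 15.0,
        "max_translation_mm": 30.0,
        "deformation_amplitude": 1.0,
        "deformation_wavelength": 80.0,
        "noise_sigma": 0.2,
        "n_targets": 4,
        "max_target_distance": 30.0,
        "surface_density": 2.0,
        "n_frames": 60,
        "pixel_spacing": 0.2,
    },
    "segment": {"dark_cutoff": 0.5, "confidence_cutoff": 0.5,
                "min_px": 40, "max_px": 50000},
    "reconstruct": {"stride": 1, "voxel": 0.5, "normals_k": 30},
    "register": {"radius": 3.0, "score_threshold": 0.2, "max_points": 500,
                 "nms_radius": 1.0, "max_iter": 100, "tol": 1.0e-4,
                 "reject_multiplier": 3.0},
}

METRICS = ["rmsa_mm", "rotation_error_deg", "translation_error_mm", "tle_mm"]


def merge_config(overrides: Optional[dict]) -> dict:
    """Defaults overlaid with a (possibly partial) user config."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for section, values in (overrides or {}).items():
        if section not in cfg:
            raise ValueError(f"unknown config section '{section}'")
        if not isinstance(values, dict):
            raise ValueError(f"config section '{section}' must be a mapping")
        for key, value in values.items():
            if key not in cfg[section]:
                raise ValueError(f"unknown config key '{section}.{key}'")
            cfg[section][key] = value
    return cfg


@dataclass
class ExperimentReport:
    """Per-case records plus a per-metric summary recomputable from them."""

    cases: pd.DataFrame
    summary: dict
    histories: List[List[float]] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_files(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.cases.to_csv(out_dir / "report.csv", index=False,
                          float_format="%.17g")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=1)


def summarize(cases: pd.DataFrame) -> dict:
    ok = cases[cases["error"].isna()] if "error" in cases else cases
    summary = {"n_cases": int(len(cases)), "n_failed": int(len(cases) - len(ok))}
    for metric in METRICS:
        if metric in ok and len(ok):
            col = ok[metric].astype(float)
            summary[metric] = {"mean": float(col.mean()),
                               "min": float(col.min()),
                               "max": float(col.max())}
    return summary


def make_case(seed: int, cfg: dict) -> PhantomCase:
    p = cfg["phantom"]
    tree_cfg = dict(p["tree"])
    if "branch_angle_range" in tree_cfg:
        tree_cfg["branch_angle_range"] = tuple(tree_cfg["branch_angle_range"])
    return phantom.make_phantom_case(
        seed,
        tree_params=tree_cfg,
        transform_params={"max_rotation_deg": p["max_rotation_deg"],
                          "max_translation_mm": p["max_translation_mm"]},
        deformation_amplitude=p["deformation_amplitude"],
        deformation_wavelength=p["deformation_wavelength"],
        noise_sigma=p["noise_sigma"],
        n_targets=p["n_targets"],
        max_target_distance=p["max_target_distance"],
        surface_density=p["surface_density"],
        n_frames=p["n_frames"],
        pixel_spacing=p["pixel_spacing"])


def reconstruct_us_cloud(case: PhantomCase, cfg: dict) -> VesselPointCloud:
    """Segment every frame, keep mask boundaries, reconstruct, downsample,
    and estimate normals — the ultrasound-side registration operand."""
    s, r = cfg["segment"], cfg["reconstruct"]
    boundaries = []
    for frame in case.frames:
        mask = segment.segment_frame(frame, s["dark_cutoff"],
                                     s["confidence_cutoff"],
                                     s["min_px"], s["max_px"])
        boundaries.append(segment.mask_boundary(mask))
    cloud = reconstruct.reconstruct_cloud(case.frames, boundaries, r["stride"])
    cloud = reconstruct.voxel_downsample(cloud, r["voxel"])
    return reconstruct.estimate_normals(cloud, r["normals_k"])


def run_case_pipeline(case: PhantomCase, cfg: Optional[dict] = None) -> dict:
    """Full intraoperative chain on one case; returns metrics and the result."""
    cfg = cfg if cfg is not None else merge_config(None)
    us_cloud = reconstruct_us_cloud(case, cfg)
    reg_cfg = cfg["register"]
    result = register.register_clouds(case.ct_cloud, us_cloud, **reg_cfg)
    truth = case.ct_to_world
    tle = [target_fuse.target_localization_error(
        target_fuse.localize_target(result, ct_t), world_t)
        for ct_t, world_t in zip(case.targets_ct, case.targets_world)]
    return {
        "seed": case.seed,
        "rmsa_mm": result.rmsa,
        "rotation_error_deg": rotation_error_deg(result.transform, truth),
        "translation_error_mm": translation_error_mm(result.transform, truth),
        "tle_mm": float(np.mean(tle)),
        "tle_max_mm": float(np.max(tle)),
        "tle_per_target_mm": [float(t) for t in tle],
        "iterations": result.iterations,
        "converged": result.converged,
        "n_us_points": len(us_cloud),
        "result": result,
    }


def run_phantom_study(config: Optional[dict] = None,
                      n_cases: int = 24,
                      base_seed: int = 0,
                      out_dir=None) -> ExperimentReport:
    """Seeded Monte-Carlo phantom study (default 24 cases, 4 targets each).

    A failure in any stage is recorded in that case's row and does not abort
    the study.  With ``out_dir`` set, writes ``report.csv`` and
    ``summary.json``.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    cfg = merge_config(config)
    rows, histories = [], []
    for i in range(n_cases):
        seed = int(base_seed) + i
        row = {"case": i, "seed": seed, "error": None}
        try:
            case = make_case(seed, cfg)
            metrics = run_case_pipeline(case, cfg)
            result = metrics.pop("result")
            metrics.pop("tle_per_target_mm")
            row.update(metrics)
            histories.append(list(result.history))
            logger.info("study case=%d seed=%d rmsa=%.4f tle=%.4f iters=%d",
                        i, seed, row["rmsa_mm"], row["tle_mm"],
                        row["iterations"])
        except Exception as exc:   # per-case failures are data, not crashes
            row["error"] = f"{type(exc).__name__}: {exc}"
            histories.append([])
            logger.warning("study case=%d seed=%d failed: %s", i, seed,
                           row["error"])
        rows.append(row)
    columns = ["case", "seed", "rmsa_mm", "rotation_error_deg",
               "translation_error_mm", "tle_mm", "tle_max_mm", "iterations",
               "converged", "n_us_points", "error"]
    cases = pd.DataFrame(rows).reindex(columns=columns)
    report = ExperimentReport(cases, summarize(cases), histories, cfg)
    if out_dir is not None:
        report.to_files(out_dir)
    return report


def run_registration_residual_case(seed: int,
                                   jitter_sigma: float = 0.05,
                                   surface_density: float = 2.0,
                                   max_rotation_deg: float = 15.0,
                                   max_translation_mm: float = 30.0,
                                   tree_params: Optional[dict] = None,
                                   register_params: Optional[dict] = None) -> dict:
    """One cloud-level registration residual experiment.

    A depth-3 tree's surface is sampled once (~5,000 points at the default
    density); the sampling is observed twice with independent Gaussian
    surface jitter along the normals, one observation carried through a
    hidden rigid transform.  Feature-point ICP registers the two observations
    and the RMS-A over the final accepted feature pairs is returned together
    with the transform errors against the hidden truth.
    """
    rng = np.random.default_rng(seed)
    tree = phantom.make_vessel_tree(seed=int(rng.integers(2 ** 31)),
                                    **(tree_params or {}))
    base = phantom.sample_tree_surface(tree, surface_density,
                                       seed=int(rng.integers(2 ** 31)))
    hidden = random_rigid_transform(rng, max_rotation_deg, max_translation_mm)
    moving = phantom.jitter_along_normals(base, jitter_sigma, rng).transformed(hidden)
    fixed = phantom.jitter_along_normals(base, jitter_sigma, rng)
    result = register.register_clouds(moving, fixed,
                                      **(register_params or {}))
    return {
        "seed": seed,
        "rmsa_mm": result.rmsa,
        "rotation_error_deg": rotation_error_deg(result.transform,
                                                 hidden.inverse()),
        "translation_error_mm": translation_error_mm(result.transform,
                                                     hidden.inverse()),
        "iterations": result.iterations,
        "converged": result.converged,
        "n_points": len(base),
        "history": list(result.history),
    }


def run_registration_residual_study(n_cases: int = 20,
                                    base_seed: int = 1,
                                    **kwargs) -> pd.DataFrame:
    """Residual experiment over seeds ``base_seed .. base_seed + n_cases - 1``."""
    rows = [run_registration_residual_case(int(base_seed) + i, **kwargs)
            for i in range(n_cases)]
    for row in rows:
        row.pop("history")
    return pd.DataFrame(rows)
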