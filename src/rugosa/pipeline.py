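"""End-to-end orchestration: cloud -> traits -> biomass models.

Stage order mirrors the acquisition-to-analysis chain: outlier filtering and
height calibration, density regularization, vegetation classification, plot
clipping and row extraction, canopy roughness, and cross-validated
regression against measured biomass. A JSON run log records every parameter,
seed and per-stage count so a run can be reproduced from the log alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .cloud import ColoredPointCloud
from .preprocess import (HeightBar, adjust_height, plane_fit_outlier_removal,
                         statistical_outlier_removal)
from .regularize import (build_mesh, laplacian_smooth, poisson_disk_thin,
                         repair_holes, sample_surface)
from .segment import classify_vegetation
from .roughness import compute_plot_traits
from .regression import (FAMILIES, EvaluationSet, genotype_report, loocv,
                         reject_plot_outliers)

__all__ = ["PipelineConfig", "run_pipeline", "traits_to_frame"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the standard operating values."""

    cloud_path: str = ""
    plot_map_path: str = ""
    agb_path: str = ""                 # CSV: plot_id, agb_g_m2
    bars_path: str = ""                # optional CSV: bar_id, measured_z, cloud_z
    out_dir: str = "rugosa_run"

    filter_k: int = 20
    filter_n_sigma: float = 3.0
    mesh_max_edge: float = 0.25        # m; prunes wall/gap-bridging triangles
    max_hole_perimeter: float = 0.5    # m
    smooth_radius: float = 0.10        # m
    smooth_iterations: int = 1
    sample_density: float = 500.0      # points/m^2
    poisson_min_dist: float = 0.01     # m
    green_cutoff: int = 115
    classify_direction: str = "veg_ge_cutoff"
    grid_step: float = 0.15            # m
    min_cluster_size: int = 50
    connectivity: int = 26
    roughness_radius: float = 0.10     # m
    residual_limit: float = 2.0
    min_genotype_plots: int = 3
    outlier_family: str = "linear"
    families: tuple = tuple(FAMILIES)
    skip_regularize: bool = False
    write_stage_clouds: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.green_cutoff <= 255:
            raise ValueError("green_cutoff must be in [0, 255]")
        if self.classify_direction not in ("veg_ge_cutoff", "veg_lt_cutoff"):
            raise ValueError("bad classify_direction")
        for name in ("filter_n_sigma", "smooth_radius", "sample_density",
                     "poisson_min_dist", "grid_step", "roughness_radius",
                     "residual_limit", "max_hole_perimeter", "mesh_max_edge"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.filter_k < 1 or self.min_cluster_size < 1:
            raise ValueError("filter_k and min_cluster_size must be >= 1")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        bad = [f for f in self.families if f not in FAMILIES]
        if bad or self.outlier_family not in FAMILIES:
            raise ValueError(f"unknown model families: {bad or self.outlier_family}")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump({**asdict(self), "families": list(self.families)}, fh)
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "families" in doc:
            doc["families"] = tuple(doc["families"])
        cfg = cls(**doc)
        cfg.validate()
        return cfg


def traits_to_frame(traits) -> pd.DataFrame:
    return pd.DataFrame([{
        "plot_id": t.plot_id, "genotype": t.genotype, "n_points": t.n_points,
        "n_undefined": t.n_undefined, "med_m": t.med, "iqr_m": t.iqr,
        "cr_m2": t.cr, "agb_g_m2": t.agb,
    } for t in traits])


def _regularize(cloud: ColoredPointCloud, cfg: PipelineConfig
                ) -> tuple[ColoredPointCloud, dict]:
    mesh = build_mesh(cloud, max_edge=cfg.mesh_max_edge)
    mesh, hole_log = repair_holes(mesh, cfg.max_hole_perimeter)
    mesh = laplacian_smooth(mesh, radius=cfg.smooth_radius,
                            iterations=cfg.smooth_iterations)
    sampled = sample_surface(mesh, density=cfg.sample_density, seed=cfg.seed)
    thinned = poisson_disk_thin(sampled, min_dist=cfg.poisson_min_dist,
                                seed=cfg.seed + 1)
    log = {"mesh_area_m2": mesh.area, **hole_log,
           "n_sampled": len(sampled), "n_after_thinning": len(thinned)}
    return thinned, log


def run_pipeline(config: PipelineConfig,
                 cloud: ColoredPointCloud | None = None,
                 plot_map: rio.PlotMap | None = None,
                 agb: dict[str, float] | None = None):
    """Execute the full pipeline; returns (trait table, reports, genotype table).

    Inputs may be passed in memory or read from the paths in ``config``. All
    artifacts (trait CSV, model JSON, LOOCV CSV, genotype CSV, run log) are
    written under ``config.out_dir``. Identical config + inputs produce
    bit-identical outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": {**asdict(config), "families": list(config.families)},
                 "stages": {}}

    if cloud is None:
        cloud = rio.read_point_cloud(config.cloud_path)
    if plot_map is None:
        plot_map = rio.read_plot_map(config.plot_map_path)
    if agb is None and config.agb_path:
        df = pd.read_csv(config.agb_path, dtype={"plot_id": str})
        agb = dict(zip(df["plot_id"], df["agb_g_m2"].astype(float)))
    log["stages"]["input"] = {"n_points": len(cloud), "n_plots": len(plot_map)}

    # --- preprocess -------------------------------------------------------
    cloud, rep1 = statistical_outlier_removal(cloud, k=config.filter_k,
                                              n_sigma=config.filter_n_sigma)
    cloud, rep2 = plane_fit_outlier_removal(cloud, k=config.filter_k,
                                            n_sigma=config.filter_n_sigma)
    log["stages"]["preprocess"] = {"statistical": rep1.to_dict(),
                                   "plane_fit": rep2.to_dict()}
    if config.bars_path:
        bars_df = rio.read_height_bars(config.bars_path)
        bars = [HeightBar(r.bar_id, r.measured_z, r.cloud_z)
                for r in bars_df.itertuples()]
        cloud, offset, residuals = adjust_height(cloud, bars)
        log["stages"]["height_adjust"] = {
            "offset_m": offset, "max_abs_residual_m": float(np.abs(residuals).max())}

    # --- regularize -------------------------------------------------------
    if not config.skip_regularize:
        cloud, reg_log = _regularize(cloud, config)
        log["stages"]["regularize"] = reg_log
    if config.write_stage_clouds:
        rio.write_point_cloud(cloud, out / "regularized.ply")

    # --- segment ----------------------------------------------------------
    classified = classify_vegetation(cloud, green_cutoff=config.green_cutoff,
                                     direction=config.classify_direction)
    log["stages"]["classify"] = {"n_vegetation": classified.n_vegetation,
                                 "n_soil": classified.n_soil,
                                 "cutoff": classified.cutoff_used}
    if config.write_stage_clouds and classified.n_vegetation:
        rio.write_point_cloud(classified.vegetation, out / "vegetation.ply")

    # --- roughness --------------------------------------------------------
    traits, failures = compute_plot_traits(
        classified.vegetation, plot_map,
        radius=config.roughness_radius, grid_step=config.grid_step,
        min_cluster_size=config.min_cluster_size,
        connectivity=config.connectivity)
    if agb:
        for t in traits:
            t.agb = agb.get(t.plot_id)
    trait_frame = traits_to_frame(traits)
    trait_frame.to_csv(out / "plot_traits.csv", index=False)
    log["stages"]["roughness"] = {"n_plots_ok": len(traits),
                                  "failures": failures}

    # --- regression -------------------------------------------------------
    reports, genotype_table = {}, pd.DataFrame()
    with_agb = [t for t in traits if t.agb is not None]
    if len(with_agb) >= 5:
        data = EvaluationSet.from_traits(with_agb)
        kept, removed = reject_plot_outliers(data, config.outlier_family,
                                             limit=config.residual_limit)
        for family in config.families:
            try:
                rep = loocv(kept, family)
            except ValueError as exc:
                log["stages"].setdefault("regression_skipped", {})[family] = str(exc)
                continue
            rep.outliers_removed = removed
            reports[family] = rep
        if reports:
            best = max(reports, key=lambda f: (np.nan_to_num(reports[f].r2), f))
            log["stages"]["regression"] = {
                "n_plots_fit": len(kept), "outliers_removed": removed,
                "best_family": best,
                "families": {f: r.to_dict() for f, r in reports.items()}}
            with open(out / "model_report.json", "w") as fh:
                json.dump(log["stages"]["regression"], fh, indent=2, sort_keys=True)
            best_rep = reports[best]
            pd.DataFrame({
                "plot_id": best_rep.plot_ids,
                "y_obs_g_m2": best_rep.y_obs,
                "loocv_pred_g_m2": best_rep.loocv_predictions,
            }).to_csv(out / "loocv_predictions.csv", index=False)
            genotype_table = genotype_report(best_rep, kept,
                                             min_plots=config.min_genotype_plots)
            genotype_table.to_csv(out / "genotype_table.csv", index=False)
    else:
        log["stages"]["regression"] = {
            "skipped": f"only {len(with_agb)} plots with AGB (need >= 5)"}

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    return trait_frame, reports, genotype_table
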