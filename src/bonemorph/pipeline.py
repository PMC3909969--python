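"""Two-time-point growth-assessment pipeline.

Orchestrates the full workflow on a baseline/follow-up scan pair:
segmentation, fiducial detection, surface meshing, two superimposition
routes — (A) implant-based rigid superimposition with stability
diagnostics, and (B) affine + nonrigid intensity registration with mesh
warping and Procrustes alignment — and the quantitative outputs: signed
remodelling fields, Hausdorff / mean-minimum accuracy metrics,
inter-implant distance changes, and volume change.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field as dfield

import numpy as np
import yaml

from . import grid as gridmod
from .grid import BinaryMask, ImageGrid, read_volume
from .mesh import extract_surface, mesh_volume, transform_mesh
from .morpho import (export_colormap, mean_min_report, procrustes_align,
                     signed_distances, volume_change)
from .phantom import GrowthParams, PhantomScenario, apply_growth, make_phantom
from .register import (AffineConfig, DemonsConfig, FiducialFitReport,
                       leave_one_out_stability, match_fiducials, fit_rigid,
                       register_affine, register_nonrigid, warp_mesh)
from .segment import (FiducialSet, default_metal_threshold, detect_fiducials,
                      mask_out_fiducials, pairwise_distances, threshold_bone)
from .transforms import RigidTransform

logger = logging.getLogger("bonemorph")

__all__ = ["PipelineConfig", "GrowthReport", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class SegmentationConfig:
    method: str = "otsu"
    fixed_low: float | None = None
    min_component_mm3: float = 1.0
    keep_largest: bool = True


@dataclass
class DetectionConfig:
    metal_threshold: float | None = None  # default: midpoint bone-mean/max
    diameter_mm: float = 1.0
    diameter_tol: float = 0.6
    min_sphericity: float = 0.6
    expected_count: int | None = None
    exclusion_radius_mm: float = 1.0


@dataclass
class RegistrationConfig:
    flag_threshold_mm: float = 1.0
    affine: AffineConfig = dfield(default_factory=AffineConfig)
    demons: DemonsConfig = dfield(default_factory=DemonsConfig)
    procrustes_scaling: bool = True


@dataclass
class DistanceConfig:
    near_zero_band_mm: float = 0.2
    area_weighted: bool = False


@dataclass
class PipelineConfig:
    """Pipeline inputs and parameters; every field has a documented default.

    Unknown keys in a YAML config are rejected.
    """

    baseline: str | None = None
    followup: str | None = None
    baseline_mask: str | None = None
    followup_mask: str | None = None
    baseline_fiducials: str | None = None
    followup_fiducials: str | None = None
    outdir: str = "bonemorph_out"
    seed: int = 0
    smooth_sigma_mm: float | None = None  # mask pre-smoothing (default 0.5 voxel)
    run_intensity_route: bool = True
    segmentation: SegmentationConfig = dfield(default_factory=SegmentationConfig)
    detection: DetectionConfig = dfield(default_factory=DetectionConfig)
    registration: RegistrationConfig = dfield(default_factory=RegistrationConfig)
    distance: DistanceConfig = dfield(default_factory=DistanceConfig)
    phantom: dict = dfield(default_factory=dict)  # simulate-subcommand block

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        return _build_dataclass(cls, raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping: {path}")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_dataclass(cls, raw: dict):
    if not isinstance(raw, dict):
        raise ConfigError(f"expected mapping for {cls.__name__}, got {raw!r}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in raw.items():
        ftype = fields[name].type
        default = fields[name].default_factory() \
            if fields[name].default_factory is not dataclasses.MISSING else None
        if dataclasses.is_dataclass(default):
            kwargs[name] = _build_dataclass(type(default), value or {})
        else:
            kwargs[name] = value
    return cls(**kwargs)


@dataclass
class GrowthReport:
    """Aggregated quantitative outcome of a two-time-point analysis."""

    fiducial_fit: dict | None
    implant_route: dict | None
    intensity_route: dict | None
    volumes: dict
    distance_table: list
    artefacts: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save_json(self, path) -> str:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
        return str(path)


def _load_or_segment(path, mask_path, cfg: PipelineConfig, tag: str):
    if path is None:
        raise FileNotFoundError(f"no {tag} input volume configured")
    grid = read_volume(path)
    if mask_path is not None:
        m = read_volume(mask_path)
        mask = BinaryMask(m.data > 0, m.spacing, m.origin, m.direction)
    else:
        s = cfg.segmentation
        mask = threshold_bone(grid, s.method, s.fixed_low,
                              s.min_component_mm3, s.keep_largest)
    return grid, mask


def _load_or_detect(grid, mask, fid_path, cfg: DetectionConfig):
    if fid_path is not None:
        return FiducialSet.load_csv(fid_path)
    thr = cfg.metal_threshold
    if thr is None:
        thr = default_metal_threshold(grid, mask)
    return detect_fiducials(grid, thr, cfg.diameter_mm, cfg.diameter_tol,
                            cfg.min_sphericity, cfg.expected_count)


def run_pipeline(config: PipelineConfig) -> GrowthReport:
    """Run segmentation, registration and measurement on a scan pair.

    Route A (implant-based) needs at least three matched fiducials in both
    scans; if unavailable it is skipped with a warning and only the
    intensity route is reported.  Deterministic given config and seed.
    """
    t_start = time.time()
    os.makedirs(config.outdir, exist_ok=True)
    art = {}

    grid_a, mask_a = _load_or_segment(config.baseline, config.baseline_mask,
                                      config, "baseline")
    grid_b, mask_b = _load_or_segment(config.followup, config.followup_mask,
                                      config, "followup")
    logger.info("segmented baseline (%d voxels) and follow-up (%d voxels)",
                int(mask_a.data.sum()), int(mask_b.data.sum()))

    fids_a = _load_or_detect(grid_a, mask_a, config.baseline_fiducials,
                             config.detection)
    fids_b = _load_or_detect(grid_b, mask_b, config.followup_fiducials,
                             config.detection)
    logger.info("detected %d / %d fiducials", len(fids_a), len(fids_b))
    art["fiducials_baseline"] = fids_a.save_csv(
        os.path.join(config.outdir, "fiducials_baseline.csv"))
    art["fiducials_followup"] = fids_b.save_csv(
        os.path.join(config.outdir, "fiducials_followup.csv"))

    excl = config.detection.exclusion_radius_mm
    mesh_a = extract_surface(mask_out_fiducials(mask_a, fids_a, excl),
                             smooth_sigma_mm=config.smooth_sigma_mm)
    mesh_b = extract_surface(mask_out_fiducials(mask_b, fids_b, excl),
                             smooth_sigma_mm=config.smooth_sigma_mm)
    vol_a, vol_b = mesh_volume(mesh_a), mesh_volume(mesh_b)
    delta, percent = volume_change(vol_a, vol_b)
    volumes = {"baseline_cm3": vol_a, "followup_cm3": vol_b,
               "delta_cm3": delta, "percent": percent}
    logger.info("volumes: %.3f -> %.3f cm^3 (%+.1f%%)", vol_a, vol_b, percent)

    fiducial_fit = None
    implant_route = None
    distance_rows = []
    can_rigid = len(fids_a) >= 3 and len(fids_a) == len(fids_b)
    if can_rigid:
        perm = match_fiducials(fids_a, fids_b)
        fids_b_m = FiducialSet([fids_b.markers[i] for i in perm])
        stability = leave_one_out_stability(
            fids_a, fids_b_m, config.registration.flag_threshold_mm,
            correspondence=list(range(len(fids_a))))
        stability.correspondence = perm
        flagged = {l for l, _ in stability.flags}
        keep = [i for i, l in enumerate(fids_a.labels) if l not in flagged]
        if len(keep) >= 3:
            transform, fit = fit_rigid(fids_a.positions[keep],
                                       fids_b_m.positions[keep],
                                       labels=[fids_a.labels[i] for i in keep])
        else:
            transform, fit = fit_rigid(fids_a.positions, fids_b_m.positions,
                                       labels=fids_a.labels)
        fiducial_fit = {"fit": fit.to_dict(), "stability": stability.to_dict(),
                        "markers_used": [fids_a.labels[i] for i in keep]
                        if len(keep) >= 3 else fids_a.labels}
        art["rigid_transform"] = transform.save(
            os.path.join(config.outdir, "implant_rigid.txt"))

        warped_a = transform_mesh(mesh_a, transform)
        rep = mean_min_report(warped_a, mesh_b,
                              config.distance.area_weighted)
        art["implant_colormap"] = export_colormap(
            rep.per_vertex_field,
            os.path.join(config.outdir, "remodelling_implant.vtk"),
            config.distance.near_zero_band_mm)
        implant_route = rep.to_dict()
        logger.info("implant route: max mean-min %.3f mm, Hausdorff %.3f mm",
                    rep.max_mean_min, rep.hausdorff)

        # matched labels across time points for the change table
        fids_b_named = FiducialSet([
            dataclasses.replace(m, label=l)
            for l, m in zip(fids_a.labels, fids_b_m.markers)])
        table = pairwise_distances(fids_a, fids_b_named)
        art["distance_table"] = table.save_csv(
            os.path.join(config.outdir, "implant_distances.csv"))
        distance_rows = table.table.to_dict(orient="records")
    else:
        logger.warning("implant route unavailable "
                       "(%d vs %d fiducials); falling back to intensity route",
                       len(fids_a), len(fids_b))

    intensity_route = None
    if config.run_intensity_route:
        affine = register_affine(grid_b, grid_a, config.registration.affine)
        field = register_nonrigid(grid_b, grid_a, affine,
                                  config.registration.demons)
        warped_a = warp_mesh(mesh_a, field, "inverse")
        pro, aligned = procrustes_align(
            mesh_a.vertices, warped_a.vertices,
            with_scaling=config.registration.procrustes_scaling)
        aligned_mesh = transform_mesh(
            mesh_a, _procrustes_affine(pro))
        rep = mean_min_report(aligned_mesh, mesh_b,
                              config.distance.area_weighted)
        art["intensity_colormap"] = export_colormap(
            rep.per_vertex_field,
            os.path.join(config.outdir, "remodelling_intensity.vtk"),
            config.distance.near_zero_band_mm)
        intensity_route = {"procrustes": pro.to_dict(), **rep.to_dict()}
        logger.info("intensity route: max mean-min %.3f mm (scale %.4f)",
                    rep.max_mean_min, pro.scale)

    report = GrowthReport(fiducial_fit, implant_route, intensity_route,
                          volumes, distance_rows, art)
    art["report"] = report.save_json(os.path.join(config.outdir,
                                                  "growth_report.json"))
    logger.info("pipeline finished in %.1f s", time.time() - t_start)
    return report


def _procrustes_affine(pro):
    from .transforms import AffineTransform

    return AffineTransform(pro.scale * pro.rotation, pro.translation)


# ---------------------------------------------------------------------------

def simulate_pair(config: PipelineConfig, outdir: str | None = None):
    """Generate a phantom baseline/follow-up pair on disk and return the
    updated config pointing at the generated files."""
    outdir = outdir or config.outdir
    os.makedirs(outdir, exist_ok=True)
    p = dict(config.phantom)
    seed = int(p.pop("seed", config.seed))
    rot = tuple(p.pop("pose_rotation_deg", (3.0, -2.0, 4.0)))
    trans = tuple(p.pop("pose_translation_mm", (1.0, -0.8, 1.5)))
    growth = GrowthParams(**p.pop("growth", {}))
    displaced = p.pop("displace_marker", None)
    if displaced is not None:
        displaced = (displaced["label"], np.asarray(displaced["offset_mm"]))
    scenario = PhantomScenario(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in p.items()})
    center = (np.array(scenario.shape) - 1) * scenario.spacing / 2.0
    pose = RigidTransform.from_euler(rot, trans, center=center)
    grid_a, truth_a = make_phantom(scenario, seed=seed)
    grid_b, truth_b = apply_growth(truth_a, growth, pose, displaced,
                                   seed=seed + 1)
    paths = {}
    paths["baseline"] = gridmod.write_volume(
        grid_a, os.path.join(outdir, "baseline.nii.gz"))
    paths["followup"] = gridmod.write_volume(
        grid_b, os.path.join(outdir, "followup.nii.gz"))
    truth_a.fiducial_truth.save_csv(
        os.path.join(outdir, "truth_fiducials_baseline.csv"))
    truth_b.fiducial_truth.save_csv(
        os.path.join(outdir, "truth_fiducials_followup.csv"))
    truth_b.pose_change.save(os.path.join(outdir, "truth_pose.txt"))
    cfg = dataclasses.replace(config, baseline=paths["baseline"],
                              followup=paths["followup"], outdir=outdir)
    return cfg, (truth_a, truth_b)
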