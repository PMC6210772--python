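"""End-to-end experiment orchestration.

One config drives the whole chain: synthesize a stand → (optionally)
simulate, filter and register TLS scans → classify → voxelize → derive the
four canopy configurations (LR reference, L5/L10 thinned, LRT
translated) → build scenes → render reflectance → vegetation-index report.

Stage seeds are derived deterministically from one master seed via
``numpy.random.SeedSequence([master_seed, stage_index])`` with a fixed
stage table, so re-running an identical config is bit-identical and
changing the master seed re-randomizes every stage coherently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .classify import classify_points, remove_ground
from .filtering import FilterParameters, apply_filter, filter_ghost_points
from .indices import VIReport
from .registration import fit_sphere, register_scans
from .render import IlluminationModel, SensorConfig, canopy_openness, render_reflectance
from .scan import ScanSetup, simulate_scan
from .scene import CanopyScene, build_scene, clone_scene, cylinder_tube_mesh
from .spectra import Spectrum, generate_material_spectra
from .stand import CLASS_LEAF, CLASS_TRUNK, Stand, StandParameters, generate_stand
from .voxel import VoxelGrid, lad_profile, reduce_lai, translate_lad, voxelize

log = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "stage_seed"]

_STAGES = {
    "stand": 0,
    "scan_ghosts": 1,
    "leaf_azimuth": 2,
    "reduce": 3,
    "translate": 4,
    "render": 5,
    "openness": 6,
}

#: structural-analysis bands: the wavelengths the six indices read
INDEX_BAND_SET = (550.0, 670.0, 695.0, 710.0, 750.0, 760.0, 800.0, 850.0, 1650.0)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 (documented derivation)."""
    ss = np.random.SeedSequence([int(master_seed), _STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class ConfigurationSpec:
    """One canopy structure configuration derived from the reference."""

    reduce_fraction: float = 0.0
    translate_fraction: float = 0.0
    split_height: float = 17.0
    floor_height: float = 1.3

    def validate(self) -> None:
        if not (0.0 <= self.reduce_fraction < 1.0):
            raise ValueError(f"reduce_fraction {self.reduce_fraction} outside [0, 1)")
        if not (0.0 <= self.translate_fraction <= 1.0):
            raise ValueError("translate_fraction outside [0, 1]")
        if self.split_height <= self.floor_height:
            raise ValueError("split_height must exceed floor_height")


def _default_configurations() -> dict[str, ConfigurationSpec]:
    return {
        "LR": ConfigurationSpec(),
        "L5": ConfigurationSpec(reduce_fraction=0.05),
        "L10": ConfigurationSpec(reduce_fraction=0.10),
        "LRT": ConfigurationSpec(translate_fraction=0.5),
    }


@dataclass
class ExperimentConfig:
    """Full experiment description; defaults encode the emulated stand and
    acquisition conditions.

    The reference voxel canopy is built from ground truth by default
    (``canopy_source='ground_truth'``); ``'tls'`` runs the scan → filter →
    register → classify chain instead.
    """

    master_seed: int = 1
    stand: StandParameters = field(default_factory=StandParameters)
    canopy_source: str = "ground_truth"
    scan: ScanSetup | None = None
    filter: FilterParameters = field(default_factory=FilterParameters)
    classification_cell: float = 0.25
    classification_connectivity: int = 26
    ground_height: float = 0.2
    voxel_side: float = 0.02
    layer_dz: float = 1.0
    leaf_zenith_deg: float = 42.5
    configurations: dict[str, ConfigurationSpec] = field(default_factory=_default_configurations)
    reference: str = "LR"
    clone_grid_n: int = 5
    sun_zenith_deg: float = 30.0
    sun_azimuth_deg: float = 180.0
    diffuse_scale: float = 1.0
    soil_scale: float = 1.0
    bands: tuple = INDEX_BAND_SET
    samples_per_band: int = 256
    band_samples: dict = field(default_factory=dict)
    footprint_size: float = 21.0
    tvi_variant: str = "printed"
    openness_rays: int = 20000

    def validate(self) -> None:
        if self.canopy_source not in ("ground_truth", "tls"):
            raise ValueError("canopy_source must be 'ground_truth' or 'tls'")
        if len(set(self.configurations)) != len(self.configurations):
            raise ValueError("configuration names must be unique")
        if self.reference not in self.configurations:
            raise ValueError(f"reference {self.reference!r} not among configurations")
        for spec in self.configurations.values():
            spec.validate()
        if self.footprint_size > self.stand.plot_size:
            raise ValueError("sensor footprint exceeds the core tile")
        if self.samples_per_band < 1:
            raise ValueError("samples_per_band must be >= 1")

    # --- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.scan is not None:
            d["scan"]["scanner_positions"] = [list(map(float, p)) for p in self.scan.scanner_positions]
            d["scan"]["sphere_targets"] = [
                [list(map(float, c)), float(r)] for c, r in self.scan.sphere_targets
            ]
        d["bands"] = list(self.bands)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "stand" in d:
            stand = d["stand"]
            if "lad_peak_height_range" in stand:
                stand["lad_peak_height_range"] = tuple(stand["lad_peak_height_range"])
            d["stand"] = StandParameters(**stand)
        if d.get("scan"):
            scan = dict(d["scan"])
            scan["scanner_positions"] = [np.array(p) for p in scan.get("scanner_positions", [])]
            scan["sphere_targets"] = [
                (np.array(c), float(r)) for c, r in scan.get("sphere_targets", [])
            ]
            for key in ("azimuth_window", "elevation_window"):
                if key in scan:
                    scan[key] = tuple(scan[key])
            d["scan"] = ScanSetup(**scan)
        if "filter" in d and isinstance(d["filter"], dict):
            d["filter"] = FilterParameters(**d["filter"])
        if "configurations" in d:
            d["configurations"] = {
                name: spec if isinstance(spec, ConfigurationSpec) else ConfigurationSpec(**spec)
                for name, spec in d["configurations"].items()
            }
        if "bands" in d:
            d["bands"] = tuple(float(b) for b in d["bands"])
        if "band_samples" in d:
            d["band_samples"] = {float(k): int(v) for k, v in d["band_samples"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ExperimentResult:
    stand: Stand
    grids: dict[str, VoxelGrid]
    lad: dict
    reflectance: dict[str, Spectrum]
    reflectance_se: dict[str, Spectrum]
    report: VIReport
    openness: tuple[float, float]
    provenance: dict


def _materials(config: ExperimentConfig) -> dict[str, Spectrum]:
    soil = generate_material_spectra("soil")
    soil = Spectrum(soil.wavelengths, soil.values * config.soil_scale, kind=soil.kind)
    return {
        "leaf_reflectance": generate_material_spectra("leaf_reflectance"),
        "leaf_transmittance": generate_material_spectra("leaf_transmittance"),
        "trunk_reflectance": generate_material_spectra("trunk"),
        "soil_reflectance": soil,
    }


def _reference_grid_ground_truth(config: ExperimentConfig, stand: Stand) -> VoxelGrid:
    from .stand import stand_point_cloud

    points, classes = stand_point_cloud(stand)
    labels = np.where(classes == CLASS_TRUNK, 1, 0)
    return voxelize(
        points, labels, side=config.voxel_side, origin=np.zeros(3),
        ground_area=config.stand.plot_size**2,
    )


def _reference_grid_tls(config: ExperimentConfig, stand: Stand) -> VoxelGrid:
    """Scan → filter → register-back → classify → voxelize chain."""
    setup = config.scan or ScanSetup()
    grids = simulate_scan(
        stand, setup,
        leaf_seed=stage_seed(config.master_seed, "leaf_azimuth"),
        ghost_seed=stage_seed(config.master_seed, "scan_ghosts"),
    )
    rng = np.random.default_rng(stage_seed(config.master_seed, "scan_ghosts") + 1)
    merged_pts = []
    for grid in grids:
        keep = filter_ghost_points(grid, config.filter)
        filtered = apply_filter(grid, keep)
        # express the scan in a local frame and recover the pose from the
        # fitted sphere targets, as a field campaign would
        yaw = float(rng.uniform(0.0, 360.0))
        local = filtered.transformed(yaw, np.zeros(3))
        pts, labels = local.to_points()
        if len(setup.sphere_targets) >= 3 and filtered.labels is not None:
            src_centers = _sphere_centers(local)
            dst_centers = np.array([c for c, _ in setup.sphere_targets])
            if len(src_centers) >= 3:
                tf = register_scans(src_centers, dst_centers, correspondence="search")
                pts = tf.apply(pts)
            else:
                pts, labels = filtered.to_points()
        else:
            pts, labels = filtered.to_points()
        merged_pts.append(pts[labels != -1])
    points = np.concatenate(merged_pts)
    above = remove_ground(points, config.ground_height)
    veg = points[above]
    labels, _, _ = classify_points(
        veg, config.classification_cell, config.classification_connectivity
    )
    return voxelize(
        veg, labels, side=config.voxel_side, origin=np.zeros(3),
        ground_area=config.stand.plot_size**2,
    )


def _sphere_centers(grid) -> np.ndarray:
    """Fit sphere centers from labeled sphere returns of one scan."""
    from .classify import build_components
    from .stand import CLASS_SPHERE

    pts, labels = grid.to_points()
    sp = pts[labels == CLASS_SPHERE]
    if len(sp) < 4:
        return np.empty((0, 3))
    comps = build_components(sp, min_cell_size=0.1)
    centers = []
    for comp in comps:
        if len(comp.point_indices) >= 10:
            try:
                c, _, _ = fit_sphere(sp[comp.point_indices])
                centers.append(c)
            except ValueError:
                continue
    return np.array(centers) if centers else np.empty((0, 3))


def _derive_grid(name: str, spec: ConfigurationSpec, ref: VoxelGrid,
                 config: ExperimentConfig) -> VoxelGrid:
    grid = ref
    if spec.reduce_fraction > 0:
        grid = reduce_lai(
            grid, spec.reduce_fraction,
            seed=stage_seed(config.master_seed, "reduce"),
            layer_dz=config.layer_dz,
        )
    if spec.translate_fraction > 0:
        grid = translate_lad(
            grid, spec.translate_fraction, spec.split_height, spec.floor_height,
            seed=stage_seed(config.master_seed, "translate"),
            layer_dz=config.layer_dz,
        )
    return grid


def _scene_for(config: ExperimentConfig, stand: Stand, grid: VoxelGrid,
               materials: dict[str, Spectrum]) -> CanopyScene:
    trunks = [
        cylinder_tube_mesh((t.x, t.y), t.trunk_radius, 0.0, t.crown_base)
        for t in stand.trees
    ]
    core = build_scene(
        grid.leaf_centers(), trunks, config.stand.plot_size, materials,
        zenith_deg=config.leaf_zenith_deg,
        quantum=config.stand.leaf_quantum,
        seed=stage_seed(config.master_seed, "leaf_azimuth"),
    )
    return clone_scene(core, config.clone_grid_n)


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentResult:
    """Run the full experiment; optionally serialize every intermediate.

    Deterministic under a fixed config (master seed included); any stage
    failure aborts with the stage name in the exception message.
    """
    config.validate()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    stand = _stage(
        "stand", generate_stand,
        replace(config.stand, rng_seed=stage_seed(config.master_seed, "stand")),
    )
    log.info("stand: %d trees, %d leaves, LAI %.3f", len(stand.trees),
             len(stand.leaf_positions), stand.lai)
    if config.canopy_source == "tls":
        ref_grid = _stage("tls_chain", _reference_grid_tls, config, stand)
    else:
        ref_grid = _stage("voxelize", _reference_grid_ground_truth, config, stand)

    grids: dict[str, VoxelGrid] = {}
    lads = {}
    for name, spec in config.configurations.items():
        grids[name] = _stage(f"derive:{name}", _derive_grid, name, spec, ref_grid, config)
        lads[name] = lad_profile(grids[name], config.layer_dz, config.stand.leaf_quantum)
        log.info("configuration %s: %d leaf voxels, LAI %.3f",
                 name, grids[name].n_leaf, lads[name].lai)

    materials = _materials(config)
    illum = IlluminationModel(
        sun_zenith_deg=config.sun_zenith_deg,
        sun_azimuth_deg=config.sun_azimuth_deg,
    )
    if config.diffuse_scale != 1.0:
        illum.diffuse = Spectrum(
            illum.diffuse.wavelengths, illum.diffuse.values * config.diffuse_scale,
            kind=illum.diffuse.kind,
        )
    sensor = SensorConfig(
        footprint_size=config.footprint_size,
        bands=np.array(config.bands, dtype=float),
        samples_per_band=config.samples_per_band,
        band_samples=dict(config.band_samples),
        seed=stage_seed(config.master_seed, "render"),
    )
    reflectance: dict[str, Spectrum] = {}
    reflectance_se: dict[str, Spectrum] = {}
    openness = (np.nan, np.nan)
    for name in config.configurations:
        scene = _stage(f"scene:{name}", _scene_for, config, stand, grids[name], materials)
        refl, se = _stage(f"render:{name}", render_reflectance, scene, illum, sensor)
        reflectance[name] = refl
        reflectance_se[name] = se
        if name == config.reference:
            openness = _stage(
                "openness", canopy_openness, scene,
                n_rays=config.openness_rays,
                seed=stage_seed(config.master_seed, "openness"),
            )
        del scene

    report = VIReport.from_spectra(reflectance, config.reference, config.tvi_variant)

    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    provenance = {
        "package": "voxcanopy",
        "master_seed": config.master_seed,
        "stage_seeds": {k: stage_seed(config.master_seed, k) for k in _STAGES},
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "versions": _versions(),
        "stand": {"n_trees": len(stand.trees), "n_leaves": len(stand.leaf_positions),
                  "lai": stand.lai},
        "openness": {"value": openness[0], "stderr": openness[1]},
    }
    result = ExperimentResult(
        stand, grids, lads, reflectance, reflectance_se, report, openness, provenance
    )
    if out is not None:
        _serialize(result, config, out, cfg_yaml)
    return result


def _versions() -> dict:
    import numba
    import scipy

    return {"numpy": np.__version__, "scipy": scipy.__version__, "numba": numba.__version__}


def _serialize(result: ExperimentResult, config: ExperimentConfig, out: Path,
               cfg_yaml: str) -> None:
    import pandas as pd

    from .io import write_ply_points

    (out / "config.yaml").write_text(cfg_yaml)
    write_ply_points(
        out / "stand_leaves.ply", result.stand.leaf_positions,
        np.full(len(result.stand.leaf_positions), CLASS_LEAF),
    )
    for name, grid in result.grids.items():
        grid.save(out / f"voxels_{name}.npz")
        result.lad[name].to_csv(out / f"lad_{name}.csv")
        pd.DataFrame(
            {
                "wavelength_nm": result.reflectance[name].wavelengths,
                "reflectance": result.reflectance[name].values,
                "stderr": result.reflectance_se[name].values,
            }
        ).to_csv(out / f"reflectance_{name}.csv", index=False)
    result.report.to_csv(out / "vi_report.csv")
    result.report.to_json(out / "vi_report.json")
    with open(out / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, sort_keys=True)
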