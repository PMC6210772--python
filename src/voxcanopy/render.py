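"""Spectral Monte Carlo rendering of top-of-canopy reflectance.

The integrator is a forward path tracer started at a nadir orthographic
sensor: at every surface interaction the direct sun is sampled by
next-event estimation (binary visibility — diffuse leaf transmission does
not propagate the collimated beam), while the isotropic diffuse sky is
collected when a path escapes the scene.  Scattering events are sampled by
single-scattering albedo with cosine-weighted directions, so path
throughput stays at unity until absorption; Russian roulette bounds path
length without truncation bias.  Leaves are bi-Lambertian (same ρ/τ on
both faces), trunks and soil Lambertian.

The retrieved quantity per band is the hemispherical-directional
reflectance factor π·L_nadir / E_horizontal, with its Monte Carlo standard
error.  Bands are rendered independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tracing
from .scene import CanopyScene
from .spectra import Spectrum, generate_material_spectra
from .stand import CLASS_LEAF

__all__ = [
    "IlluminationModel",
    "SensorConfig",
    "render_reflectance",
    "canopy_openness",
    "intersect",
    "default_bands",
]


def default_bands() -> np.ndarray:
    """Sensor band grid: 400-2500 nm at 10 nm."""
    return 400.0 + 10.0 * np.arange(211)


@dataclass
class IlluminationModel:
    """Directional sun plus isotropic diffuse sky.

    ``direct`` is spectral irradiance on a plane perpendicular to the sun
    (W m⁻² nm⁻¹); ``diffuse`` is sky radiance (W m⁻² sr⁻¹ nm⁻¹), assumed
    isotropic over the upper hemisphere.  Defined on 350-2500 nm; the
    sensor may sense a subset.
    """

    sun_zenith_deg: float = 30.0
    sun_azimuth_deg: float = 180.0
    direct: Spectrum = field(default_factory=lambda: generate_material_spectra("sun_direct"))
    diffuse: Spectrum = field(default_factory=lambda: generate_material_spectra("sky_diffuse"))

    def __post_init__(self) -> None:
        if np.any(self.direct.values < 0) or np.any(self.diffuse.values < 0):
            raise ValueError("irradiance/radiance values must be >= 0")

    @property
    def sun_direction(self) -> np.ndarray:
        """Unit vector pointing from the surface toward the sun."""
        tz = np.deg2rad(self.sun_zenith_deg)
        az = np.deg2rad(self.sun_azimuth_deg)
        return np.array([np.sin(tz) * np.cos(az), np.sin(tz) * np.sin(az), np.cos(tz)])

    def horizontal_irradiance(self, lam: float) -> float:
        """Total downwelling irradiance on a horizontal plane at band λ."""
        e_dir = self.direct.value_at(lam) * np.cos(np.deg2rad(self.sun_zenith_deg))
        e_dif = np.pi * self.diffuse.value_at(lam)
        return float(e_dir + e_dif)


@dataclass
class SensorConfig:
    """Nadir orthographic sensor over a square footprint.

    ``band_samples`` overrides the per-band Monte Carlo budget for selected
    wavelengths, e.g. ``{670: 120000, 800: 120000}`` to concentrate effort
    on the bands a target index reads.
    """

    footprint_center: tuple[float, float] | None = None  # default: core tile center
    footprint_size: float = 21.0
    bands: np.ndarray = field(default_factory=default_bands)
    samples_per_band: int = 256
    band_samples: dict = field(default_factory=dict)
    seed: int = 0
    max_depth: int = 48
    rr_depth: int = 8
    rr_prob: float = 0.8

    def samples_for(self, lam: float) -> int:
        return int(self.band_samples.get(lam, self.samples_per_band))


class SceneTracer:
    """BVH-backed intersection context for a scene (built lazily, cached)."""

    def __init__(self, scene: CanopyScene):
        tris, mats = scene.core_triangles()
        self.bvh = tracing.build_bvh(tris)
        self.mats_sorted = mats[self.bvh.order] if len(mats) else mats
        self.offsets = np.ascontiguousarray(scene.clone_offsets, dtype=float)
        if len(tris):
            self.z_top = float(tris[..., 2].max())
        else:
            self.z_top = 0.0

    def args(self):
        return self.bvh.args()


def _tracer(scene: CanopyScene) -> SceneTracer:
    cached = getattr(scene, "_tracer_cache", None)
    if cached is None:
        cached = SceneTracer(scene)
        object.__setattr__(scene, "_tracer_cache", cached)
    return cached


def _material_tables(scene: CanopyScene, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """(rho, tau) indexed by material class id, at band λ."""
    m = scene.materials
    rho = np.zeros(8)
    tau = np.zeros(8)
    rho[0] = m["leaf_reflectance"].value_at(lam)
    tau[0] = m["leaf_transmittance"].value_at(lam)
    rho[1] = m["trunk_reflectance"].value_at(lam)
    rho[2] = m["soil_reflectance"].value_at(lam)
    if "sphere_reflectance" in m:
        rho[3] = m["sphere_reflectance"].value_at(lam)
    return rho, tau


def render_reflectance(
    scene: CanopyScene,
    illum: IlluminationModel,
    sensor: SensorConfig,
) -> tuple[Spectrum, Spectrum]:
    """Render per-band HDRF over the sensor footprint.

    Returns ``(reflectance, standard_error)`` spectra on the sensor band
    grid.  Raises on non-physical materials (ρ+τ > 1 at a sensed band) and
    on zero total illumination at a sensed band.
    """
    for name in CanopyScene.REQUIRED_MATERIALS:
        if name not in scene.materials:
            raise ValueError(f"scene is missing material binding {name!r}")
    bands = np.asarray(sensor.bands, dtype=float)
    if sensor.footprint_center is None:
        cx = cy = scene.tile_width / 2.0
    else:
        cx, cy = sensor.footprint_center
    half = sensor.footprint_size / 2.0
    if not (0.0 <= cx - half and cx + half <= scene.tile_width
            and 0.0 <= cy - half and cy + half <= scene.tile_width):
        raise ValueError("sensor footprint must lie inside the core tile")

    tr = _tracer(scene)
    sun = np.ascontiguousarray(illum.sun_direction, dtype=float)
    refl = np.empty(len(bands))
    serr = np.empty(len(bands))
    for bi, lam in enumerate(bands):
        rho, tau = _material_tables(scene, lam)
        if np.any(rho + tau > 1.0 + 1e-12):
            raise ValueError(f"non-physical material at {lam} nm: rho+tau > 1")
        e_perp = illum.direct.value_at(lam)
        l_sky = illum.diffuse.value_at(lam)
        e_h = illum.horizontal_irradiance(lam)
        if e_h <= 0:
            raise ValueError(f"zero illumination at {lam} nm")
        band_seed = (sensor.seed * 1000003 + bi * 7919 + 1) % (2**31 - 1)
        mean, se = tracing.render_band_kernel(
            *tr.args(), tr.mats_sorted, tr.offsets,
            rho, tau, sun, e_perp, l_sky, e_h,
            cx - half, cx + half, cy - half, cy + half, tr.z_top + 1.0,
            sensor.samples_for(lam), band_seed,
            sensor.max_depth, sensor.rr_depth, sensor.rr_prob,
        )
        refl[bi] = mean
        serr[bi] = se
    return (
        Spectrum(bands, refl, kind="hdrf"),
        Spectrum(bands, serr, kind="hdrf_stderr"),
    )


def canopy_openness(
    scene: CanopyScene,
    view_point: np.ndarray | None = None,
    n_rays: int = 20000,
    seed: int = 0,
) -> tuple[float, float]:
    """Sky fraction of the upper hemisphere from below the canopy.

    Emulates hemispherical photography: rays are sampled uniformly over the
    upper-hemisphere solid angle from ``view_point`` (default: center of the
    core tile at 1.3 m) and the unobstructed fraction is returned with its
    binomial standard error.
    """
    if n_rays < 100:
        raise ValueError("n_rays must be >= 100 for a meaningful estimate")
    if view_point is None:
        view_point = np.array([scene.tile_width / 2.0, scene.tile_width / 2.0, 1.3])
    tr = _tracer(scene)
    frac, se = tracing.openness_kernel(
        *tr.args(), tr.offsets,
        float(view_point[0]), float(view_point[1]), float(view_point[2]),
        int(n_rays), int(seed) % (2**31 - 1),
    )
    return float(frac), float(se)


def intersect(
    ray_origin: np.ndarray,
    ray_direction: np.ndarray,
    scene: CanopyScene,
) -> tuple[bool, float, int, np.ndarray | None]:
    """Nearest-hit query: (hit?, distance, core triangle index, unit normal).

    The triangle index refers to the scene's core triangle soup
    (:meth:`CanopyScene.core_triangles` order); -1 when nothing is hit.
    """
    tr = _tracer(scene)
    o = np.asarray(ray_origin, dtype=float)
    d = np.asarray(ray_direction, dtype=float)
    d = d / np.linalg.norm(d)
    t, i, k = tracing._intersect_tiled(
        o[0], o[1], o[2], d[0], d[1], d[2], 1e-12, 1e30, tr.offsets, *tr.args()
    )
    if i < 0:
        return False, np.inf, -1, None
    normal = np.cross(tr.bvh.e1[i], tr.bvh.e2[i])
    normal = normal / np.linalg.norm(normal)
    return True, float(t), int(tr.bvh.order[i]), normal
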