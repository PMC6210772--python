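"""Radiative transfer: closed-form recoveries and estimator contracts."""

import dataclasses

import numpy as np
import pytest

from tests.conftest import flat_materials, flat_spectrum
from voxcanopy import tracing
from voxcanopy.render import (
    IlluminationModel,
    SensorConfig,
    canopy_openness,
    intersect,
    render_reflectance,
)
from voxcanopy.scene import build_scene, clone_scene

W = 200.0
BANDS = np.array([500.0, 800.0])


def soil_scene(soil_rho):
    return build_scene(np.empty((0, 3)), [], W, flat_materials(soil_r=soil_rho))


def slab_scene(leaf_r, leaf_t, soil_rho, z=1.0):
    """A huge opaque/translucent horizontal slab above a Lambertian soil."""
    scene = build_scene(
        np.empty((0, 3)), [], W,
        flat_materials(leaf_r=leaf_r, leaf_t=leaf_t, soil_r=soil_rho),
    )
    slab = np.array(
        [[[-2000.0, -2000, z], [3000, -2000, z], [3000, 3000, z]],
         [[-2000.0, -2000, z], [3000, 3000, z], [-2000, 3000, z]]]
    )
    return dataclasses.replace(scene, leaf_vertices=slab)


def sensor(n=4000, seed=7, bands=BANDS):
    return SensorConfig(footprint_center=(W / 2, W / 2), footprint_size=21.0,
                        bands=bands, samples_per_band=n, seed=seed)


ILLUM = IlluminationModel(sun_zenith_deg=30.0)


def test_lambertian_plane_recovers_albedo():
    refl, se = render_reflectance(soil_scene(0.25), ILLUM, sensor())
    assert np.all(np.abs(refl.values - 0.25) < 3 * se.values + 1e-12)


def test_black_scene_is_exactly_zero():
    refl, se = render_reflectance(soil_scene(0.0), ILLUM, sensor(n=500))
    assert np.all(refl.values == 0.0)


def test_opaque_slab_hides_soil():
    refl, se = render_reflectance(slab_scene(0.5, 0.0, 0.9), ILLUM, sensor())
    assert np.all(np.abs(refl.values - 0.5) < 3 * se.values + 1e-12)


def test_white_furnace_reaches_unity():
    refl, se = render_reflectance(slab_scene(1.0, 0.0, 1.0), ILLUM, sensor())
    assert np.all(np.abs(refl.values - 1.0) < 3 * se.values + 1e-9)
    assert np.all(refl.values <= 1.0 + 3 * se.values + 1e-9)


def test_translucent_slab_over_soil_matches_adding_formula():
    # Lambertian layer (rho1, tau1) over Lambertian soil rho_s:
    # R = rho1 + tau1^2 rho_s / (1 - rho1 rho_s)
    rho1, tau1, rho_s = 0.3, 0.4, 0.8
    expected = rho1 + tau1**2 * rho_s / (1 - rho1 * rho_s)
    refl, se = render_reflectance(slab_scene(rho1, tau1, rho_s), ILLUM, sensor(n=20000))
    assert np.all(np.abs(refl.values - expected) < 3 * se.values)


def test_energy_conservation_under_diffuse_sky_only():
    illum = IlluminationModel(sun_zenith_deg=30.0,
                              direct=flat_spectrum(0.0),
                              diffuse=flat_spectrum(0.3))
    refl, se = render_reflectance(slab_scene(0.45, 0.45, 0.9), illum, sensor(n=8000))
    assert np.all(refl.values <= 1.0 + 3 * se.values)
    assert np.all(refl.values >= 0.0)


def test_variance_shrinks_with_sample_count():
    ses = []
    for n in (1000, 4000, 16000):
        _, se = render_reflectance(slab_scene(0.3, 0.4, 0.8), ILLUM,
                                   sensor(n=n, bands=np.array([800.0])))
        ses.append(se.values[0])
    assert ses[2] < ses[1] < ses[0]
    # ~1/sqrt(n): quadrupling samples should halve the error (loosely)
    assert ses[1] / ses[0] == pytest.approx(0.5, abs=0.2)
    assert ses[2] / ses[1] == pytest.approx(0.5, abs=0.2)


def test_seeded_determinism():
    a, _ = render_reflectance(slab_scene(0.3, 0.4, 0.8), ILLUM, sensor(n=2000))
    b, _ = render_reflectance(slab_scene(0.3, 0.4, 0.8), ILLUM, sensor(n=2000))
    np.testing.assert_array_equal(a.values, b.values)


def test_nonphysical_material_rejected():
    scene = slab_scene(0.7, 0.5, 0.5)  # rho + tau = 1.2
    with pytest.raises(ValueError, match="non-physical"):
        render_reflectance(scene, ILLUM, sensor(n=100))


def test_zero_illumination_rejected():
    illum = IlluminationModel(direct=flat_spectrum(0.0), diffuse=flat_spectrum(0.0))
    with pytest.raises(ValueError, match="zero illumination"):
        render_reflectance(soil_scene(0.3), illum, sensor(n=100))


def test_footprint_must_fit_core_tile():
    scene = soil_scene(0.3)
    bad = SensorConfig(footprint_center=(5.0, 5.0), footprint_size=21.0, bands=BANDS)
    with pytest.raises(ValueError, match="footprint"):
        render_reflectance(scene, ILLUM, bad)


class TestOpenness:
    def test_empty_scene_fully_open(self):
        scene = build_scene(np.empty((0, 3)), [], 50.0, flat_materials())
        frac, se = canopy_openness(scene, n_rays=2000, seed=1)
        assert frac == 1.0

    def test_full_slab_fully_closed(self):
        # the slab is finite, so a handful of near-horizontal rays can
        # slip past its rim; everything else must be blocked
        frac, se = canopy_openness(slab_scene(0.5, 0.0, 0.5, z=5.0),
                                   view_point=np.array([W / 2, W / 2, 1.3]),
                                   n_rays=2000, seed=1)
        assert frac <= 0.005

    def test_half_plane_half_open(self):
        # slab covering x > viewpoint only: half the azimuths blocked
        scene = build_scene(np.empty((0, 3)), [], W, flat_materials())
        half = np.array(
            [[[W / 2, -2000.0, 5.0], [3000, -2000, 5.0], [3000, 3000, 5.0]],
             [[W / 2, -2000.0, 5.0], [3000, 3000, 5.0], [W / 2, 3000, 5.0]]]
        )
        scene = dataclasses.replace(scene, leaf_vertices=half)
        frac, se = canopy_openness(scene, view_point=np.array([W / 2, W / 2, 1.3]),
                                   n_rays=20000, seed=3)
        assert abs(frac - 0.5) < 3 * se + 0.01

    def test_too_few_rays_rejected(self):
        with pytest.raises(ValueError):
            canopy_openness(soil_scene(0.2), n_rays=50)


class TestIntersectionOracle:
    def random_scene(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        centers = rng.random((n, 3)) * 10.0
        span = rng.standard_normal((n, 2, 3)) * 0.3
        tris = np.stack([centers, centers + span[:, 0], centers + span[:, 1]], axis=1)
        return tris

    def brute_force(self, o, d, v0, e1, e2):
        """Vectorized Moller-Trumbore over every triangle (oracle)."""
        p = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, p)
        ok = np.abs(det) > 1e-14
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = o - v0
        u = np.einsum("ij,ij->i", tvec, p) * inv
        q = np.cross(tvec, e1)
        v = np.einsum("j,ij->i", d, q) * inv
        t = np.einsum("ij,ij->i", e2, q) * inv
        ok &= (u >= -1e-9) & (u <= 1 + 1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
        ok &= t > 1e-7
        if not ok.any():
            return np.inf, -1
        j = np.flatnonzero(ok)[np.argmin(t[ok])]
        return t[j], j

    def test_bvh_equals_brute_force_on_500_triangles(self):
        tris = self.random_scene()
        bvh = tracing.build_bvh(tris)
        v0 = bvh.v0.astype(float)
        e1 = bvh.e1.astype(float)
        e2 = bvh.e2.astype(float)
        rng = np.random.default_rng(1)
        origins = rng.random((10_000, 3)) * 12.0 - 1.0
        dirs = rng.standard_normal((10_000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        offsets = np.zeros((1, 2))
        mism = 0
        for o, d in zip(origins, dirs):
            t_b, i_b, _ = tracing._intersect_tiled(
                o[0], o[1], o[2], d[0], d[1], d[2], 1e-7, 1e30, offsets, *bvh.args()
            )
            t_o, i_o = self.brute_force(o, d, v0, e1, e2)
            if i_o == -1:
                assert i_b == -1
            else:
                assert i_b == i_o or abs(t_b - t_o) < 1e-9
        assert mism == 0

    def test_miss_returns_sentinel(self):
        tris = self.random_scene(10)
        scene = build_scene(np.empty((0, 3)), [], 50.0, flat_materials())
        scene = dataclasses.replace(scene, leaf_vertices=tris,
                                    soil_vertices=np.empty((0, 3, 3)))
        hit, t, idx, normal = intersect(np.array([0.0, 0, 100.0]),
                                        np.array([0.0, 0, 1.0]), scene)
        assert not hit and idx == -1 and normal is None

    def test_single_triangle_exact_hit(self):
        tri = np.array([[[0.0, 0, 1], [1, 0, 1], [0, 1, 1.0]]])
        scene = build_scene(np.empty((0, 3)), [], 50.0, flat_materials())
        scene = dataclasses.replace(scene, leaf_vertices=tri,
                                    soil_vertices=np.empty((0, 3, 3)))
        hit, t, idx, normal = intersect(np.array([0.2, 0.2, 0.0]),
                                        np.array([0.0, 0, 1.0]), scene)
        assert hit and idx == 0
        assert t == pytest.approx(1.0, abs=1e-6)
        assert abs(abs(normal[2]) - 1.0) < 1e-9
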