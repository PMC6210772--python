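import numpy as np
import pytest

from voxcanopy.voxel import (
    VoxelGrid,
    lad_profile,
    reduce_lai,
    translate_lad,
    voxelize,
)


def grid_from_cells(leaf_cells, trunk_cells=None, side=0.02, ground_area=1.0):
    leaf = np.asarray(leaf_cells, dtype=np.int64).reshape(-1, 3)
    trunk = (np.empty((0, 3), dtype=np.int64) if trunk_cells is None
             else np.asarray(trunk_cells, dtype=np.int64).reshape(-1, 3))
    cells = np.vstack([leaf, trunk]) if len(leaf) + len(trunk) else leaf
    dims = cells.max(axis=0) + 1 if len(cells) else np.zeros(3, dtype=np.int64)
    return VoxelGrid(np.zeros(3), side, dims, leaf, trunk, ground_area)


class TestVoxelize:
    def test_single_point_fills_one_cell_at_origin(self):
        g = voxelize(np.array([[0.01, 0.01, 0.01]]), side=0.02, origin=np.zeros(3))
        assert g.n_leaf == 1
        np.testing.assert_array_equal(g.leaf_cells[0], [0, 0, 0])

    def test_two_close_points_share_a_voxel(self):
        pts = np.array([[0.010, 0.010, 0.010], [0.011, 0.010, 0.010]])
        g = voxelize(pts, side=0.02, origin=np.zeros(3))
        assert g.n_filled == 1

    def test_lattice_of_cell_centers_counts_exactly(self):
        ii = np.arange(10)
        gx, gy, gz = np.meshgrid(ii, ii, ii, indexing="ij")
        pts = 0.02 * (np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + 0.5)
        g = voxelize(pts, side=0.02, origin=np.zeros(3))
        assert g.n_filled == 1000

    def test_trunk_wins_class_ties(self):
        pts = np.array([[0.01, 0.01, 0.01], [0.012, 0.011, 0.011]])
        g = voxelize(pts, labels=np.array([0, 1]), side=0.02, origin=np.zeros(3))
        assert g.n_trunk == 1 and g.n_leaf == 0

    def test_empty_input_is_a_valid_empty_grid(self):
        g = voxelize(np.empty((0, 3)))
        assert g.n_filled == 0

    def test_order_independence(self):
        rng = np.random.default_rng(0)
        pts = rng.random((500, 3))
        labels = (rng.random(500) < 0.3).astype(int)
        a = voxelize(pts, labels, side=0.05, origin=np.zeros(3))
        perm = rng.permutation(500)
        b = voxelize(pts[perm], labels[perm], side=0.05, origin=np.zeros(3))
        assert {tuple(c) for c in a.leaf_cells} == {tuple(c) for c in b.leaf_cells}
        assert {tuple(c) for c in a.trunk_cells} == {tuple(c) for c in b.trunk_cells}


class TestLADProfile:
    def test_counting_arithmetic(self):
        # 2500 leaf voxels x 4e-4 m2 over 1 m2 ground -> LAI exactly 1
        cells = np.column_stack([np.arange(2500) % 50, np.arange(2500) // 50,
                                 np.zeros(2500, dtype=int)])
        g = grid_from_cells(cells, ground_area=1.0)
        prof = lad_profile(g, layer_dz=1.0, quantum=4e-4)
        assert prof.lai == pytest.approx(1.0)
        assert g.lai() == pytest.approx(1.0)

    def test_empty_grid_zero_profile(self):
        g = grid_from_cells(np.empty((0, 3)))
        prof = lad_profile(g)
        assert prof.lai == 0.0
        assert np.all(prof.lad == 0.0)

    def test_study_scale_bookkeeping(self):
        # 5,220,000 leaf voxels over 900 m2 -> LAI 2.32
        n = 5_220_000
        side = 1500  # 30 m / 0.02 m
        idx = np.arange(n, dtype=np.int64)
        cells = np.column_stack([idx % side, (idx // side) % side, idx // side**2])
        g = grid_from_cells(cells, ground_area=900.0)
        assert g.lai() == pytest.approx(2.32)

    def test_layer_misalignment_and_zero_area_rejected(self):
        g = grid_from_cells([[0, 0, 0]])
        with pytest.raises(ValueError, match="multiple"):
            lad_profile(g, layer_dz=0.05)
        g_bad = grid_from_cells([[0, 0, 0]], ground_area=0.0)
        with pytest.raises(ValueError, match="ground_area"):
            lad_profile(g_bad)

    def test_lai_equals_sum_lad_dz(self):
        rng = np.random.default_rng(2)
        cells = rng.integers(0, 200, size=(4000, 3))
        g = grid_from_cells(np.unique(cells, axis=0), ground_area=4.0)
        prof = lad_profile(g, layer_dz=0.5)
        assert prof.lai == pytest.approx(np.sum(prof.lad) * 0.5)
        assert prof.lai == pytest.approx(g.lai())


class TestReduceLAI:
    def make(self, n_per_layer=10, n_layers=3):
        cells = []
        for layer in range(n_layers):
            for i in range(n_per_layer):
                cells.append([i, layer, layer * 50 + 5])
        return grid_from_cells(cells)

    def test_zero_fraction_is_identity(self):
        g = self.make()
        out = reduce_lai(g, 0.0)
        np.testing.assert_array_equal(out.leaf_cells, g.leaf_cells)

    def test_per_layer_counting(self):
        g = self.make(n_per_layer=10, n_layers=4)
        out = reduce_lai(g, 0.10, seed=1)
        zc = out.leaf_cells[:, 2] // 50
        for layer in range(4):
            assert (zc == layer).sum() == 9  # exactly one removed per layer

    def test_lad_scales_by_one_minus_f(self):
        rng = np.random.default_rng(3)
        cells = np.unique(rng.integers(0, 100, size=(5000, 3)), axis=0)
        g = grid_from_cells(cells, ground_area=4.0)
        prof = lad_profile(g)
        out = reduce_lai(g, 0.25, seed=2)
        prof2 = lad_profile(out)
        quantum_per_layer = 4e-4 / 4.0
        for a, b in zip(prof.lad, prof2.lad):
            assert abs(b - 0.75 * a) <= quantum_per_layer + 1e-12

    def test_trunks_untouched_and_bad_fraction_rejected(self):
        g = grid_from_cells([[0, 0, 0]], trunk_cells=[[1, 1, 1]])
        out = reduce_lai(g, 0.5, seed=0)
        np.testing.assert_array_equal(out.trunk_cells, g.trunk_cells)
        for bad in (-0.1, 1.0, 1.2):
            with pytest.raises(ValueError):
                reduce_lai(g, bad)

    def test_seeded_reproducibility(self):
        g = self.make(50, 5)
        a = reduce_lai(g, 0.3, seed=9)
        b = reduce_lai(g, 0.3, seed=9)
        np.testing.assert_array_equal(a.leaf_cells, b.leaf_cells)


class TestTranslateLAD:
    def make(self, n_upper=1000, n_lower=300):
        rng = np.random.default_rng(0)
        upper = np.column_stack([
            rng.integers(0, 300, n_upper), rng.integers(0, 300, n_upper),
            rng.integers(900, 1200, n_upper),  # z in [18, 24) m at 2 cm
        ])
        lower = np.column_stack([
            rng.integers(50, 250, n_lower), rng.integers(50, 250, n_lower),
            rng.integers(400, 700, n_lower),  # z in [8, 14) m
        ])
        cells = np.unique(np.vstack([upper, lower]), axis=0)
        return grid_from_cells(cells, ground_area=36.0)

    def test_zero_move_is_identity(self):
        g = self.make()
        out = translate_lad(g, 0.0)
        np.testing.assert_array_equal(out.leaf_cells, g.leaf_cells)

    def test_counts_and_exact_lai_conservation(self):
        g = self.make()
        zc0 = (g.leaf_cells[:, 2] + 0.5) * g.side
        n_upper = int((zc0 >= 17.0).sum())
        out = translate_lad(g, 0.5, split_height=17.0, floor_height=1.3, seed=4)
        assert out.n_leaf == g.n_leaf  # LAI conserved exactly
        zc = (out.leaf_cells[:, 2] + 0.5) * out.side
        moved = n_upper - int((zc >= 17.0).sum())
        assert moved == round(0.5 * n_upper)
        assert int((zc < 17.0).sum()) - (g.n_leaf - n_upper) == moved

    def test_new_voxels_empty_before_and_in_receiving_band(self):
        g = self.make()
        out = translate_lad(g, 0.5, seed=4)
        before = {tuple(c) for c in g.leaf_cells}
        new = [tuple(c) for c in out.leaf_cells if tuple(c) not in before]
        zc = np.array([(c[2] + 0.5) * g.side for c in new])
        assert np.all((zc > 1.3) & (zc < 17.0))

    def test_no_receiving_layers_errors(self):
        rng = np.random.default_rng(1)
        upper_only = np.column_stack([
            rng.integers(0, 100, 200), rng.integers(0, 100, 200),
            rng.integers(900, 1000, 200),
        ])
        g = grid_from_cells(np.unique(upper_only, axis=0))
        with pytest.raises(ValueError, match="receiving"):
            translate_lad(g, 0.5)

    def test_invalid_parameters(self):
        g = self.make()
        with pytest.raises(ValueError):
            translate_lad(g, 1.5)
        with pytest.raises(ValueError):
            translate_lad(g, 0.5, split_height=1.0, floor_height=2.0)

    def test_seeded_reproducibility(self):
        g = self.make()
        a = translate_lad(g, 0.5, seed=8)
        b = translate_lad(g, 0.5, seed=8)
        np.testing.assert_array_equal(a.leaf_cells, b.leaf_cells)


def test_voxelize_idempotent_on_voxel_centers():
    rng = np.random.default_rng(5)
    cells = np.unique(rng.integers(0, 50, size=(400, 3)), axis=0)
    g = grid_from_cells(cells)
    again = voxelize(g.leaf_centers(), side=g.side, origin=g.origin)
    assert {tuple(c) for c in again.leaf_cells} == {tuple(c) for c in g.leaf_cells}


def test_save_load_round_trip(tmp_path):
    g = grid_from_cells([[1, 2, 3], [4, 5, 6]], trunk_cells=[[7, 8, 9]],
                        ground_area=4.0)
    path = tmp_path / "grid.npz"
    g.save(path)
    back = VoxelGrid.load(path)
    np.testing.assert_array_equal(back.leaf_cells, g.leaf_cells)
    np.testing.assert_array_equal(back.trunk_cells, g.trunk_cells)
    assert back.ground_area == g.ground_area
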