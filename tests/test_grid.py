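"""Grid data model: interpolation, mask algebra, margins, centroids, I/O."""

import numpy as np
import pytest

import warp4d as w
from warp4d.grid import GridMismatchError


class TestGrid3D:
    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(ValueError, match="spacing"):
            w.Grid3D((5, 5, 5), (0.0, 1.0, 1.0))

    def test_rejects_empty_shape(self):
        with pytest.raises(ValueError):
            w.Grid3D((0, 5, 5), (1.0, 1.0, 1.0))

    def test_world_index_round_trip(self, small_grid, rng):
        idx = rng.uniform(0, 9, size=(20, 3))
        back = small_grid.world_to_index(small_grid.index_to_world(idx))
        np.testing.assert_allclose(back, idx, atol=1e-12)


class TestTrilinearSampling:
    def test_voxel_centers_return_stored_values(self, random_volume):
        g = random_volume.grid
        idx = np.array([[0, 0, 0], [3, 4, 5], [11, 9, 13]])
        got = w.sample_trilinear(random_volume, g.index_to_world(idx))
        np.testing.assert_allclose(got, random_volume.values[tuple(idx.T)],
                                   atol=1e-12)

    def test_constant_volume_interior_points(self, small_grid, rng):
        vol = w.ScalarVolume(small_grid, np.full(small_grid.shape, 7.25))
        pts = small_grid.index_to_world(
            rng.uniform(0.5, 8.5, size=(50, 3)))
        np.testing.assert_allclose(w.sample_trilinear(vol, pts), 7.25,
                                   atol=1e-12)

    def test_matches_eight_neighbor_oracle(self, random_volume, rng):
        """Interior samples equal an independently coded weighted sum of the
        8 surrounding voxel values."""
        g = random_volume.grid
        frac_idx = rng.uniform(0.0, np.array(g.shape) - 1.001, size=(100, 3))
        pts = g.index_to_world(frac_idx)
        got = w.sample_trilinear(random_volume, pts)

        expected = []
        for fi in frac_idx:
            i0 = np.floor(fi).astype(int)
            f = fi - i0
            val = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        wgt = ((f[0] if dx else 1 - f[0])
                               * (f[1] if dy else 1 - f[1])
                               * (f[2] if dz else 1 - f[2]))
                        val += wgt * random_volume.values[
                            i0[0] + dx, i0[1] + dy, i0[2] + dz]
            expected.append(val)
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_out_of_grid_policies(self, random_volume):
        far = np.array([[1e4, 1e4, 1e4]])
        assert w.sample_trilinear(random_volume, far, out_of_grid=0.0) == 0.0
        edge_val = w.sample_trilinear(random_volume, far, out_of_grid="nearest")
        assert edge_val == random_volume.values[-1, -1, -1]

    def test_rejects_nonfinite_points(self, random_volume):
        with pytest.raises(ValueError):
            w.sample_trilinear(random_volume, np.array([[np.nan, 0, 0]]))


class TestMaskBoolean:
    @pytest.fixture
    def masks(self, rng):
        g = w.Grid3D((20, 20, 20), (1.0, 1.0, 1.0))
        a = w.StructureMask(g, rng.random(g.shape) > 0.5, "a")
        b = w.StructureMask(g, rng.random(g.shape) > 0.7, "b")
        return a, b

    @pytest.mark.parametrize("op", ["union", "intersection", "difference"])
    def test_matches_voxel_loop_oracle(self, masks, op):
        a, b = masks
        got = w.mask_boolean(a, b, op).member
        fn = {"union": lambda x, y: x or y,
              "intersection": lambda x, y: x and y,
              "difference": lambda x, y: x and not y}[op]
        for idx in [(0, 0, 0), (5, 7, 3), (19, 19, 19), (12, 1, 8)]:
            assert got[idx] == fn(bool(a.member[idx]), bool(b.member[idx]))
        # full exhaustive check via vectorized equivalent of the loop
        expected = np.array(
            [fn(bool(x), bool(y))
             for x, y in zip(a.member.ravel(), b.member.ravel())]
        ).reshape(a.member.shape)
        assert np.array_equal(got, expected)

    def test_union_idempotent(self, masks):
        a, _ = masks
        assert np.array_equal(w.mask_boolean(a, a, "union").member, a.member)

    def test_difference_subset_and_volume_conservation(self, masks):
        a, b = masks
        diff = w.mask_boolean(a, b, "difference")
        inter = w.mask_boolean(a, b, "intersection")
        assert not np.any(diff.member & ~a.member)
        assert diff.voxel_count + inter.voxel_count == a.voxel_count
        assert diff.volume_cc + inter.volume_cc == pytest.approx(
            a.volume_cc, rel=1e-12)

    def test_grid_mismatch_rejected(self, masks):
        a, _ = masks
        other = w.StructureMask(w.Grid3D((20, 20, 20), (2.0, 1.0, 1.0)),
                                np.zeros((20, 20, 20), bool))
        with pytest.raises(GridMismatchError):
            w.mask_boolean(a, other, "union")


class TestExpandMargin:
    def test_single_voxel_matches_distance_oracle(self):
        g = w.Grid3D((21, 21, 21), (1.0, 1.0, 1.0))
        m = np.zeros(g.shape, bool)
        m[10, 10, 10] = True
        got = w.expand_margin(w.StructureMask(g, m, "seed"), 5.0)
        ii, jj, kk = np.meshgrid(*[np.arange(21)] * 3, indexing="ij")
        dist = np.sqrt((ii - 10.0) ** 2 + (jj - 10.0) ** 2 + (kk - 10.0) ** 2)
        assert np.array_equal(got.member, dist <= 5.0 + 1e-9)

    def test_anisotropic_grid_uses_mm_distance(self):
        g = w.Grid3D((11, 11, 11), (1.0, 2.0, 4.0))
        m = np.zeros(g.shape, bool)
        m[5, 5, 5] = True
        got = w.expand_margin(w.StructureMask(g, m, "seed"), 4.0)
        assert got.member[5, 5, 6]      # 4 mm along z
        assert got.member[5, 7, 5]      # 4 mm along y
        assert not got.member[5, 5, 7]  # 8 mm along z
        assert got.member[9, 5, 5] and not got.member[10, 5, 5]

    def test_zero_margin_is_identity(self, rng):
        g = w.Grid3D((15, 15, 15), (1.0, 1.0, 1.0))
        m = w.StructureMask(g, rng.random(g.shape) > 0.8, "m")
        assert np.array_equal(w.expand_margin(m, 0.0).member, m.member)

    def test_monotone_in_margin(self, rng):
        g = w.Grid3D((20, 20, 20), (1.5, 1.5, 1.5))
        m = w.StructureMask(g, rng.random(g.shape) > 0.95, "m")
        e3 = w.expand_margin(m, 3.0)
        e5 = w.expand_margin(m, 5.0)
        assert not np.any(e3.member & ~e5.member)
        assert not np.any(m.member & ~e3.member)

    def test_negative_margin_rejected(self, rng):
        g = w.Grid3D((5, 5, 5), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            w.expand_margin(w.StructureMask(g, np.ones(g.shape, bool)), -1.0)


class TestCentroid:
    def test_symmetric_cube(self):
        g = w.Grid3D((10, 10, 10), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
        m = np.zeros(g.shape, bool)
        m[2:5, 2:5, 2:5] = True
        np.testing.assert_allclose(
            w.centroid(w.StructureMask(g, m)), [6.0, 6.0, 6.0])

    def test_single_voxel(self):
        g = w.Grid3D((6, 6, 6), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        m = np.zeros(g.shape, bool)
        m[2, 3, 4] = True
        np.testing.assert_allclose(
            w.centroid(w.StructureMask(g, m)), [2.0, 3.0, 4.0])

    def test_matches_mean_oracle(self, rng):
        g = w.Grid3D((12, 12, 12), (1.0, 2.0, 3.0), (-5.0, 0.0, 7.0))
        m = w.StructureMask(g, rng.random(g.shape) > 0.6, "m")
        expected = np.mean(
            [g.index_to_world(i)[0] for i in np.argwhere(m.member)], axis=0)
        np.testing.assert_allclose(w.centroid(m), expected, atol=1e-9)

    def test_empty_mask_rejected(self):
        g = w.Grid3D((4, 4, 4), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            w.centroid(w.StructureMask(g, np.zeros(g.shape, bool)))


class TestBuildTargets:
    def test_identical_gtvs_give_itv_equal_gtv(self, rng):
        g = w.Grid3D((16, 16, 16), (1.0, 1.0, 1.0))
        m = w.StructureMask(g, rng.random(g.shape) > 0.9, "GTV")
        t = w.build_targets(m, m, margin_mm=0.0)
        assert np.array_equal(t["ITV"].member, m.member)

    def test_disjoint_union_doubles_volume(self):
        g = w.Grid3D((20, 20, 20), (1.0, 1.0, 1.0))
        a = np.zeros(g.shape, bool)
        b = np.zeros(g.shape, bool)
        a[2:5, 2:5, 2:5] = True
        b[10:13, 10:13, 10:13] = True
        t = w.build_targets(w.StructureMask(g, a), w.StructureMask(g, b),
                            margin_mm=0.0)
        assert t["ITV"].voxel_count == 2 * 27

    def test_intersection_mode(self):
        g = w.Grid3D((10, 10, 10), (1.0, 1.0, 1.0))
        a = np.zeros(g.shape, bool)
        b = np.zeros(g.shape, bool)
        a[2:6, 2:6, 2:6] = True
        b[4:8, 2:6, 2:6] = True
        t = w.build_targets(w.StructureMask(g, a), w.StructureMask(g, b),
                            margin_mm=0.0, itv_mode="intersection")
        assert np.array_equal(t["ITV"].member, a & b)

    def test_containment_chain_on_shifted_gtvs(self):
        """GTV < ITV < PTV volume ordering for a translated GTV pair."""
        g = w.Grid3D((40, 40, 40), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        xs, ys, zs = g.coordinate_arrays()
        sphere = lambda cz: np.sqrt(
            (xs - 20) ** 2 + (ys - 20) ** 2 + (zs - cz) ** 2) <= 6.0
        gtv_ex = w.StructureMask(g, sphere(14.0), "GTV")
        gtv_in = w.StructureMask(g, sphere(24.0), "GTV")
        t = w.build_targets(gtv_ex, gtv_in, margin_mm=5.0)
        assert not np.any(gtv_ex.member & ~t["ITV"].member)
        assert not np.any(gtv_in.member & ~t["ITV"].member)
        assert not np.any(t["ITV"].member & ~t["PTV"].member)
        assert gtv_ex.volume_cc < t["ITV"].volume_cc < t["PTV"].volume_cc


class TestVolumeIO:
    def test_round_trip_identity(self, tmp_path, random_volume):
        path = str(tmp_path / "vol.nrrd")
        w.write_volume(random_volume, path)
        back = w.read_volume(path, kind="HU")
        assert back.grid.same_geometry(random_volume.grid, tol=0.0)
        np.testing.assert_array_equal(back.values, random_volume.values)

    @pytest.mark.parametrize("ext", ["nrrd", "mha"])
    def test_header_fields_preserved(self, tmp_path, ext):
        g = w.Grid3D((5, 5, 5), (3.0, 3.0, 3.0), (-100.0, -100.0, -50.0))
        vol = w.ScalarVolume(g, np.zeros(g.shape), "Gy")
        path = str(tmp_path / f"zeros.{ext}")
        w.write_volume(vol, path)
        back = w.read_volume(path, kind="Gy")
        assert back.grid.spacing == (3.0, 3.0, 3.0)
        assert back.grid.origin == (-100.0, -100.0, -50.0)
        np.testing.assert_array_equal(back.values, 0.0)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            w.read_volume(str(tmp_path / "absent.nrrd"))

    def test_mask_round_trip(self, tmp_path, rng):
        g = w.Grid3D((8, 8, 8), (2.0, 2.0, 2.0), (1.0, 2.0, 3.0))
        m = w.StructureMask(g, rng.random(g.shape) > 0.5, "liver")
        path = str(tmp_path / "mask.nrrd")
        w.write_mask(m, path)
        back = w.read_mask(path, name="liver")
        assert np.array_equal(back.member, m.member)

    def test_vector_field_round_trip(self, tmp_path, rng):
        g = w.Grid3D((6, 7, 8), (1.0, 2.0, 3.0), (0.0, 0.0, 0.0))
        f = w.VectorField(g, rng.normal(0, 5, g.shape + (3,)))
        path = str(tmp_path / "dvf.nrrd")
        w.write_vector_field(f, path)
        back = w.read_vector_field(path)
        np.testing.assert_allclose(back.displacements, f.displacements,
                                   atol=1e-12)


class TestResample:
    def test_identity_on_same_grid(self, random_volume):
        out = w.resample_to_grid(random_volume, random_volume.grid)
        np.testing.assert_array_equal(out.values, random_volume.values)

    def test_downsample_constant(self, small_grid):
        vol = w.ScalarVolume(small_grid, np.full(small_grid.shape, 3.5))
        coarse = w.Grid3D((5, 5, 5), (4.0, 4.0, 4.0), (-8.0, 7.0, -18.0))
        out = w.resample_to_grid(vol, coarse)
        np.testing.assert_allclose(out.values, 3.5)
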