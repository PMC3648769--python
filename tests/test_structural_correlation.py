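import numpy as np
import pytest
from scipy import stats

from alevbm import coords, structural_correlation as sc
from alevbm.coords import Point3
from alevbm.errors import ValidationError
from alevbm.structural_correlation import (
    ClusterConfig,
    GMImageSet,
    StatMap,
    cluster_peaks,
    gaussian_smooth,
    overlap_report,
    sphere_roi,
    suprathreshold_clusters,
    voxelwise_slope_t,
)


def flood_fill_labels(binary, connectivity):
    """Independent BFS labeling oracle for 6/18/26-connectivity."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                order = abs(di) + abs(dj) + abs(dk)
                if order == 0:
                    continue
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    for start in map(tuple, np.argwhere(binary)):
        if labels[start]:
            continue
        current += 1
        queue = [start]
        labels[start] = current
        while queue:
            ijk = queue.pop()
            for off in offsets:
                nb = tuple(np.add(ijk, off))
                if any(c < 0 or c >= s for c, s in zip(nb, binary.shape)):
                    continue
                if binary[nb] and not labels[nb]:
                    labels[nb] = current
                    queue.append(nb)
    return labels, current


class TestGaussianSmooth:
    def test_fwhm_zero_identity(self, grid16, rng):
        vol = rng.normal(size=grid16.shape)
        assert np.array_equal(gaussian_smooth(vol, 0.0, grid16), vol)

    def test_constant_preserved_everywhere(self, grid16):
        vol = np.full(grid16.shape, 3.7)
        out = gaussian_smooth(vol, 6.0, grid16)
        assert out == pytest.approx(vol, abs=1e-10)

    def test_delta_impulse_matches_closed_form(self):
        grid = coords.isotropic_grid((33, 33, 33), 2.0)
        vol = np.zeros(grid.shape)
        vol[16, 16, 16] = 1.0
        fwhm = 6.0
        out = gaussian_smooth(vol, fwhm, grid)
        sigma_vox = fwhm / 2.0 / np.sqrt(2 * np.log(2))  # mm; 2-mm voxels
        centers = grid.all_voxel_centers()
        d2 = np.sum(centers**2, axis=1)
        kernel = np.exp(-0.5 * d2 / sigma_vox**2)
        kernel /= kernel.sum()
        assert out.ravel() == pytest.approx(kernel, abs=2e-5)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_anisotropic_voxels_per_axis_sigma(self):
        aff = np.diag([1.0, 2.0, 4.0, 1.0])
        grid = coords.VolumeGrid(shape=(21, 21, 21), affine=aff)
        vol = np.zeros(grid.shape)
        vol[10, 10, 10] = 1.0
        out = gaussian_smooth(vol, 8.0, grid)
        # in voxel units the blur is widest along the finest axis
        profile_x = out[:, 10, 10]
        profile_z = out[10, 10, :]
        assert profile_x[12] > profile_z[12]

    def test_negative_fwhm_rejected(self, grid16):
        with pytest.raises(ValidationError):
            gaussian_smooth(np.zeros(grid16.shape), -1.0, grid16)


class TestVoxelwiseSlopeT:
    def _image_set(self, grid, data):
        return GMImageSet(grid=grid, images=data)

    def test_orthogonal_covariate_gives_zero_t(self, corner_grid):
        n = 8
        x = np.arange(n, dtype=float)
        xc = x - x.mean()
        y_vec = np.ones(n)  # constant => residual orthogonal to x
        data = np.tile(y_vec[:, None, None, None], (1, *corner_grid.shape))
        # add a voxel whose values are orthogonal to x but not constant
        perp = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        perp -= perp @ xc / (xc @ xc) * xc
        data[:, 0, 0, 0] = perp
        stat = voxelwise_slope_t(self._image_set(corner_grid, data), x)
        assert stat.t_values[0, 0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_pearson_identity_r_half_n_101(self, rng):
        grid = coords.isotropic_grid((2, 2, 2), 2.0)
        n = 101
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        xs = (x - x.mean()) / x.std()
        zc = z - z.mean() - (z - z.mean()) @ xs / (xs @ xs) * xs
        zs = zc / zc.std()
        r = 0.5
        y = r * xs + np.sqrt(1 - r**2) * zs  # sample correlation exactly 0.5
        data = rng.normal(size=(n, *grid.shape))
        data[:, 0, 0, 0] = y
        stat = voxelwise_slope_t(GMImageSet(grid=grid, images=data), x)
        expected = r * np.sqrt((n - 2) / (1 - r**2))
        assert stat.t_values[0, 0, 0] == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(5.745, abs=1e-3)

    def test_matches_linregress_oracle(self, rng):
        grid = coords.isotropic_grid((4, 4, 4), 2.0)
        n = 17
        x = rng.normal(size=n)
        data = rng.normal(size=(n, *grid.shape))
        stat = voxelwise_slope_t(GMImageSet(grid=grid, images=data), x)
        for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            res = stats.linregress(x, data[(slice(None), *idx)])
            t_oracle = res.slope / res.stderr
            assert stat.t_values[idx] == pytest.approx(t_oracle, abs=1e-10)
            assert stat.p_values[idx] == pytest.approx(
                stats.t.sf(t_oracle, n - 2), rel=1e-10
            )

    def test_duplicating_subjects_inflates_t(self, rng):
        grid = coords.isotropic_grid((2, 2, 2), 2.0)
        n = 10
        x = rng.normal(size=n)
        data = rng.normal(size=(n, *grid.shape)) + 0.5 * x[:, None, None, None]
        t1 = voxelwise_slope_t(GMImageSet(grid=grid, images=data), x)
        t2 = voxelwise_slope_t(
            GMImageSet(grid=grid, images=np.concatenate([data, data])),
            np.concatenate([x, x]),
        )
        assert t2.df == 2 * n - 2
        # duplication preserves r but doubles n: T scales by
        # sqrt((2n - 2)/(n - 2))
        scale = np.sqrt((2 * n - 2) / (n - 2))
        assert t2.t_values == pytest.approx(t1.t_values * scale, rel=1e-10)

    def test_constant_covariate_rejected(self, corner_grid, rng):
        data = rng.normal(size=(5, *corner_grid.shape))
        with pytest.raises(ValidationError):
            voxelwise_slope_t(GMImageSet(grid=corner_grid, images=data),
                              np.ones(5))

    def test_constant_voxel_flagged(self, rng, caplog):
        grid = coords.isotropic_grid((2, 2, 2), 2.0)
        data = rng.normal(size=(6, *grid.shape))
        data[:, 0, 0, 0] = 2.0
        with caplog.at_level("WARNING"):
            stat = voxelwise_slope_t(GMImageSet(grid=grid, images=data),
                                     np.arange(6.0))
        assert stat.t_values[0, 0, 0] == 0.0
        assert stat.p_values[0, 0, 0] == 1.0
        assert "constant" in caplog.text

    def test_null_exceedance_rate_calibrated(self, rng):
        grid = coords.isotropic_grid((12, 12, 12), 2.0)
        fracs = []
        for _ in range(20):
            data = rng.normal(size=(30, *grid.shape))
            x = rng.normal(size=30)
            stat = voxelwise_slope_t(GMImageSet(grid=grid, images=data), x)
            fracs.append(np.mean(stat.p_values < 0.01))
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.01) <= 3 * max(se, 1e-4)


def stat_from_t(grid, t, df=20):
    return StatMap(grid=grid, t_values=t, df=df)


class TestClusters:
    def test_no_suprathreshold_voxels_empty(self, grid16):
        stat = stat_from_t(grid16, np.zeros(grid16.shape))
        assert suprathreshold_clusters(stat, ClusterConfig()) == []

    def test_extent_150_rejected_151_retained(self, rng):
        grid = coords.isotropic_grid((20, 20, 20), 2.0)
        cfg = ClusterConfig()  # k_min 150, strict
        for size, expected in [(150, 0), (151, 1)]:
            t = np.zeros(grid.shape)
            # a connected slab: fill consecutive voxels of a 6x6 x-y block
            block = np.zeros(grid.shape, dtype=bool)
            count = 0
            for k in range(grid.shape[2]):
                for i in range(6):
                    for j in range(6):
                        if count < size:
                            block[i, j, k] = True
                            count += 1
            t[block] = 10.0
            stat = stat_from_t(grid, t)
            clusters = suprathreshold_clusters(stat, cfg)
            assert len(clusters) == expected
            if expected:
                assert clusters[0].size_voxels == size

    def test_corner_touching_blobs_connectivity(self):
        grid = coords.isotropic_grid((8, 8, 8), 2.0)
        t = np.zeros(grid.shape)
        t[0:2, 0:2, 0:2] = 9.0
        t[2:4, 2:4, 2:4] = 9.0  # touches only at the (2,2,2)/(1,1,1) corner
        stat = stat_from_t(grid, t)
        c26 = suprathreshold_clusters(stat, ClusterConfig(k_min=0, connectivity=26))
        c6 = suprathreshold_clusters(stat, ClusterConfig(k_min=0, connectivity=6))
        assert len(c26) == 1
        assert len(c6) == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labeling_matches_flood_fill_oracle(self, rng, connectivity):
        grid = coords.isotropic_grid((10, 10, 10), 2.0)
        binary = rng.random(grid.shape) < 0.25
        t = np.where(binary, 8.0 + rng.random(grid.shape), 0.0)
        stat = stat_from_t(grid, t)
        clusters = suprathreshold_clusters(
            stat, ClusterConfig(k_min=0, connectivity=connectivity)
        )
        oracle_labels, n_oracle = flood_fill_labels(binary, connectivity)
        assert len(clusters) == n_oracle
        oracle_sizes = sorted(
            int((oracle_labels == lab).sum()) for lab in range(1, n_oracle + 1)
        )
        assert sorted(c.size_voxels for c in clusters) == oracle_sizes

    def test_sorted_by_peak_t(self, rng):
        grid = coords.isotropic_grid((12, 12, 12), 2.0)
        t = np.zeros(grid.shape)
        t[1:3, 1:3, 1:3] = 5.0
        t[8:10, 8:10, 8:10] = 7.0
        clusters = suprathreshold_clusters(stat_from_t(grid, t),
                                           ClusterConfig(k_min=0))
        assert clusters[0].peak_t == pytest.approx(7.0)
        assert clusters[1].peak_t == pytest.approx(5.0)


class TestClusterPeaks:
    def test_single_voxel_cluster(self, grid16):
        t = np.zeros(grid16.shape)
        t[3, 3, 3] = 5.0
        stat = stat_from_t(grid16, t)
        peaks = cluster_peaks(stat, np.array([[3, 3, 3]]))
        assert len(peaks) == 1
        assert peaks[0][1] == pytest.approx(5.0)
        assert peaks[0][0].as_array() == pytest.approx(
            grid16.voxel_to_world([3, 3, 3])[0]
        )

    def test_two_bumps_twenty_mm_apart(self):
        grid = coords.isotropic_grid((21, 21, 21), 2.0)
        centers = grid.all_voxel_centers()
        c1 = np.array([-10.0, 0.0, 0.0])
        c2 = np.array([10.0, 0.0, 0.0])
        t = (
            6 * np.exp(-np.sum((centers - c1) ** 2, axis=1) / 50)
            + 5 * np.exp(-np.sum((centers - c2) ** 2, axis=1) / 50)
        ).reshape(grid.shape)
        stat = stat_from_t(grid, t)
        idx = np.argwhere(t > 0.5)
        peaks = cluster_peaks(stat, idx, min_separation_mm=8.0)
        assert len(peaks) == 2
        assert peaks[0][0].as_array() == pytest.approx(c1, abs=2.0)
        assert peaks[1][0].as_array() == pytest.approx(c2, abs=2.0)

    def test_plateau_deterministic_tie_break(self, grid16):
        t = np.zeros(grid16.shape)
        t[4:6, 4:6, 4] = 3.0  # 4-voxel plateau
        idx = np.argwhere(t > 0)
        peaks = cluster_peaks(stat_from_t(grid16, t), idx, min_separation_mm=0.0)
        # lexicographically smallest voxel of the plateau wins first
        assert peaks[0][0].as_array() == pytest.approx(
            grid16.voxel_to_world([4, 4, 4])[0]
        )


class TestSphereAndOverlap:
    def test_tiny_radius_single_voxel(self, grid16):
        # (1, 1, 1) is a voxel center of the origin-centered 16^3 grid
        roi = sphere_roi(Point3(1, 1, 1, "world"), 0.5, grid16)
        assert roi.sum() == 1

    def test_radius_10_matches_bruteforce(self, grid16):
        roi = sphere_roi(Point3(0, 0, 0, "world"), 10.0, grid16)
        centers = grid16.all_voxel_centers()
        brute = (np.linalg.norm(centers, axis=1) <= 10.0).sum()
        assert roi.sum() == brute

    def test_growing_radius_monotone(self, grid16):
        sizes = [
            sphere_roi(Point3(1, 2, 3, "world"), r, grid16).sum()
            for r in (1, 3, 5, 8, 12)
        ]
        assert sizes == sorted(sizes)

    def test_outside_grid_warns_empty(self, grid16, caplog):
        with caplog.at_level("WARNING"):
            roi = sphere_roi(Point3(500, 0, 0, "world"), 3.0, grid16)
        assert roi.sum() == 0
        assert "outside" in caplog.text

    def test_overlap_disjoint(self, grid16):
        a = np.zeros(grid16.shape, bool)
        b = np.zeros(grid16.shape, bool)
        a[0, 0, 0] = True
        b[5, 5, 5] = True
        assert overlap_report(a, b, grid16).n_overlap == 0

    def test_subset_fraction_one(self, grid16):
        b = np.zeros(grid16.shape, bool)
        b[2:8, 2:8, 2:8] = True
        a = np.zeros(grid16.shape, bool)
        a[3:5, 3:5, 3:5] = True
        rep = overlap_report(a, b, grid16)
        assert rep.n_overlap == a.sum()
        assert rep.fraction_of_a == pytest.approx(1.0)

    def test_random_pair_matches_bruteforce(self, grid16, rng):
        a = rng.random(grid16.shape) < 0.3
        b = rng.random(grid16.shape) < 0.3
        rep = overlap_report(a, b, grid16)
        brute = sum(
            1
            for i in range(16)
            for j in range(16)
            for k in range(16)
            if a[i, j, k] and b[i, j, k]
        )
        assert rep.n_overlap == brute
        assert rep.overlap_mm3 == pytest.approx(brute * 8.0)
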