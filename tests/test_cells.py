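"""Membrane smoothing, cell segmentation, 3D morphometry, extraction."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from mitoquant.cells import (
    CellLabels,
    NoiseModel,
    close_labels,
    estimate_background_noise,
    extract_cell_stack,
    measure_cells,
    segment_cells,
    smooth_membrane,
)
from mitoquant.io import ImageStack, VoxelSpacing

ANISO = VoxelSpacing(0.104, 0.104, 0.72)
ISO = VoxelSpacing(0.2, 0.2, 0.2)


def _shell_stack(shape=(24, 48, 48), centre=None, radius=8.0, thickness=1.5):
    """Bright spherical shell (synthetic membrane) on dark background."""
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    c = centre or [(s - 1) / 2 for s in shape]
    r = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
    return np.exp(-0.5 * ((r - radius) / thickness) ** 2)


class TestSmoothMembrane:
    def test_constant_image_unchanged(self):
        stack = ImageStack(np.full((6, 12, 12), 2.0), ISO)
        out = smooth_membrane(stack)
        assert np.allclose(out.voxels, 2.0)

    def test_hot_pixel_suppressed(self):
        vox = np.full((7, 15, 15), 1.0)
        vox[3, 7, 7] = 100.0
        out = smooth_membrane(ImageStack(vox, ISO))
        assert out.voxels[3, 7, 7] == pytest.approx(1.0, abs=0.2)

    def test_step_edge_stays_put(self):
        vox = np.ones((6, 20, 20))
        vox[:, :, 10:] = 5.0
        out = smooth_membrane(ImageStack(vox, ISO))
        # the half-way crossing of the step must remain within 1 voxel
        profile = out.voxels[3, 10, :]
        crossing = np.argmax(profile > 3.0)
        assert abs(crossing - 10) <= 1

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            smooth_membrane(ImageStack(np.ones((4, 8, 8)), ISO), sigma_radius=0)


class TestSegmentCells:
    def test_single_shell_fills_interior(self):
        memb = ImageStack(_shell_stack(), ISO)
        labels = segment_cells(memb, seeds=[(11, 23, 23)])
        zz, yy, xx = np.mgrid[0:24, 0:48, 0:48]
        c = [(s - 1) / 2 for s in (24, 48, 48)]
        interior = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= 8.0**2
        pred = labels.grid == 1
        jac = (interior & pred).sum() / (interior | pred).sum()
        assert jac >= 0.9

    def test_two_cell_phantom_two_labels(self):
        a = _shell_stack(shape=(24, 48, 80), centre=(11.5, 23.5, 20), radius=8)
        b = _shell_stack(shape=(24, 48, 80), centre=(11.5, 23.5, 56), radius=8)
        memb = ImageStack(a + b, ISO)
        labels = segment_cells(memb, seeds=[(11, 23, 20), (11, 23, 56)])
        zz, yy, xx = np.mgrid[0:24, 0:48, 0:80]
        for lab, cx in [(1, 20), (2, 56)]:
            interior = (zz - 11.5) ** 2 + (yy - 23.5) ** 2 + (xx - cx) ** 2 <= 64
            pred = labels.grid == lab
            assert (interior & pred).sum() / (interior | pred).sum() >= 0.9

    def test_zero_seeds_rejected(self):
        with pytest.raises(ValueError):
            segment_cells(ImageStack(_shell_stack(), ISO), seeds=[])

    def test_seed_on_ridge_snapped_with_warning(self, caplog):
        memb = ImageStack(_shell_stack(), ISO)
        # (11, 23, 31) sits on the bright shell (radius 8 from centre)
        with caplog.at_level("WARNING", logger="mitoquant.cells"):
            labels = segment_cells(memb, seeds=[(11, 23, 31)])
        assert any("ridge" in r.message for r in caplog.records)
        assert (labels.grid == 1).sum() > 0


class TestCloseLabels:
    def test_pinhole_filled(self):
        grid = np.zeros((9, 15, 15), dtype=np.int32)
        grid[2:7, 3:12, 3:12] = 1
        grid[4, 7, 7] = 0  # interior pinhole
        out = close_labels(CellLabels(grid, ISO), radius=2)
        assert out.grid[4, 7, 7] == 1

    def test_convex_label_unchanged(self):
        grid = np.zeros((9, 15, 15), dtype=np.int32)
        grid[2:7, 3:12, 3:12] = 1
        out = close_labels(CellLabels(grid, ISO), radius=2)
        assert np.array_equal(out.grid, grid)

    def test_adjacent_labels_never_merge(self):
        from scipy import ndimage

        grid = np.zeros((7, 15, 24), dtype=np.int32)
        grid[2:5, 4:11, 2:10] = 1
        grid[2:5, 4:11, 11:21] = 2  # 1 voxel gap at x=10
        out = close_labels(CellLabels(grid, ISO), radius=4)
        assert set(np.unique(out.grid)) == {0, 1, 2}
        for lab in (1, 2):
            _, n = ndimage.label(out.grid == lab, structure=np.ones((3, 3, 3)))
            assert n == 1
        # no voxel carries both labels: contested voxels went to the nearer one
        assert ((out.grid == 1) & (out.grid == 2)).sum() == 0


class TestMeasureCells:
    def test_box_volume_arithmetic(self):
        grid = np.zeros((8, 16, 16), dtype=np.int32)
        grid[1:6, 2:12, 3:13] = 1  # 5 x 10 x 10 = 500 voxels
        (m,) = measure_cells(CellLabels(grid, ANISO))
        assert m.volume_um3 == pytest.approx(500 * 0.104 * 0.104 * 0.72, abs=1e-9)
        assert m.volume_um3 == pytest.approx(3.8937, abs=1e-4)

    def test_two_voxels_along_z(self):
        grid = np.zeros((4, 4, 4), dtype=np.int32)
        grid[1:3, 2, 2] = 1
        (m,) = measure_cells(CellLabels(grid, ANISO))
        assert m.feret_um == pytest.approx(0.72, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_feret_equals_allpairs_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        grid = np.zeros((8, 14, 14), dtype=np.int32)
        # random blob: dilated random points
        pts = rng.integers((1, 2, 2), (7, 12, 12), size=(12, 3))
        grid[pts[:, 0], pts[:, 1], pts[:, 2]] = 1
        from scipy import ndimage

        grid = ndimage.binary_dilation(grid.astype(bool), iterations=1).astype(np.int32)
        (m,) = measure_cells(CellLabels(grid, ANISO))
        coords = np.argwhere(grid)[:, ::-1] * np.array(ANISO.xyz)
        assert m.feret_um == pytest.approx(pdist(coords).max(), abs=1e-9)

    def test_translation_invariance(self):
        grid = np.zeros((10, 20, 20), dtype=np.int32)
        grid[2:5, 3:9, 4:12] = 1
        (a,) = measure_cells(CellLabels(grid, ISO))
        (b,) = measure_cells(CellLabels(np.roll(grid, (3, 5, 6), axis=(0, 1, 2)), ISO))
        assert a.volume_um3 == b.volume_um3
        assert a.feret_um == pytest.approx(b.feret_um, abs=1e-9)

    def test_missing_label_errors(self):
        grid = np.zeros((4, 6, 6), dtype=np.int32)
        grid[1, 2, 2] = 1
        with pytest.raises(ValueError):
            measure_cells(CellLabels(grid, ISO), ids=[5])


class TestExtract:
    def _setup(self):
        rng = np.random.default_rng(3)
        mito = ImageStack(rng.random((8, 20, 20)).astype(np.float32), ISO)
        grid = np.zeros((8, 20, 20), dtype=np.int32)
        grid[2:6, 5:15, 5:15] = 1
        return mito, CellLabels(grid, ISO)

    def test_inside_voxels_copied_exactly(self):
        mito, labels = self._setup()
        out = extract_cell_stack(mito, labels, 1, NoiseModel(0.1, 0.02, seed=9))
        inside = labels.grid == 1
        assert np.array_equal(out.voxels[inside], mito.voxels[inside])

    def test_outside_noise_statistics(self):
        mito, labels = self._setup()
        noise = NoiseModel(0.4, 0.05, seed=9)
        out = extract_cell_stack(mito, labels, 1, noise)
        outside = labels.grid != 1
        n = outside.sum()
        assert abs(out.voxels[outside].mean() - noise.mean) < 3 * noise.sd / np.sqrt(n)

    def test_reproducible_given_seed(self):
        mito, labels = self._setup()
        a = extract_cell_stack(mito, labels, 1, NoiseModel(0.2, 0.05, seed=4))
        b = extract_cell_stack(mito, labels, 1, NoiseModel(0.2, 0.05, seed=4))
        assert np.array_equal(a.voxels, b.voxels)

    def test_sd_zero_constant_fill_warns(self, caplog):
        mito, labels = self._setup()
        with caplog.at_level("WARNING", logger="mitoquant.cells"):
            out = extract_cell_stack(mito, labels, 1, NoiseModel(0.0, 0.0, seed=1))
        assert np.all(out.voxels[labels.grid != 1] == 0)
        assert any("degrade" in r.message for r in caplog.records)

    def test_missing_cell_id(self):
        mito, labels = self._setup()
        with pytest.raises(ValueError):
            extract_cell_stack(mito, labels, 7, NoiseModel(0, 0))

    def test_auto_noise_estimate_recovers_background(self):
        rng = np.random.default_rng(8)
        bg = np.clip(rng.normal(0.3, 0.05, size=(10, 40, 40)), 0, None)
        bg[4:6, 10:30, 10:30] += 4.0  # sparse bright "signal"
        est = estimate_background_noise(ImageStack(bg, ISO))
        assert est.mean == pytest.approx(0.3, rel=0.25)
        assert est.sd <= 0.06
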