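import numpy as np
import pytest

from mtalign.circstats import fit_axial_von_mises
from mtalign.imaging import (
    cell_direction_histogram,
    cells_to_table,
    fourier_directionality,
    max_project,
    quantify_cells,
    quantify_field,
    quantify_frames,
    sobel_5x5,
    stretch_contrast,
)
from mtalign.synthetic import generate_cell_field, generate_line_image


class TestMaxProject:
    def test_single_slice_identity(self, rng):
        img = rng.uniform(size=(1, 20, 20))
        assert np.array_equal(max_project(img), img[0])

    def test_disjoint_spots_union(self):
        stack = np.zeros((2, 10, 10))
        stack[0, 2, 2] = 1.0
        stack[1, 7, 7] = 2.0
        proj = max_project(stack)
        assert proj[2, 2] == 1.0 and proj[7, 7] == 2.0

    def test_matches_elementwise_oracle(self, rng):
        stack = rng.uniform(size=(5, 16, 16))
        expected = np.maximum.reduce([stack[i] for i in range(5)])
        assert np.array_equal(max_project(stack), expected)


class TestStretchContrast:
    def test_constant_warns_and_passes_through(self):
        img = np.full((10, 10), 7.0)
        with pytest.warns(UserWarning):
            out = stretch_contrast(img)
        assert np.array_equal(out, img)

    def test_percentile_oracle(self):
        img = np.arange(1000.0).reshape(20, 50)
        out = stretch_contrast(img, clip=0.005)
        lo = np.quantile(img, 0.005)
        assert (out[img <= lo] == 0).all()
        hi = np.quantile(img, 0.995)
        assert (out[img >= hi] == 1).all()
        mid = (img > lo) & (img < hi)
        assert np.allclose(out[mid], (img[mid] - lo) / (hi - lo))

    def test_near_idempotent(self, rng):
        img = rng.uniform(size=(50, 50))
        once = stretch_contrast(img)
        twice = stretch_contrast(once)
        assert np.allclose(once, twice, atol=0.02)


class TestSobel:
    def test_constant_image(self):
        f = sobel_5x5(np.full((12, 12), 3.0))
        assert np.allclose(f.magnitude, 0.0)

    def test_linear_ramp_along_x(self):
        x = np.tile(np.arange(32.0), (32, 1))
        f = sobel_5x5(x)
        inner = (slice(4, -4), slice(4, -4))
        assert np.allclose(f.gy[inner], 0.0)
        assert np.allclose(f.gx[inner], f.gx[inner][0, 0])
        assert f.gx[inner][0, 0] > 0
        assert np.allclose(f.direction[inner], 0.0)

    def test_three_four_five(self):
        # ramp 3 per column-step and 4 per row-step: M = 5 * unit response,
        # direction atan2(-4, 3) mod 180 = 126.87 (y-up)
        yy, xx = np.mgrid[0:32, 0:32]
        img = 3.0 * xx + 4.0 * yy
        f = sobel_5x5(img)
        inner = (slice(4, -4), slice(4, -4))
        unit = sobel_5x5(np.tile(np.arange(32.0), (32, 1))).gx[8, 8]
        assert f.magnitude[inner][0, 0] == pytest.approx(5 * unit)
        assert f.direction[inner][0, 0] == pytest.approx(np.degrees(np.arctan2(-4, 3)) % 180, abs=1e-9)


class TestDirectionHistogram:
    def test_vertical_stripes_point_at_90(self):
        img = np.zeros((64, 64))
        img[:, ::6] = 1.0
        hist = cell_direction_histogram(sobel_5x5(img), np.ones((64, 64), bool))
        assert fit_axial_von_mises(hist).mu == pytest.approx(90.0, abs=1.0)

    def test_normalized(self, rng):
        img = rng.uniform(size=(64, 64))
        hist = cell_direction_histogram(sobel_5x5(img), np.ones((64, 64), bool))
        assert hist.total == pytest.approx(1.0)

    def test_background_mask_is_empty(self, rng):
        img = rng.uniform(size=(64, 64))
        hist = cell_direction_histogram(sobel_5x5(img), np.zeros((64, 64), bool))
        assert hist.total == 0.0
        assert fit_axial_von_mises(hist).sigma == 90.0


class TestQuantifyCells:
    def test_parallel_filaments(self):
        img, mask, _ = generate_line_image(0.9, 0.0, rng_seed=4)
        c = quantify_cells(img, mask)[0]
        assert c.mtsd < 10.0
        assert c.mtdev < 5.0
        assert c.included

    def test_uniform_angles_are_unaligned(self):
        rng = np.random.default_rng(0)
        img, mask, _ = generate_line_image(0.3, 1e6, rng_seed=5)  # huge sigma wraps ~uniform
        c = quantify_cells(img, mask)[0]
        assert c.mtsd > 60.0

    def test_two_identical_cells(self):
        img1, mask1, _ = generate_line_image(0.8, 25.0, img_size=128, rng_seed=6)
        field = np.zeros((128, 280))
        labels = np.zeros((128, 280), dtype=np.uint16)
        field[:, :128] = img1
        field[:, 140:268] = img1
        labels[:, :128] = mask1
        labels[:, 140:268][mask1 > 0] = 2
        tab = cells_to_table(quantify_cells(field, labels))
        assert len(tab) == 2
        for col in ("eccentricity", "mtsd_deg", "mtdev_deg", "n_pixels_used"):
            assert tab[col].iloc[0] == pytest.approx(tab[col].iloc[1], rel=1e-6)

    def test_rotation_by_90_degrees(self):
        img, mask, _ = generate_line_image(0.85, 20.0, rng_seed=7)
        c0 = quantify_cells(img, mask)[0]
        c90 = quantify_cells(np.rot90(img), np.rot90(mask))[0]
        diff = abs(c90.mt_main_direction - (c0.mt_main_direction + 90)) % 180
        assert min(diff, 180 - diff) < 3.0
        assert c90.mtsd == pytest.approx(c0.mtsd, rel=0.05)

    def test_intensity_scale_invariance(self):
        img, mask, _ = generate_line_image(0.8, 30.0, rng_seed=8)
        a = quantify_cells(img, mask)[0]
        b = quantify_cells(img * 37.5, mask)[0]
        assert b.mtsd == pytest.approx(a.mtsd, rel=1e-6)
        assert b.mt_main_direction == pytest.approx(a.mt_main_direction, rel=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            quantify_cells(np.zeros((10, 10)), np.zeros((12, 12), dtype=int))


class TestQuantifyField:
    def test_single_cell_field_equals_cell_mode(self):
        img, mask, _ = generate_line_image(0.8, 25.0, rng_seed=9)
        cell = quantify_cells(img, mask)[0]
        fld = quantify_field(img, mask > 0)
        assert fld.mtsd == pytest.approx(cell.mtsd, rel=1e-9)

    def test_coherent_field_matches_cell_mean(self):
        img, labels = generate_cell_field(9, orientation_sigma_deg=0.0, rng_seed=10)
        cells = [c for c in quantify_cells(img, labels) if c.included]
        fld = quantify_field(img)
        mean_cell = np.mean([c.mtsd for c in cells])
        assert fld.mtsd == pytest.approx(mean_cell, rel=0.15)

    def test_dispersed_field_exceeds_cell_mean(self):
        img, labels = generate_cell_field(9, orientation_sigma_deg=40.0, rng_seed=11)
        cells = [c for c in quantify_cells(img, labels) if c.included]
        fld = quantify_field(img)
        assert fld.mtsd >= np.mean([c.mtsd for c in cells])


class TestQuantifyFrames:
    def test_per_frame_rows(self):
        img, mask, _ = generate_line_image(0.8, 25.0, img_size=96, rng_seed=12)
        stack = np.stack([img, img * 1.5, img])
        tab = quantify_frames(stack, mask)
        assert sorted(tab.frame.unique()) == [0, 1, 2]
        assert tab.groupby("frame").size().eq(1).all()
        # scale invariance across frames
        assert tab.mtsd_deg.std() < 1e-6


class TestFourier:
    def test_vertical_stripes(self):
        img = np.zeros((128, 128))
        img[:, ::8] = 1.0
        hist = fourier_directionality(img)
        assert fit_axial_von_mises(hist).mu == pytest.approx(90.0, abs=2.0)

    def test_white_noise_near_uniform(self):
        ratios = []
        for seed in range(10):
            img = np.random.default_rng(seed).uniform(size=(256, 256))
            h = fourier_directionality(img)
            ratios.append(h.weights.max() / h.weights.min())
        assert max(ratios) < 2.0

    def test_agrees_with_sobel_on_synthetic_lines(self):
        diffs = []
        for seed in range(5):
            img, mask, _ = generate_line_image(0.8, 30.0, rng_seed=seed)
            sob = quantify_cells(img, mask)[0].mtsd
            fou = fit_axial_von_mises(fourier_directionality(img)).sigma
            diffs.append(abs(sob - fou) / sob)
        assert np.mean(diffs) < 0.15
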