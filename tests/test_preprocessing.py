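"""Background modelling, border replacement, cropping, smoothing, sample mask."""

import numpy as np
import pytest
from scipy import ndimage

import oracles
from episeg.preprocessing import (
    BackgroundModel,
    compute_background_threshold,
    crop_to_content,
    make_sample_mask,
    mean_filter,
    remove_small_components,
    replace_border_black,
)


def uniform_rgb(h, w, rgb):
    return np.tile(np.asarray(rgb, dtype=np.uint8), (h, w, 1))


class TestBackgroundThreshold:
    def test_uniform_image_mode(self):
        model = compute_background_threshold(uniform_rgb(8, 8, (200, 200, 200)))
        assert model.bg_thresh == 600

    def test_black_pixels_excluded_from_mode(self):
        img = uniform_rgb(10, 10, (250, 250, 250))
        img[:1, :] = 0  # 10% black
        assert compute_background_threshold(img).bg_thresh == 750

    def test_matches_exhaustive_histogram_oracle(self):
        rng = np.random.default_rng(42)
        img = rng.integers(100, 111, size=(64, 64, 3)).astype(np.uint8)
        model = compute_background_threshold(img)
        assert model.bg_thresh == oracles.mode_of_nonzero_composite(img)

    @pytest.mark.parametrize("n_black", [1, 50, 500])
    def test_inserting_black_pixels_never_shifts_mode(self, n_black):
        rng = np.random.default_rng(7)
        img = rng.integers(180, 256, size=(40, 40, 3)).astype(np.uint8)
        base = compute_background_threshold(img).bg_thresh
        n_rows = -(-n_black // img.shape[1])  # append rows of pure black
        padded = np.vstack([img, np.zeros((n_rows, img.shape[1], 3), dtype=np.uint8)])
        assert compute_background_threshold(padded).bg_thresh == base

    def test_all_black_image_rejected(self):
        with pytest.raises(ValueError, match="non-black"):
            compute_background_threshold(np.zeros((5, 5, 3), dtype=np.uint8))

    def test_border_fill_matches_mode_pixels(self):
        img = uniform_rgb(8, 8, (240, 238, 242))
        model = compute_background_threshold(img)
        assert model.border_fill_rgb == (240, 238, 242)

    def test_alpha_channel_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            compute_background_threshold(np.zeros((5, 5, 4), dtype=np.uint8))


class TestReplaceBorderBlack:
    def test_noop_without_black_pixels(self):
        img = uniform_rgb(6, 6, (10, 20, 30))
        model = BackgroundModel(bg_thresh=60, offset=1.0, border_fill_rgb=(9, 9, 9))
        assert np.array_equal(replace_border_black(img, model), img)

    def test_black_columns_replaced_by_background(self):
        img = uniform_rgb(20, 20, (250, 250, 250))
        img[:, :5] = 0
        model = compute_background_threshold(img)
        out = replace_border_black(img, model)
        assert np.array_equal(out[:, :5], uniform_rgb(20, 5, (250, 250, 250)))

    def test_only_black_positions_change(self):
        rng = np.random.default_rng(3)
        img = rng.integers(1, 256, size=(30, 30, 3)).astype(np.uint8)
        black = rng.random((30, 30)) < 0.1
        img[black] = 0
        model = compute_background_threshold(img)
        out = replace_border_black(img, model)
        k = out.astype(int).sum(axis=2)
        assert (k > 0).all()
        changed = (out != img).any(axis=2)
        assert np.array_equal(changed, black)


class TestCropToContent:
    def make_bordered(self):
        img = uniform_rgb(120, 120, (250, 250, 250))
        img[30:90, 40:100] = (40, 30, 50)  # dark tissue block
        return img

    def test_no_crop_when_all_rows_pass(self):
        img = uniform_rgb(10, 10, (100, 100, 100))
        model = BackgroundModel(bg_thresh=300, offset=1.0)
        out, box = crop_to_content(img, model)
        assert box == (0, 10, 0, 10)
        assert np.array_equal(out, img)

    def test_matches_bruteforce_row_col_sums(self):
        img = self.make_bordered()
        model = compute_background_threshold(img)
        _, box = crop_to_content(img, model)
        k = img.astype(np.int64).sum(axis=2)
        m, n = k.shape
        rows = [i for i in range(m) if k[i].sum() >= model.bg_thresh * n]
        cols = [j for j in range(n) if k[:, j].sum() >= model.bg_thresh * m]
        assert box == (rows[0], rows[-1] + 1, cols[0], cols[-1] + 1)

    def test_idempotent(self):
        img = self.make_bordered()
        model = compute_background_threshold(img)
        once, box1 = crop_to_content(img, model)
        twice, box2 = crop_to_content(once, model)
        assert np.array_equal(once, twice)
        assert box2 == (0, once.shape[0], 0, once.shape[1])

    def test_crop_box_maps_back_losslessly(self):
        img = self.make_bordered()
        model = compute_background_threshold(img)
        cropped, (r0, r1, c0, c1) = crop_to_content(img, model)
        assert np.array_equal(img[r0:r1, c0:c1], cropped)

    def test_all_background_rejected(self):
        img = uniform_rgb(10, 10, (100, 100, 100))  # K = 300 everywhere
        model = BackgroundModel(bg_thresh=600, offset=1.0)
        with pytest.raises(ValueError, match="no sample content"):
            crop_to_content(img, model)


class TestMeanFilter:
    def test_constant_image_unchanged(self):
        img = np.full((15, 15), 3.7)
        assert np.allclose(mean_filter(img, 5), img)

    def test_impulse_response_is_kernel(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        out = mean_filter(img, 3)
        assert np.allclose(out[3:6, 3:6], 1 / 9)
        assert out[0, 0] == 0

    @pytest.mark.parametrize("size", [3, 5])
    def test_interior_matches_nested_loop_oracle(self, size):
        rng = np.random.default_rng(11)
        img = rng.random((11, 11))
        out = mean_filter(img, size)
        expected = oracles.mean_filter_interior(img, size)
        interior = ~np.isnan(expected)
        assert np.allclose(out[interior], expected[interior], atol=1e-9)

    def test_multichannel_filtered_per_channel(self):
        rng = np.random.default_rng(5)
        img = rng.random((11, 11, 3))
        out = mean_filter(img, 3)
        for c in range(3):
            assert np.allclose(out[..., c], mean_filter(img[..., c], 3))

    @pytest.mark.parametrize("size", [0, 2, 4])
    def test_even_or_nonpositive_size_rejected(self, size):
        with pytest.raises(ValueError):
            mean_filter(np.zeros((5, 5)), size)


class TestSampleMask:
    def tissue_image(self, h=400, w=400, block=(100, 300, 100, 300)):
        img = uniform_rgb(h, w, (250, 250, 250))
        r0, r1, c0, c1 = block
        img[r0:r1, c0:c1] = (60, 40, 70)
        return img

    def test_covers_known_block_geometry(self):
        # The mask must contain the dark block and stay within the block
        # dilated by the smoothing half-window (the only blur source).
        img = self.tissue_image()
        model = compute_background_threshold(img)
        mask = make_sample_mask(img, model, smooth_size=29, min_object_px=5000)
        truth = np.zeros((400, 400), dtype=bool)
        truth[100:300, 100:300] = True
        halo = np.zeros_like(truth)
        halo[100 - 15 : 300 + 15, 100 - 15 : 300 + 15] = True
        assert mask[truth].all()
        assert halo[mask].all()
        jaccard = (mask & truth).sum() / (mask | truth).sum()
        assert jaccard >= 200**2 / 230**2  # worst case of the halo bound

    def test_internal_hole_is_filled(self):
        img = self.tissue_image()
        img[150:200, 150:200] = (250, 250, 250)  # white hole inside tissue
        model = compute_background_threshold(img)
        mask = make_sample_mask(img, model, min_object_px=5000)
        assert mask[150:200, 150:200].all()

    def test_small_component_removed_large_kept(self):
        img = uniform_rgb(600, 600, (250, 250, 250))
        img[50:250, 50:200] = (60, 40, 70)    # 30,000 px
        img[400:500, 400:500] = (60, 40, 70)  # 10,000 px
        model = compute_background_threshold(img)
        mask = make_sample_mask(img, model, smooth_size=1, min_object_px=25000)
        assert mask[100:200, 100:150].all()
        assert not mask[400:500, 400:500].any()

    def test_mask_is_binary_holefree_and_filtered(self):
        img = self.tissue_image()
        img[150:200, 150:200] = (250, 250, 250)
        model = compute_background_threshold(img)
        mask = make_sample_mask(img, model, min_object_px=5000)
        assert mask.dtype == bool
        # no enclosed background component (4-connectivity)
        assert np.array_equal(ndimage.binary_fill_holes(mask), mask)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        sizes = np.bincount(labels.ravel())[1:]
        assert (sizes >= 5000).all()

    def test_background_only_image_rejected(self):
        img = uniform_rgb(100, 100, (250, 250, 250))
        model = compute_background_threshold(img)
        with pytest.raises(ValueError, match="no tissue"):
            make_sample_mask(img, model, min_object_px=100)


def test_remove_small_components_threshold_is_strict():
    mask = np.zeros((20, 20), dtype=bool)
    mask[0:2, 0:2] = True   # 4 px
    mask[10:13, 10:13] = True  # 9 px
    out = remove_small_components(mask, 9)
    assert not out[0:2, 0:2].any()
    assert out[10:13, 10:13].all()
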