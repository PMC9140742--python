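import numpy as np
import pytest
from PIL import Image
from skimage import color as skcolor

from pupilkit import images


def _save(tmp_path, arr, name="img.png"):
    path = tmp_path / name
    Image.fromarray(arr).save(path)
    return path


class TestLoadAndResize:
    def test_identity_passthrough(self, tmp_path, rng):
        arr = rng.integers(0, 256, size=(250, 333, 3), dtype=np.uint8)
        out = images.load_and_resize(_save(tmp_path, arr))
        np.testing.assert_array_equal(out, arr)

    def test_downscale_dimensions(self, tmp_path, rng):
        arr = rng.integers(0, 256, size=(500, 666, 3), dtype=np.uint8)
        out = images.load_and_resize(_save(tmp_path, arr))
        assert out.shape == (250, 333, 3)

    def test_missing_file_raises_with_path(self, tmp_path):
        with pytest.raises(OSError, match="nope.png"):
            images.load_and_resize(tmp_path / "nope.png")

    def test_corrupt_file_raises(self, tmp_path):
        path = tmp_path / "bad.png"
        path.write_bytes(b"this is not an image")
        with pytest.raises(OSError, match="bad.png"):
            images.load_and_resize(path)


class TestEnhanceExposure:
    def test_factor_one_is_identity(self, rng):
        img = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        np.testing.assert_array_equal(images.enhance_exposure(img, 1.0), img)

    @pytest.mark.parametrize("value,factor,expected", [(50, 3.0, 150), (100, 3.0, 255), (85, 3.0, 255)])
    def test_scaling_and_clipping(self, value, factor, expected):
        img = np.full((4, 4, 3), value, dtype=np.uint8)
        assert images.enhance_exposure(img, factor)[0, 0, 0] == expected

    def test_monotone_in_factor(self, rng):
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        lo = images.enhance_exposure(img, 1.5)
        hi = images.enhance_exposure(img, 2.5)
        assert (hi.astype(int) >= lo.astype(int)).all()

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            images.enhance_exposure(np.zeros((4, 4, 3), np.uint8), 0.0)


class TestSlidingMean:
    def test_output_dimensions(self, rng):
        img = rng.integers(0, 256, size=(250, 333, 3), dtype=np.uint8)
        m = images.sliding_mean_3x3(img, "red")
        assert m.values.shape == (248, 331)

    def test_constant_image(self):
        img = np.full((10, 12, 3), 77, dtype=np.uint8)
        m = images.sliding_mean_3x3(img, "green")
        np.testing.assert_allclose(m.values, 77.0)

    def test_single_block_mean(self):
        img = np.zeros((3, 3, 3), dtype=np.uint8)
        img[:, :, 0] = np.arange(1, 10).reshape(3, 3)
        m = images.sliding_mean_3x3(img, "red")
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == pytest.approx(5.0)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            h, w = rng.integers(3, 21, size=2)
            img = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
            m = images.sliding_mean_3x3(img, "blue")
            plane = img[:, :, 2].astype(float)
            oracle = np.empty((h - 2, w - 2))
            for i in range(h - 2):
                for j in range(w - 2):
                    oracle[i, j] = plane[i : i + 3, j : j + 3].mean()
            np.testing.assert_allclose(m.values, oracle, atol=1e-9)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            images.sliding_mean_3x3(np.zeros((2, 5, 3), np.uint8), "red")


class TestRgbToHsv:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((255, 0, 0), (0, 255, 255)),
            ((0, 255, 0), (60, 255, 255)),
            ((0, 0, 255), (120, 255, 255)),
            ((255, 255, 0), (30, 255, 255)),
            ((0, 255, 255), (90, 255, 255)),
            ((255, 0, 255), (150, 255, 255)),
        ],
    )
    def test_primary_and_secondary_hues(self, rgb, expected):
        img = np.array([[rgb]], dtype=np.uint8)
        assert tuple(images.rgb_to_hsv(img)[0, 0]) == expected

    def test_gray_pixels_have_zero_saturation(self):
        img = np.stack([np.arange(256, dtype=np.uint8)] * 3, axis=-1)[None]
        hsv = images.rgb_to_hsv(img)
        assert (hsv[..., 1] == 0).all()
        np.testing.assert_array_equal(hsv[..., 2], img[..., 0])

    def test_value_is_channel_maximum(self, rng):
        img = rng.integers(0, 256, size=(20, 20, 3), dtype=np.uint8)
        hsv = images.rgb_to_hsv(img)
        np.testing.assert_array_equal(hsv[..., 2], img.max(axis=-1))

    def test_agrees_with_skimage(self, rng):
        img = rng.integers(0, 256, size=(30, 30, 3), dtype=np.uint8)
        ours = images.rgb_to_hsv(img).astype(float)
        ref = skcolor.rgb2hsv(img)
        np.testing.assert_allclose(ours[..., 1], ref[..., 1] * 255, atol=1.0)
        np.testing.assert_allclose(ours[..., 2], ref[..., 2] * 255, atol=1.0)
        # hue is circular in [0, 180)
        dh = np.abs(ours[..., 0] - ref[..., 0] * 180)
        np.testing.assert_array_less(np.minimum(dh, 180 - dh), 1.0)


class TestGrayscales:
    def test_worked_micro_example(self):
        img = np.array([[[100, 50, 200]]], dtype=np.uint8)
        assert images.grayscale_standard(img)[0, 0] == 82
        assert images.grayscale_blue_weighted(img)[0, 0] == 170

    def test_white_and_black(self):
        white = np.full((2, 2, 3), 255, np.uint8)
        black = np.zeros((2, 2, 3), np.uint8)
        for fn in (images.grayscale_standard, images.grayscale_blue_weighted):
            assert (fn(white) == 255).all()
            assert (fn(black) == 0).all()

    def test_green_ignored_by_blue_weighted(self):
        img = np.array([[[0, 255, 0]]], dtype=np.uint8)
        assert images.grayscale_blue_weighted(img)[0, 0] == 0

    def test_bounded(self, rng):
        img = rng.integers(0, 256, size=(25, 25, 3), dtype=np.uint8)
        for fn in (images.grayscale_standard, images.grayscale_blue_weighted):
            g = fn(img)
            assert g.dtype == np.uint8 and g.min() >= 0 and g.max() <= 255


class TestEqualizeHistogram:
    def test_constant_image_unchanged(self):
        img = np.full((10, 10), 93, np.uint8)
        np.testing.assert_array_equal(images.equalize_histogram(img), img)

    def test_two_level_cdf_oracle(self):
        # 25% at level 10, 75% at level 200: CDF mapping sends the lower
        # level to 0 and the upper to 255, preserving rank
        img = np.full((10, 10), 200, np.uint8)
        img[:5, :5] = 10
        out = images.equalize_histogram(img)
        assert set(np.unique(out)) == {0, 255}
        assert (out[:5, :5] == 0).all()

    def test_uniform_histogram_nearly_unchanged(self):
        img = np.tile(np.arange(256, dtype=np.uint8), (4, 1))
        out = images.equalize_histogram(img)
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 2

    def test_output_in_range(self, rng):
        img = rng.integers(30, 200, size=(40, 40), dtype=np.uint8)
        out = images.equalize_histogram(img)
        assert out.min() >= 0 and out.max() <= 255


class TestGaussianBlur:
    def test_constant_unchanged(self):
        img = np.full((15, 15), 120, np.uint8)
        np.testing.assert_array_equal(images.gaussian_blur(img, 5), img)

    def test_kernel_one_is_identity(self, rng):
        img = rng.integers(0, 256, size=(12, 12), dtype=np.uint8)
        np.testing.assert_array_equal(images.gaussian_blur(img, 1), img)

    def test_single_pixel_spreads_symmetrically(self):
        img = np.zeros((11, 11), np.uint8)
        img[5, 5] = 255
        out = images.gaussian_blur(img, 5).astype(int)
        assert out[5, 5] < 255
        np.testing.assert_array_equal(out, out[::-1, :])
        np.testing.assert_array_equal(out, out[:, ::-1])
        assert abs(int(out.sum()) - 255) <= 10  # mass conserved within rounding

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            images.gaussian_blur(np.zeros((8, 8), np.uint8), 4)
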