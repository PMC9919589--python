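"""Unit tests for image I/O and the simplified MSRCR enhancer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from seepvision.imaging import (
    DimensionError,
    ImageReadError,
    ImageRGB,
    RetinexParams,
    channel_stats,
    msr_prefilter,
    msrcr_enhance,
    read_image,
    write_image,
)

from .conftest import random_image


def msrcr_pixel_oracle(pixels: np.ndarray, dyn: float) -> np.ndarray:
    """Brute-force per-pixel enhancement: explicit loops, scalar math."""
    h, w, _ = pixels.shape
    out = np.empty_like(pixels)
    for c in range(3):
        ch = pixels[:, :, c]
        mean = ch.sum() / ch.size
        sigma = np.sqrt(((ch - mean) ** 2).sum() / ch.size)
        lo, hi = mean - dyn * sigma, mean + dyn * sigma
        for i in range(h):
            for j in range(w):
                v = ch[i, j]
                if hi == lo:
                    y = v
                else:
                    y = (v - lo) / (hi - lo) * 255.0
                y = min(max(y, 0.0), 255.0)
                out[i, j, c] = np.floor(y + 0.5)
    return out


class TestReadWrite:
    def test_rgb_round_trip(self, tmp_path):
        arr = np.full((8, 8, 3), (10, 20, 30), dtype=np.uint8)
        p = tmp_path / "c.png"
        Image.fromarray(arr).save(p)
        img = read_image(p)
        assert img.pixels.shape == (8, 8, 3)
        assert np.array_equal(img.pixels, arr.astype(np.float64))

    def test_grayscale_replicated(self, tmp_path):
        p = tmp_path / "g.png"
        Image.fromarray(np.full((8, 8), 77, dtype=np.uint8), mode="L").save(p)
        img = read_image(p)
        assert np.all(img.pixels == 77)
        assert img.pixels.shape == (8, 8, 3)

    def test_rgba_alpha_dropped(self, tmp_path):
        arr = np.zeros((8, 8, 4), dtype=np.uint8)
        arr[..., :3] = (5, 6, 7)
        arr[..., 3] = 128
        p = tmp_path / "a.png"
        Image.fromarray(arr, mode="RGBA").save(p)
        img = read_image(p)
        assert img.pixels.shape == (8, 8, 3)

    def test_corrupt_file_raises_io(self, tmp_path):
        p = tmp_path / "fake.png"
        p.write_text("this is not an image")
        with pytest.raises(ImageReadError, match="fake.png"):
            read_image(p)

    def test_too_small_raises_dimension(self, tmp_path):
        p = tmp_path / "tiny.png"
        Image.fromarray(np.zeros((4, 4, 3), dtype=np.uint8)).save(p)
        with pytest.raises(DimensionError):
            read_image(p)

    def test_write_read_identity(self, tmp_path, rng):
        img = random_image(rng)
        p = tmp_path / "out.png"
        write_image(img, p)
        assert np.array_equal(read_image(p).pixels, img.pixels)


class TestChannelStats:
    def test_constant_image(self):
        img = ImageRGB(np.full((8, 8, 3), 100.0))
        s = channel_stats(img, dyn=2.0)
        assert np.allclose(s.mean, 100) and np.allclose(s.var, 0)
        assert np.allclose(s.min_bound, 100) and np.allclose(s.max_bound, 100)

    def test_two_value_channel_hand_oracle(self):
        # channel of {10, 20} in equal proportion: mean 15, population sigma 5
        px = np.full((8, 8, 3), 15.0)
        px[:4, :, 0] = 10.0
        px[4:, :, 0] = 20.0
        s = channel_stats(ImageRGB(px), dyn=1.0)
        assert s.mean[0] == 15.0
        assert s.var[0] == 5.0
        assert s.min_bound[0] == 10.0 and s.max_bound[0] == 20.0

    def test_bounds_are_mean_plus_minus_dyn_sigma(self, rng):
        img = random_image(rng)
        for dyn in (0.4, 2.0, 6.0):
            s = channel_stats(img, dyn)
            assert np.allclose(s.max_bound - s.min_bound, 2 * dyn * s.var)
            assert np.allclose((s.max_bound + s.min_bound) / 2, s.mean)

    def test_invalid_dyn_rejected(self, rng):
        with pytest.raises(ValueError):
            channel_stats(random_image(rng), dyn=0.0)


def _stats_image(values: list[float]) -> np.ndarray:
    """Channel-0 holds the given values; total pixel count 16 (4x4)."""
    assert len(values) <= 16
    ch = np.array(values + [128.0] * (16 - len(values))).reshape(4, 4)
    px = np.zeros((4, 4, 3))
    px[:, :, 0] = ch
    return px


class TestMsrcrEnhance:
    def test_hand_computed_stretch_values(self):
        # Construct a channel with mean exactly 128 and sigma exactly 32 that
        # contains the probe values 64, 128 and 200, by solving for two
        # balancing values x, y with x + y - 256 = -8 and
        # (x-128)^2 + (y-128)^2 = 16*1024 - 64^2 - 72^2.
        rem = 16 * 32.0**2 - 64.0**2 - 72.0**2
        s = -8.0
        disc = np.sqrt(2 * rem - s * s)
        x = 128 + (s + disc) / 2
        y = 128 + (s - disc) / 2
        px = _stats_image([64.0, 200.0, 128.0, x, y])
        ch = px[:, :, 0]
        assert np.isclose(ch.mean(), 128.0) and np.isclose(ch.std(), 32.0)
        out = msrcr_enhance(ImageRGB(px), RetinexParams(dyn=2.0))
        flat_in = ch.ravel()
        flat_out = out.pixels[:, :, 0].ravel()
        # Min=64, Max=192: 128 -> 127.5 -> 128; 64 -> 0; 200 -> 270.9 -> 255
        assert flat_out[list(flat_in).index(128.0)] == 128.0
        assert flat_out[list(flat_in).index(64.0)] == 0.0
        assert flat_out[list(flat_in).index(200.0)] == 255.0

    def test_constant_image_fixed_point(self):
        img = ImageRGB(np.full((16, 16, 3), 93.0))
        out = msrcr_enhance(img, RetinexParams(dyn=2.0))
        assert np.array_equal(out.pixels, img.pixels)

    @pytest.mark.parametrize("dyn", [0.4, 1.0, 2.0, 6.0])
    def test_matches_per_pixel_oracle(self, rng, dyn):
        img = random_image(rng)
        out = msrcr_enhance(img, RetinexParams(dyn=dyn))
        assert np.array_equal(out.pixels, msrcr_pixel_oracle(img.pixels, dyn))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), dyn=st.floats(0.2, 8.0))
    def test_monotone_and_in_range(self, seed, dyn):
        img = random_image(np.random.default_rng(seed), 16, 16)
        out = msrcr_enhance(img, RetinexParams(dyn=dyn))
        assert out.pixels.min() >= 0 and out.pixels.max() <= 255
        for c in range(3):
            order = np.argsort(img.pixels[:, :, c].ravel())
            mapped = out.pixels[:, :, c].ravel()[order]
            assert np.all(np.diff(mapped) >= 0)

    def test_deterministic(self, rng):
        img = random_image(rng)
        p = RetinexParams(dyn=1.4)
        assert np.array_equal(msrcr_enhance(img, p).pixels, msrcr_enhance(img, p).pixels)


class TestMsrPrefilter:
    def test_constant_maps_to_midgray(self):
        img = ImageRGB(np.full((16, 16, 3), 40.0))
        out = msr_prefilter(img, scales=(4.0,))
        assert np.allclose(out.pixels, 127.5)
        # and through the enhancer the stored result is 128
        assert np.all(out.to_uint8() == 128)

    def test_single_scale_matches_direct_convolution(self, rng):
        img = random_image(rng, 16, 16)
        sigma = 3.0
        out = msr_prefilter(img, scales=(sigma,))
        # direct spatial-domain oracle: explicit separable kernel, symmetric pad
        radius = int(4.0 * sigma + 0.5)
        xk = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * (xk / sigma) ** 2)
        kernel /= kernel.sum()
        for c in range(3):
            ch = img.pixels[:, :, c]
            padded = np.pad(ch, radius, mode="symmetric")
            tmp = np.apply_along_axis(
                lambda r: np.convolve(r, kernel, mode="valid"), 0, padded
            )
            surround = np.apply_along_axis(
                lambda r: np.convolve(r, kernel, mode="valid"), 1, tmp
            )
            resp = np.log(ch + 1) - np.log(surround + 1)
            lo, hi = resp.min(), resp.max()
            expect = (resp - lo) / (hi - lo) * 255.0
            assert np.abs(out.pixels[:, :, c] - expect).max() <= 1.0

    def test_multi_scale_is_mean_of_responses(self, rng):
        from scipy.ndimage import gaussian_filter

        img = random_image(rng, 16, 16)
        scales = (2.0, 5.0, 9.0)
        out = msr_prefilter(img, scales=scales)
        for c in range(3):
            ch = img.pixels[:, :, c]
            resps = [
                np.log(ch + 1) - np.log(gaussian_filter(ch, s, mode="reflect") + 1)
                for s in scales
            ]
            resp = sum(resps) / len(resps)
            lo, hi = resp.min(), resp.max()
            assert np.allclose(out.pixels[:, :, c], (resp - lo) / (hi - lo) * 255.0)

    def test_empty_scales_rejected(self, rng):
        with pytest.raises(ValueError):
            msr_prefilter(random_image(rng), scales=())

    def test_prefilter_feeds_enhancer(self, rng):
        img = random_image(rng, 16, 16)
        on = msrcr_enhance(img, RetinexParams(dyn=2.0, msr_prefilter=True, msr_scales=(4.0,)))
        off = msrcr_enhance(img, RetinexParams(dyn=2.0))
        assert not np.array_equal(on.pixels, off.pixels)
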