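import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serialreg.errors import DegenerateStainError, EmptyHistogramError
from serialreg.preprocess import (
    EOSIN_OD,
    HEMATOXYLIN_OD,
    SaturationBounds,
    build_stain_matrix,
    channel_histogram,
    deconvolve,
    default_he_matrix,
    extract_feature_image,
    normalize_image,
    od_to_rgb,
    rgb_to_od,
    saturation_bounds,
    stretch_channel,
)


# ---------------------------------------------------------------- oracles
def brute_force_bounds(hist, p_low, p_high):
    """Independent cumulative-sum loop for the saturation bounds."""
    total = sum(hist)
    x_low = 255
    acc = 0
    for level in range(256):
        acc += hist[level]
        if acc > p_low * total:
            x_low = level
            break
    x_high = 0
    acc = 0
    for level in range(255, -1, -1):
        acc += hist[level]
        if acc > p_high * total:
            x_high = level
            break
    return x_low, max(x_high, x_low)


class TestHistogram:
    def test_constant_image(self):
        h = channel_histogram(np.full((4, 4), 7, dtype=np.uint8))
        assert h[7] == 16 and h.sum() == 16

    def test_extremes(self):
        img = np.array([[0, 0], [255, 255]], dtype=np.uint8)
        h = channel_histogram(img)
        assert h[0] == 2 and h[255] == 2 and h.sum() == 4

    def test_sums_to_pixel_count(self, rng):
        img = rng.integers(0, 256, (31, 17), dtype=np.uint8)
        assert channel_histogram(img).sum() == 31 * 17


class TestSaturationBounds:
    def test_no_saturation(self, rng):
        img = rng.integers(20, 200, (32, 32), dtype=np.uint8)
        h = channel_histogram(img)
        b = saturation_bounds(h, 0.0, 0.0)
        assert b.x_low == img.min() and b.x_high == img.max()

    def test_delta_histogram(self):
        h = np.zeros(256, dtype=int)
        h[100] = 50
        for p in (0.0, 0.01, 0.2):
            b = saturation_bounds(h, p, p)
            assert (b.x_low, b.x_high) == (100, 100)

    def test_uniform_histogram_vs_oracle(self):
        h = np.full(256, 4, dtype=int)  # total 1024
        b = saturation_bounds(h, 0.01, 0.01)
        assert (b.x_low, b.x_high) == brute_force_bounds(h, 0.01, 0.01)

    @given(
        hist=st.lists(st.integers(0, 50), min_size=256, max_size=256),
        p_low=st.floats(0, 0.49),
        p_high=st.floats(0, 0.49),
    )
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence(self, hist, p_low, p_high):
        if sum(hist) == 0:
            with pytest.raises(EmptyHistogramError):
                saturation_bounds(np.array(hist), p_low, p_high)
            return
        b = saturation_bounds(np.array(hist), p_low, p_high)
        assert (b.x_low, b.x_high) == brute_force_bounds(hist, p_low, p_high)

    def test_empty_histogram(self):
        with pytest.raises(EmptyHistogramError, match="empty histogram"):
            saturation_bounds(np.zeros(256, dtype=int), 0.01, 0.01)


class TestStretch:
    def test_identity_bounds(self, rng):
        img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        out = stretch_channel(img, SaturationBounds(0, 255, 0, 0))
        np.testing.assert_array_equal(out, img)

    def test_midpoint_arithmetic(self):
        img = np.full((4, 4), 100, dtype=np.uint8)
        out = stretch_channel(img, SaturationBounds(50, 150, 0, 0))
        assert int(out[0, 0]) == 128  # round(255*50/100)

    def test_per_pixel_oracle(self, rng):
        img = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        b = SaturationBounds(30, 201, 0.01, 0.01)
        out = stretch_channel(img, b)
        for y in range(20):
            for x in range(20):
                want = round(255.0 * (int(img[y, x]) - 30) / (201 - 30))
                assert int(out[y, x]) == min(255, max(0, want))

    def test_constant_channel_maps_to_zero(self):
        img = np.full((8, 8), 99, dtype=np.uint8)
        out = stretch_channel(img, SaturationBounds(99, 99, 0, 0))
        assert out.max() == 0

    @given(a=st.integers(0, 255), b=st.integers(0, 255))
    @settings(max_examples=50, deadline=None)
    def test_monotone(self, a, b):
        lo, hi = min(a, b), max(a, b)
        bounds = SaturationBounds(40, 210, 0, 0)
        img = np.array([[lo, hi]], dtype=np.uint8)
        out = stretch_channel(img, bounds)
        assert out[0, 0] <= out[0, 1]


class TestNormalize:
    def test_full_range_unchanged(self, rng):
        img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        img.flat[0], img.flat[1] = 0, 255
        np.testing.assert_array_equal(normalize_image(img, 0.0, 0.0), img)

    def test_idempotent_once_full_range(self, rng):
        img = rng.integers(50, 100, (32, 32), dtype=np.uint8)
        once = normalize_image(img, 0.0, 0.0)
        twice = normalize_image(once, 0.0, 0.0)
        np.testing.assert_array_equal(once, twice)

    def test_channels_independent(self, rng):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        img[:, :, 0] = rng.integers(100, 121, (32, 32))  # dim red
        img[:, :, 1] = rng.integers(0, 256, (32, 32))
        img[:, :, 2] = rng.integers(0, 256, (32, 32))
        out = normalize_image(img, 0.0, 0.0)
        assert out[:, :, 0].min() == 0 and out[:, :, 0].max() == 255
        red_only = normalize_image(img[:, :, 0], 0.0, 0.0)
        np.testing.assert_array_equal(out[:, :, 0], red_only)

    def test_constant_image_all_zero(self):
        img = np.full((16, 16), 123, dtype=np.uint8)
        assert normalize_image(img).max() == 0


class TestOpticalDensity:
    def test_white_pixel_zero_od(self):
        od = rgb_to_od(np.full((1, 1, 3), 255, dtype=np.uint8))
        np.testing.assert_allclose(od, 0.0)

    def test_scalar_oracle(self):
        od = rgb_to_od(np.full((1, 1, 3), 26, dtype=np.uint8))
        want = -np.log10(26 / 255)
        np.testing.assert_allclose(od[0, 0], [want] * 3, rtol=1e-12)

    def test_zero_clamped(self):
        od = rgb_to_od(np.zeros((1, 1, 3), dtype=np.uint8))
        np.testing.assert_allclose(od[0, 0], -np.log10(1 / 255), rtol=1e-12)
        assert np.all(np.isfinite(od))

    def test_antitone(self, rng):
        a = rng.integers(0, 200, (8, 8, 3), dtype=np.uint8)
        b = (a + 40).astype(np.uint8)  # strictly brighter
        assert np.all(rgb_to_od(b) <= rgb_to_od(a))


class TestStainMatrix:
    def test_orthonormal_input(self):
        m = build_stain_matrix((1, 0, 0), (0, 1, 0))
        np.testing.assert_allclose(m.rows, np.eye(3), atol=1e-12)

    def test_he_defaults_unit_rows(self):
        m = default_he_matrix()
        np.testing.assert_allclose(np.linalg.norm(m.rows, axis=1), 1.0, atol=1e-9)

    def test_parallel_rejected(self):
        with pytest.raises(DegenerateStainError, match="degenerate"):
            build_stain_matrix((0.5, 0.5, 0.1), (1.0, 1.0, 0.2))

    def test_zero_rejected(self):
        with pytest.raises(DegenerateStainError):
            build_stain_matrix((0, 0, 0), (0, 1, 0))


class TestDeconvolve:
    def test_identity_matrix_recovers_od(self, rng):
        m = build_stain_matrix((1, 0, 0), (0, 1, 0))
        img = rng.integers(1, 256, (8, 8, 3), dtype=np.uint8)
        _, conc = deconvolve(img, m)
        np.testing.assert_allclose(conc, rgb_to_od(img), atol=1e-9)

    def test_forward_model_round_trip(self):
        # synthesize a pure stain-1 pixel at amount a: OD = a * row1
        m = default_he_matrix()
        a = 0.7
        od = a * m.rows[0]
        img = od_to_rgb(np.broadcast_to(od, (4, 4, 3)))
        _, conc = deconvolve(img, m)
        np.testing.assert_allclose(conc[..., 0], a, atol=0.02)
        np.testing.assert_allclose(conc[..., 1:], 0.0, atol=0.02)

    def test_white_zero_concentration(self):
        m = default_he_matrix()
        img = np.full((4, 4, 3), 255, dtype=np.uint8)
        _, conc = deconvolve(img, m)
        np.testing.assert_allclose(conc, 0.0, atol=1e-9)

    def test_round_trip_random_concentrations(self, rng):
        # deconvolve(render(C, M), M) recovers C within 8-bit quantization
        m = default_he_matrix()
        c = rng.uniform(0, 0.8, (6, 6, 3))
        od = c @ m.rows  # forward: OD = M^T C per pixel
        img = od_to_rgb(od)
        _, got = deconvolve(img, m)
        assert np.abs(got - c).max() < 0.02 * np.linalg.cond(m.rows.T) + 0.02


class TestFeatureImage:
    def test_grayscale_passthrough(self, texture128):
        f = extract_feature_image(texture128)
        assert f.provenance == "gray_normalized"
        np.testing.assert_array_equal(f.pixels, texture128)

    def test_eosin_blobs_bright(self):
        # eosin-only blobs on white background
        m = default_he_matrix()
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        blob = od_to_rgb(0.9 * m.rows[1])
        img[20:30, 20:30] = blob
        f = extract_feature_image(img, m, "eosin")
        inside = f.pixels[22:28, 22:28].mean()
        outside = f.pixels[40:, 40:].mean()
        assert inside > outside + 100

    def test_pure_hematoxylin_dark_in_eosin(self):
        m = default_he_matrix()
        img = np.full((32, 32, 3), 255, dtype=np.uint8)
        img[8:24, 8:24] = od_to_rgb(0.9 * m.rows[0])
        f = extract_feature_image(img, m, "eosin")
        _, conc = deconvolve(img, m)
        assert np.abs(conc[10:20, 10:20, 1]).max() < 0.05  # eosin amount near zero

    def test_rgb_without_matrix_luminance(self, rng):
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        f = extract_feature_image(img, None)
        assert f.provenance == "luminance"
        assert f.pixels.shape == (16, 16)
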