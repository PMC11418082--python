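"""Forward operator behavior: bicubic dialect, corruptions, composition."""

import numpy as np
import pytest

from latsr import degradation as dg


def reference_bicubic_downscale(img, factor, a=-0.5):
    """Independent direct-convolution Keys-kernel downscale (naive loops)."""

    def kernel(t):
        t = abs(t)
        if t <= 1:
            return (a + 2) * t**3 - (a + 3) * t**2 + 1
        if t < 2:
            return a * t**3 - 5 * a * t**2 + 8 * a * t - 4 * a
        return 0.0

    def fold(j, n):
        j = j % (2 * n)
        return 2 * n - 1 - j if j >= n else j

    C, H, W = img.shape
    h, w = H // factor, W // factor
    out = np.zeros((C, h, w))
    for c in range(C):
        tmp = np.zeros((h, W))
        for i in range(h):
            center = (i + 0.5) * factor - 0.5
            j0 = int(np.ceil(center - 2 * factor))
            j1 = int(np.floor(center + 2 * factor))
            ws = np.array([kernel((j - center) / factor) / factor
                           for j in range(j0, j1 + 1)])
            ws /= ws.sum()
            for k, j in enumerate(range(j0, j1 + 1)):
                tmp[i] += ws[k] * img[c, fold(j, H)]
        for i in range(w):
            center = (i + 0.5) * factor - 0.5
            j0 = int(np.ceil(center - 2 * factor))
            j1 = int(np.floor(center + 2 * factor))
            ws = np.array([kernel((j - center) / factor) / factor
                           for j in range(j0, j1 + 1)])
            ws /= ws.sum()
            for k, j in enumerate(range(j0, j1 + 1)):
                out[c, :, i] += ws[k] * tmp[:, fold(j, W)]
    return out


class TestBicubic:
    def test_factor_one_is_identity(self):
        img = np.random.default_rng(0).uniform(-1, 1, (3, 8, 8))
        np.testing.assert_array_equal(dg.bicubic_downscale(img, 1), img)

    @pytest.mark.parametrize("factor", [2, 4])
    def test_constant_preserved(self, factor):
        img = np.full((2, 16, 16), 0.37)
        out = dg.bicubic_downscale(img, factor)
        np.testing.assert_allclose(out, 0.37, atol=1e-12)

    def test_ramp_matches_direct_convolution_reference(self):
        ramp = np.tile(np.linspace(-1, 1, 8), (8, 1))[None]
        out = dg.bicubic_downscale(ramp, 2)
        ref = reference_bicubic_downscale(ramp, 2)
        assert np.max(np.abs(out - ref)) < 1e-6

    def test_random_image_matches_reference(self):
        img = np.random.default_rng(1).uniform(-1, 1, (2, 16, 16))
        for factor in (2, 4):
            out = dg.bicubic_downscale(img, factor)
            ref = reference_bicubic_downscale(img, factor)
            assert np.max(np.abs(out - ref)) < 1e-6

    def test_linearity(self):
        rng = np.random.default_rng(2)
        x, y = rng.uniform(-1, 1, (1, 16, 16)), rng.uniform(-1, 1, (1, 16, 16))
        lhs = dg.bicubic_downscale(0.3 * x + 0.7 * y, 4)
        rhs = 0.3 * dg.bicubic_downscale(x, 4) + 0.7 * dg.bicubic_downscale(y, 4)
        assert np.max(np.abs(lhs - rhs)) < 1e-8

    def test_non_divisible_raises(self):
        with pytest.raises(ValueError):
            dg.bicubic_downscale(np.zeros((1, 9, 9)), 2)


class TestNoise:
    def test_zero_sigma_identity(self):
        img = np.zeros((1, 8, 8))
        np.testing.assert_array_equal(dg.add_gaussian_noise(img, 0.0, 0), img)

    def test_moments(self):
        img = np.zeros((1, 64, 64))
        out = dg.add_gaussian_noise(img, 0.1, seed=3)
        assert abs(out.std() - 0.1) < 0.01

    def test_deterministic_given_seed(self):
        img = np.zeros((1, 16, 16))
        np.testing.assert_array_equal(dg.add_gaussian_noise(img, 0.2, 7),
                                      dg.add_gaussian_noise(img, 0.2, 7))

    def test_negative_sigma_raises(self):
        with pytest.raises(ValueError):
            dg.add_gaussian_noise(np.zeros((1, 4, 4)), -0.1, 0)

    def test_clipped_to_valid_range(self):
        img = np.ones((1, 32, 32)) * 0.99
        out = dg.add_gaussian_noise(img, 0.5, seed=0)
        assert out.max() <= 1.0 and out.min() >= -1.0


class TestSaltPepper:
    def test_p_zero_identity(self):
        img = np.random.default_rng(0).uniform(-1, 1, (1, 8, 8))
        np.testing.assert_array_equal(dg.add_salt_pepper(img, 0.0, 0), img)

    def test_p_one_saturates(self):
        img = np.zeros((1, 16, 16))
        out = dg.add_salt_pepper(img, 1.0, 0)
        assert np.all(np.isin(out, (-1.0, 1.0)))

    def test_corruption_fraction(self):
        img = np.zeros((1, 128, 128))
        out = dg.add_salt_pepper(img, 0.05, seed=1)
        frac = np.mean(out != 0.0)
        n = img.size
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)

    def test_out_of_range_p(self):
        with pytest.raises(ValueError):
            dg.add_salt_pepper(np.zeros((1, 4, 4)), 1.5, 0)


class TestBlur:
    def test_sigma_zero_identity(self):
        img = np.random.default_rng(0).uniform(-1, 1, (1, 8, 8))
        np.testing.assert_array_equal(dg.gaussian_blur(img, 0.0), img)

    def test_constant_unchanged(self):
        img = np.full((1, 16, 16), -0.4)
        np.testing.assert_allclose(dg.gaussian_blur(img, 1.5), -0.4, atol=1e-12)

    def test_impulse_center_weight(self):
        img = np.zeros((1, 17, 17))
        img[0, 8, 8] = 1.0
        out = dg.gaussian_blur(img, 1.0)
        # independently built normalized discrete 2-D kernel
        r = int(np.ceil(3.0))
        ax = np.arange(-r, r + 1)
        k1 = np.exp(-0.5 * ax**2)
        k1 /= k1.sum()
        k2d = np.outer(k1, k1)
        assert abs(out[0, 8, 8] - k2d.max()) < 1e-12


class TestOperator:
    def test_empty_operator_identity(self):
        img = np.random.default_rng(0).uniform(-1, 1, (3, 8, 8))
        np.testing.assert_array_equal(
            dg.apply_operator(dg.ForwardOperator([]), img), img)

    def test_single_downscale_matches_direct_call(self):
        img = np.random.default_rng(1).uniform(-1, 1, (3, 16, 16))
        op = dg.downscale_operator(2)
        np.testing.assert_array_equal(dg.apply_operator(op, img),
                                      dg.bicubic_downscale(img, 2))

    def test_noop_noise_step(self):
        img = np.random.default_rng(2).uniform(-1, 1, (3, 16, 16))
        op = dg.ForwardOperator([("bicubic_downscale", {"factor": 2}),
                                 ("gaussian_noise", {"sigma": 0.0, "seed": 0})])
        np.testing.assert_array_equal(dg.apply_operator(op, img),
                                      dg.bicubic_downscale(img, 2))

    def test_two_downscales_rejected(self):
        with pytest.raises(ValueError):
            dg.ForwardOperator([("bicubic_downscale", {"factor": 2}),
                                ("bicubic_downscale", {"factor": 2})])

    def test_non_power_of_two_factor_rejected(self):
        with pytest.raises(ValueError):
            dg.downscale_operator(3)

    def test_parse_operator_spec(self):
        op = dg.parse_operator("bicubic:4,gauss:0.05:3,sp:0.02,blur:1.0")
        kinds = [k for k, _ in op.steps]
        assert kinds == ["bicubic_downscale", "gaussian_noise",
                         "salt_pepper", "gaussian_blur"]
        assert op.factor == 4

    def test_outputs_stay_in_range(self):
        img = np.random.default_rng(3).uniform(-1, 1, (3, 32, 32))
        op = dg.parse_operator("bicubic:2,gauss:0.3,sp:0.1")
        out = dg.apply_operator(op, img)
        assert out.min() >= -1.0 and out.max() <= 1.0
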