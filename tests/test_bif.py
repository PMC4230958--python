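"""BIF encoder: grayscale conversion, filter bank, seven-class labeling."""

import numpy as np
import pytest
from conftest import oracle_dtg

from pcmseg.bif import (
    DARK_BLOB,
    DARK_LINE,
    FLAT,
    GRADIENT,
    LIGHT_BLOB,
    LIGHT_LINE,
    SADDLE,
    BifLabelMap,
    EncoderConfig,
    classify_bif,
    dtg_responses,
    multiscale_bif,
    to_grayscale,
)
from pcmseg.errors import InvalidInputError, InvalidParameterError


class TestToGrayscale:
    def test_uniform_rgb_maps_to_same_gray(self):
        img = np.full((8, 8, 3), 0.5)
        out = to_grayscale(img)
        assert out.shape == (8, 8)
        # luminance weights sum to 0.9999
        assert np.allclose(out, 0.5, atol=1e-3)

    def test_pure_red_gives_red_luminance_weight(self):
        img = np.zeros((5, 5, 3))
        img[..., 0] = 1.0
        assert np.allclose(to_grayscale(img), 0.2989)

    def test_single_channel_passthrough(self):
        img = np.linspace(0, 1, 36).reshape(6, 6)
        assert np.array_equal(to_grayscale(img), img)

    def test_uint8_rescaled_by_dtype_range(self):
        img = np.full((4, 4), 255, dtype=np.uint8)
        assert np.allclose(to_grayscale(img), 1.0)

    def test_two_channels_rejected(self):
        with pytest.raises(InvalidInputError):
            to_grayscale(np.zeros((4, 4, 2)))

    def test_nonfinite_rejected(self):
        img = np.ones((4, 4))
        img[0, 0] = np.nan
        with pytest.raises(InvalidInputError):
            to_grayscale(img)


class TestDtgResponses:
    def test_constant_image(self):
        r = dtg_responses(np.full((15, 15), 0.5), sigma=1.4)
        assert np.allclose(r.s00, 0.5, atol=1e-6)
        for g in (r.s10, r.s01, r.s20, r.s11, r.s02):
            assert np.allclose(g, 0.0, atol=1e-6)

    def test_ramp_first_derivative_is_exact(self):
        a = 0.01
        img = a * np.arange(33)[None, :] * np.ones((33, 1))
        r = dtg_responses(img, sigma=2.0)
        interior = (slice(10, 23), slice(10, 23))
        assert np.allclose(r.s10[interior], 2.0 * a, atol=1e-9)
        assert np.allclose(r.s20[interior], 0.0, atol=1e-9)
        assert np.allclose(r.s01[interior], 0.0, atol=1e-9)

    @pytest.mark.parametrize("sigma", [0.7, 1.4])
    def test_matches_direct_convolution_oracle(self, sigma):
        rng = np.random.default_rng(7)
        img = rng.random((11, 11))
        r = dtg_responses(img, sigma)
        for grid, (ox, oy) in zip(
            r.as_tuple(), [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)]
        ):
            ref = oracle_dtg(img, sigma, ox, oy)
            assert np.max(np.abs(grid - ref)) < 1e-8

    def test_invalid_sigma(self):
        with pytest.raises(InvalidParameterError):
            dtg_responses(np.ones((5, 5)), sigma=0.0)


def _spot(sign, s=3.0, n=41):
    """Dark (sign=+1) or light (sign=-1) Gaussian spot on mid-gray."""
    y, x = np.mgrid[:n, :n] - n // 2
    return 0.5 + sign * -0.4 * np.exp(-(x**2 + y**2) / (2 * s**2))


def _ridge(sign, s=3.0, n=41):
    y, x = np.mgrid[:n, :n] - n // 2
    return 0.5 + sign * -0.4 * np.exp(-(x**2) / (2 * s**2))


# (name, image builder, expected center label, matched sigma); the saddle
# needs a larger sigma for its gamma score to clear the flat threshold at
# epsilon = 0.1 while the image stays within [0, 1].
ANALYTIC_CASES = [
    ("constant", lambda n: np.full((n, n), 0.6), FLAT, 3.0),
    ("ramp", lambda n: 0.8 * np.arange(n)[None, :] / n * np.ones((n, 1)), GRADIENT, 3.0),
    ("dark_spot", lambda n: _spot(+1, n=n), DARK_BLOB, 3.0),
    ("light_spot", lambda n: _spot(-1, n=n), LIGHT_BLOB, 3.0),
    ("dark_ridge", lambda n: _ridge(+1, n=n), DARK_LINE, 3.0),
    ("light_ridge", lambda n: _ridge(-1, n=n), LIGHT_LINE, 3.0),
    (
        "saddle",
        lambda n: 0.5
        + 0.5
        * ((np.mgrid[:n, :n][0] - n // 2) * (np.mgrid[:n, :n][1] - n // 2))
        / (n // 2) ** 2,
        SADDLE,
        6.0,
    ),
]


class TestClassifyBif:
    @pytest.mark.parametrize(
        "name,builder,expected,sigma", ANALYTIC_CASES, ids=[c[0] for c in ANALYTIC_CASES]
    )
    def test_each_class_attainable_on_analytic_image(self, name, builder, expected, sigma):
        """Every letter of the 7-class alphabet fires on its canonical image."""
        n = 41
        img = builder(n)
        labels = classify_bif(dtg_responses(img, sigma=sigma), epsilon=0.1).labels
        assert labels[n // 2, n // 2] == expected

    def test_all_zero_image_is_flat_by_tiebreak(self):
        labels = classify_bif(dtg_responses(np.zeros((9, 9)), 1.0), 0.1).labels
        assert np.all(labels == FLAT)

    def test_constant_image_all_flat(self):
        labels = classify_bif(dtg_responses(np.full((9, 9), 0.7), 1.0), 0.1).labels
        assert np.all(labels == FLAT)

    @pytest.mark.parametrize("k", [0.5, 3.0])
    def test_multiplicative_invariance(self, k):
        """All seven scores scale linearly, so labels ignore global gain."""
        rng = np.random.default_rng(3)
        img = rng.random((24, 24))
        base = classify_bif(dtg_responses(img, 1.4), 0.1).labels
        scaled = classify_bif(dtg_responses(k * img, 1.4), 0.1).labels
        assert np.array_equal(base, scaled)

    def test_rotation_consistency(self):
        """Classifying a 90-degree-rotated image rotates the labels."""
        rng = np.random.default_rng(4)
        img = rng.random((32, 32))
        sigma = 1.4
        lab = classify_bif(dtg_responses(img, sigma), 0.1).labels
        lab_rot = classify_bif(dtg_responses(np.rot90(img), sigma), 0.1).labels
        m = int(np.ceil(4 * sigma)) + 1
        inner = (slice(m, -m), slice(m, -m))
        assert np.array_equal(lab_rot[inner], np.rot90(lab)[inner])

    def test_label_range(self):
        rng = np.random.default_rng(5)
        labels = classify_bif(dtg_responses(rng.random((20, 20)), 0.7), 0.1).labels
        assert labels.min() >= 0 and labels.max() <= 6

    def test_shape_mismatch_rejected(self):
        r = dtg_responses(np.ones((8, 8)), 1.0)
        r.s11 = np.zeros((4, 4))
        with pytest.raises(InvalidInputError):
            classify_bif(r, 0.1)


class TestMultiscale:
    def test_default_config_gives_four_maps(self):
        maps = multiscale_bif(np.random.default_rng(0).random((16, 16)))
        assert len(maps) == 4
        assert [m.sigma for m in maps] == [0.7, 1.4, 2.8, 5.6]
        assert all(m.shape == (16, 16) for m in maps)

    def test_single_scale(self):
        maps = multiscale_bif(np.ones((8, 8)), EncoderConfig(scales=(2.0,)))
        assert len(maps) == 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"scales": ()},
            {"scales": (1.0, 0.5)},
            {"scales": (-1.0,)},
            {"epsilon": 0.0},
            {"padding": "bogus"},
        ],
    )
    def test_config_validation(self, kwargs):
        with pytest.raises(InvalidParameterError):
            EncoderConfig(**kwargs)
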