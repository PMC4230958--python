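"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately take the slow, direct route (explicit 2-D
convolution, per-pixel window counting) so they share no code path with
the separable / integral-image implementations they check.
"""

import numpy as np
import pytest


def oracle_dtg(img, sigma, order_x, order_y):
    """Direct (non-separable) 2-D Gaussian-derivative convolution.

    Builds the full 2-D kernel from the closed-form sampled 1-D factors
    and convolves by explicit window products over a mirror-padded image;
    returns the scale-normalized response.
    """
    img = np.asarray(img, dtype=np.float64)
    r = max(1, int(round(4.0 * sigma)))
    x = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g = g / g.sum()

    def k1d(order):
        if order == 0:
            return g
        if order == 1:
            k = (-x / sigma**2) * g
            return k / -(x * k).sum()  # exact unit slope on a ramp
        k = ((x**2 - sigma**2) / sigma**4) * g
        k = k - k.sum() * g  # exact zero on constants
        return k * (2.0 / (x**2 * k).sum())  # exact curvature on x^2

    K = np.outer(k1d(order_y), k1d(order_x))
    Kf = K[::-1, ::-1]  # convolution flips the kernel
    pad = np.pad(img, r, mode="reflect")
    h, w = img.shape
    out = np.empty((h, w))
    for yy in range(h):
        for xx in range(w):
            out[yy, xx] = np.sum(Kf * pad[yy : yy + 2 * r + 1, xx : xx + 2 * r + 1])
    return out * sigma ** (order_x + order_y)


def oracle_local_histograms(labels, window_side, n_classes=7):
    """Naive per-pixel window counts over a mirror-padded label map."""
    labels = np.asarray(labels)
    r = window_side // 2
    pad = np.pad(labels, r, mode="reflect")
    h, w = labels.shape
    out = np.zeros((h, w, n_classes), dtype=np.int64)
    for yy in range(h):
        for xx in range(w):
            win = pad[yy : yy + window_side, xx : xx + window_side]
            out[yy, xx] = np.bincount(win.ravel(), minlength=n_classes)
    return out


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic scene, shared across read-only tests."""
    from pcmseg.synth import SceneParams, generate_scene

    return generate_scene(SceneParams(seed=0))


@pytest.fixture(scope="session")
def trained_on_default_scene(default_scene):
    """Classifier trained on sparse annotations of the default scene."""
    from pcmseg.segmenter import PixelSegmenter
    from pcmseg.synth import annotations_from_truth

    ann = annotations_from_truth(default_scene.truth_mask, seed=0)
    model = PixelSegmenter.from_image(default_scene.image, ann)
    return model, model.fit(seed=0), ann
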