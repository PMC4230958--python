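"""Seven-class basic-image-feature (BIF) encoding at multiple scales.

Phase-contrast micrographs of adherent cultures are textured rather than
intensity-separated: colonies, feeder cells and background differ in the
*local symmetry* of the intensity surface more than in its level.  The BIF
encoder makes that explicit by classifying every pixel into one of seven
local-symmetry classes — flat, gradient (slope), dark blob, light blob,
dark line, light line, saddle — from scale-normalized
derivative-of-Gaussian responses.

At scale ``sigma`` the six responses ``s_ij`` are the image convolved with
a Gaussian derivative of order ``i`` in x (columns) and ``j`` in y (rows),
multiplied by ``sigma**(i+j)`` so that responses are commensurate across
scales.  Writing

    lambda = s20 + s02
    gamma  = sqrt((s20 - s02)**2 + 4*s11**2)

(the trace and eigenvalue spread of the smoothed Hessian), the class of a
pixel is the argmax of the seven scores

    flat        eps * s00
    gradient    2 * sqrt(s10**2 + s01**2)
    dark blob   +lambda
    light blob  -lambda
    dark line   (gamma + lambda) / sqrt(2)
    light line  (gamma - lambda) / sqrt(2)
    saddle      gamma

"Dark"/"light" refer to the object against its surround: a dark spot on a
bright background is a local minimum with positive Laplacian, hence the
``+lambda`` dark-blob score.  ``eps`` is the only free parameter; it
trades the flat class off against the structured ones.  Ties are broken
toward the lowest class index, so an all-zero response field is "flat".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, InvalidParameterError

#: Label values of the seven-class BIF alphabet, in tie-break precedence order.
FLAT, GRADIENT, DARK_BLOB, LIGHT_BLOB, DARK_LINE, LIGHT_LINE, SADDLE = range(7)

BIF_NAMES = (
    "flat",
    "gradient",
    "dark_blob",
    "light_blob",
    "dark_line",
    "light_line",
    "saddle",
)

N_BIF_CLASSES = 7

#: Default scale ladder (Gaussian sigma, px): a geometric doubling sequence.
DEFAULT_SCALES = (0.7, 1.4, 2.8, 5.6)

# ITU-R BT.601 luminance weights; the conversion convention used by the
# common rgb2gray implementations.
_LUMA_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])

_SQRT2 = math.sqrt(2.0)

_VALID_PADDING = ("mirror", "reflect", "nearest", "wrap", "constant")


@dataclass(frozen=True)
class EncoderConfig:
    """Configuration of the multi-scale BIF encoder.

    Parameters
    ----------
    scales
        Strictly increasing Gaussian sigmas in pixels.
    epsilon
        Flat-threshold parameter (dimensionless, > 0).
    padding
        Border rule for all filtering; scipy.ndimage mode name.
        The default ``"mirror"`` reflects about the edge pixel.
    """

    scales: tuple = DEFAULT_SCALES
    epsilon: float = 0.1
    padding: str = "mirror"

    def __post_init__(self):
        scales = tuple(float(s) for s in self.scales)
        object.__setattr__(self, "scales", scales)
        if not scales:
            raise InvalidParameterError("scales must be non-empty")
        if any(s <= 0 for s in scales):
            raise InvalidParameterError("scales must be positive")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise InvalidParameterError("scales must be strictly increasing")
        if not self.epsilon > 0:
            raise InvalidParameterError("epsilon must be > 0")
        if self.padding not in _VALID_PADDING:
            raise InvalidParameterError(
                f"padding must be one of {_VALID_PADDING}, got {self.padding!r}"
            )


@dataclass
class DtgResponses:
    """Scale-normalized derivative-of-Gaussian responses at one scale.

    ``sIJ`` is the order-(I, J) derivative (I in x/columns, J in y/rows),
    already multiplied by ``sigma**(I+J)``.
    """

    s00: np.ndarray
    s10: np.ndarray
    s01: np.ndarray
    s20: np.ndarray
    s11: np.ndarray
    s02: np.ndarray
    sigma: float

    def as_tuple(self):
        return (self.s00, self.s10, self.s01, self.s20, self.s11, self.s02)


@dataclass
class BifLabelMap:
    """Per-pixel BIF labels (uint8 in {0..6}) at one scale."""

    labels: np.ndarray
    sigma: float

    @property
    def shape(self):
        return self.labels.shape


def normalize_intensity(image) -> np.ndarray:
    """Rescale an image to float64 in [0, 1] by its dtype range.

    Integer dtypes divide by the dtype maximum (not a per-image stretch, so
    the flat-threshold ``epsilon`` stays comparable across a time-lapse);
    float input is assumed to already live in [0, 1] and is clipped.
    """
    arr = np.asarray(image)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("image contains non-finite intensities")
    if arr.dtype == bool:
        return arr.astype(np.float64)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        lo = float(info.min)
        return (arr.astype(np.float64) - lo) / (float(info.max) - lo)
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def to_grayscale(image) -> np.ndarray:
    """Convert an image to a single-channel [0, 1] float array.

    Three-channel input is combined with fixed BT.601 luminance weights
    (0.2989 R + 0.5870 G + 0.1140 B); single-channel input passes through
    up to dtype rescaling.
    """
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim == 2:
        return normalize_intensity(arr)
    if arr.ndim == 3 and arr.shape[-1] == 3:
        return normalize_intensity(arr) @ _LUMA_WEIGHTS
    raise InvalidInputError(
        f"expected 1 or 3 channels, got array of shape {arr.shape}"
    )


def gaussian_derivative_kernel1d(sigma: float, order: int, radius: int | None = None) -> np.ndarray:
    """Sampled 1-D Gaussian-derivative kernel (orders 0..2).

    The order-0 kernel is normalized to sum 1.  Derivative kernels start
    from the analytic derivatives of that normalized kernel and are then
    moment-corrected so that, under convolution, they are *exact* on
    polynomials up to their order: order 1 reproduces the slope of a
    linear ramp, order 2 annihilates constants and ramps and reproduces
    the curvature of a parabola.  Without the correction the sampled
    kernels leak a small sigma-dependent bias (worst at sub-pixel sigma).
    """
    if sigma <= 0:
        raise InvalidParameterError("sigma must be > 0")
    if radius is None:
        radius = max(1, int(round(4.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    phi = np.exp(-0.5 * (x / sigma) ** 2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        k = (-x / sigma**2) * phi
        # convolution of a unit ramp yields -sum(x*k); rescale to exactly 1
        return k / -(x * k).sum()
    if order == 2:
        k = ((x**2 - sigma**2) / sigma**4) * phi
        k = k - k.sum() * phi  # annihilate constants exactly
        return k * (2.0 / (x**2 * k).sum())  # curvature of x^2 is exactly 2
    raise InvalidParameterError("kernel order must be 0, 1 or 2")


def dtg_responses(image, sigma: float, padding: str = "mirror") -> DtgResponses:
    """Compute the six scale-normalized derivative-of-Gaussian responses.

    Separable implementation: each response is two 1-D convolutions (along
    columns then rows) with the sampled kernels of
    :func:`gaussian_derivative_kernel1d`, then multiplied by
    ``sigma**(order_x + order_y)``.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise InvalidInputError("expected a non-empty 2-D grayscale image")
    if sigma <= 0:
        raise InvalidParameterError("sigma must be > 0")
    kernels = {o: gaussian_derivative_kernel1d(sigma, o) for o in (0, 1, 2)}

    def sep(order_x, order_y):
        out = ndimage.convolve1d(img, kernels[order_x], axis=1, mode=padding)
        out = ndimage.convolve1d(out, kernels[order_y], axis=0, mode=padding)
        return out * sigma ** (order_x + order_y)

    return DtgResponses(
        s00=sep(0, 0),
        s10=sep(1, 0),
        s01=sep(0, 1),
        s20=sep(2, 0),
        s11=sep(1, 1),
        s02=sep(0, 2),
        sigma=sigma,
    )


def bif_scores(responses: DtgResponses, epsilon: float) -> np.ndarray:
    """Stack of the seven class scores, shape (7, h, w), in label order."""
    if epsilon <= 0:
        raise InvalidParameterError("epsilon must be > 0")
    grids = responses.as_tuple()
    shape = grids[0].shape
    if any(g.shape != shape for g in grids):
        raise InvalidInputError("response grids have mismatched shapes")
    s00, s10, s01, s20, s11, s02 = grids
    lam = s20 + s02
    gam = np.hypot(s20 - s02, 2.0 * s11)
    return np.stack(
        [
            epsilon * s00,
            2.0 * np.hypot(s10, s01),
            lam,
            -lam,
            (gam + lam) / _SQRT2,
            (gam - lam) / _SQRT2,
            gam,
        ]
    )


def classify_bif(responses: DtgResponses, epsilon: float) -> BifLabelMap:
    """Assign each pixel its argmax BIF class.

    Ties go to the lowest class index (np.argmax keeps the first maximum),
    which realizes the fixed precedence flat > gradient > dark blob >
    light blob > dark line > light line > saddle.
    """
    scores = bif_scores(responses, epsilon)
    labels = np.argmax(scores, axis=0).astype(np.uint8)
    return BifLabelMap(labels=labels, sigma=responses.sigma)


def multiscale_bif(image, config: EncoderConfig | None = None) -> list[BifLabelMap]:
    """BIF label maps at every configured scale, in scale order."""
    if config is None:
        config = EncoderConfig()
    img = np.asarray(image, dtype=np.float64)
    return [
        classify_bif(dtg_responses(img, sigma, config.padding), config.epsilon)
        for sigma in config.scales
    ]
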