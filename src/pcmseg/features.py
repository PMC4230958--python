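"""Per-pixel multi-scale BIF-histogram feature vectors.

Each pixel is described by the frequencies of the seven BIF labels inside
the window centered on it, concatenated over scales: with the default
25x25 window and four scales every pixel carries a 28-element vector.
Windows slide densely (stride 1, "each pixel gets a histogram"); at the
borders the label map is mirror-extended with the same rule used for
filtering, so the count denominator is constant everywhere.

Window counts are computed exactly with per-class integral images
(summed-area tables), which makes the dense sliding window O(n_pixels)
per class instead of O(n_pixels * window**2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .bif import BifLabelMap, EncoderConfig, N_BIF_CLASSES, multiscale_bif
from .errors import InvalidInputError, InvalidParameterError


@dataclass(frozen=True)
class HistogramConfig:
    """Local-histogram window configuration.

    ``window_side`` must be odd so the window centers on its pixel;
    ``normalize`` converts counts to frequencies summing to 1.
    """

    window_side: int = 25
    normalize: bool = True

    def __post_init__(self):
        if self.window_side % 2 == 0 or self.window_side < 3:
            raise InvalidParameterError(
                f"window_side must be odd and >= 3, got {self.window_side}"
            )


@dataclass
class FeatureStack:
    """Dense per-pixel feature array of shape (h, w, n_bins * n_scales)."""

    data: np.ndarray
    scales: tuple
    window_side: int
    normalized: bool

    @property
    def shape(self):
        return self.data.shape[:2]

    @property
    def n_features(self) -> int:
        return self.data.shape[2]

    def flat(self) -> np.ndarray:
        """View as (n_pixels, n_features), row-major pixel order."""
        return self.data.reshape(-1, self.n_features)

    def save(self, path):
        """Persist to an .npz container with a JSON sidecar of the configs."""
        path = Path(path)
        np.savez_compressed(path, data=self.data)
        sidecar = {
            "scales": list(self.scales),
            "window_side": self.window_side,
            "normalized": self.normalized,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "FeatureStack":
        path = Path(path)
        data = np.load(path)["data"]
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            data=data,
            scales=tuple(meta["scales"]),
            window_side=int(meta["window_side"]),
            normalized=bool(meta["normalized"]),
        )


def _window_counts(labels: np.ndarray, window_side: int) -> np.ndarray:
    """Exact per-class window counts via integral images, mirror borders."""
    h, w = labels.shape
    r = window_side // 2
    padded = np.pad(labels, r, mode="reflect")  # == scipy "mirror"
    counts = np.empty((h, w, N_BIF_CLASSES), dtype=np.int64)
    for c in range(N_BIF_CLASSES):
        ind = (padded == c).astype(np.int64)
        integral = np.zeros((ind.shape[0] + 1, ind.shape[1] + 1), dtype=np.int64)
        np.cumsum(np.cumsum(ind, axis=0), axis=1, out=integral[1:, 1:])
        s = window_side
        counts[..., c] = (
            integral[s : s + h, s : s + w]
            - integral[:h, s : s + w]
            - integral[s : s + h, :w]
            + integral[:h, :w]
        )
    return counts


def local_histograms(label_map, config: HistogramConfig | None = None) -> np.ndarray:
    """Per-pixel 7-bin histogram grid, shape (h, w, 7).

    With ``normalize`` on, each histogram sums to 1; off, it holds raw
    counts summing to ``window_side**2`` (mirror padding keeps the
    denominator constant at borders too).
    """
    if config is None:
        config = HistogramConfig()
    labels = label_map.labels if isinstance(label_map, BifLabelMap) else np.asarray(label_map)
    if labels.ndim != 2 or labels.size == 0:
        raise InvalidInputError("label map must be a non-empty 2-D array")
    if labels.min() < 0 or labels.max() >= N_BIF_CLASSES:
        raise InvalidInputError("labels outside the 7-class BIF alphabet")
    counts = _window_counts(labels, config.window_side)
    if config.normalize:
        return counts / float(config.window_side**2)
    return counts.astype(np.float64)


def concat_features(
    histogram_grids: Sequence[np.ndarray],
    scales: Sequence[float] = (),
    window_side: int = 25,
    normalized: bool = True,
) -> FeatureStack:
    """Concatenate per-scale histogram grids into one feature stack."""
    grids = [np.asarray(g) for g in histogram_grids]
    if not grids:
        raise InvalidInputError("need at least one histogram grid")
    shape = grids[0].shape
    if any(g.shape != shape for g in grids):
        raise InvalidInputError("histogram grids have mismatched shapes")
    data = np.concatenate(grids, axis=2)
    return FeatureStack(
        data=data,
        scales=tuple(scales) if scales else tuple(range(len(grids))),
        window_side=window_side,
        normalized=normalized,
    )


def encode(
    image,
    encoder_config: EncoderConfig | None = None,
    histogram_config: HistogramConfig | None = None,
) -> FeatureStack:
    """Full pixel encoding: multi-scale BIF labels -> local histograms -> concat.

    Deterministic; with default configs the per-pixel vector has
    7 bins x 4 scales = 28 elements.
    """
    if encoder_config is None:
        encoder_config = EncoderConfig()
    if histogram_config is None:
        histogram_config = HistogramConfig()
    label_maps = multiscale_bif(image, encoder_config)
    grids = [local_histograms(lm, histogram_config) for lm in label_maps]
    return concat_features(
        grids,
        scales=encoder_config.scales,
        window_side=histogram_config.window_side,
        normalized=histogram_config.normalize,
    )
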