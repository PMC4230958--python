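"""Random-forest pixel classification from sparse trinary annotations.

The user paints three kinds of region on a micrograph: *positive*
(definitely the cell type of interest), *negative* (definitely background,
artifact, or another cell type) and *unspecified* (everything they did not
bother to annotate).  Only specified pixels enter training; the classifier
then labels every pixel of an image cell/background from its multi-scale
BIF-histogram feature vector, and the binary mask feeds the downstream
confluency and tracking measurements.

The learner follows the model/results idiom: :class:`PixelSegmenter` binds
features to annotations, ``fit()`` trains the forest and returns a
:class:`SegmenterResults` that carries the trained ensemble, its training
diagnostics, and the prediction/segmentation methods.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .bif import EncoderConfig
from .errors import (
    InsufficientAnnotationError,
    InvalidInputError,
    InvalidParameterError,
    ModelMismatchError,
)
from .features import FeatureStack, HistogramConfig, encode

#: Annotation palette: 0 = unspecified, 1 = negative, 2 = positive.
UNSPECIFIED, NEGATIVE, POSITIVE = 0, 1, 2

#: Class order of the binary output: 0 = background, 1 = cell.
CLASS_ORDER = ("background", "cell")

_ARCHIVE_VERSION = 1


@dataclass
class TrainingTable:
    """Labeled feature rows drawn from annotated pixels.

    ``y`` is 0 for background (negative annotations) and 1 for cell.
    """

    X: np.ndarray
    y: np.ndarray
    class_counts: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.y)


def build_training_set(
    features,
    annotations,
    cap_per_class: int = 10_000,
    seed: int = 0,
) -> TrainingTable:
    """Collect (feature vector, class) rows from annotated pixels only.

    Unspecified pixels are excluded.  A class exceeding ``cap_per_class``
    is subsampled uniformly with the given seed, so repeated calls are
    reproducible.  Raises :class:`InsufficientAnnotationError` naming the
    class that is absent.
    """
    data = features.data if isinstance(features, FeatureStack) else np.asarray(features)
    ann = np.asarray(annotations)
    if data.shape[:2] != ann.shape:
        raise InvalidInputError(
            f"feature shape {data.shape[:2]} != annotation shape {ann.shape}"
        )
    if cap_per_class < 1:
        raise InvalidParameterError("cap_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    flat = data.reshape(-1, data.shape[2])
    ann_flat = ann.ravel()
    rows_x, rows_y, counts = [], [], {}
    for value, cls, name in ((NEGATIVE, 0, "negative"), (POSITIVE, 1, "positive")):
        idx = np.flatnonzero(ann_flat == value)
        if idx.size == 0:
            raise InsufficientAnnotationError(
                f"no {name} pixels in the annotation mask"
            )
        if idx.size > cap_per_class:
            idx = np.sort(rng.choice(idx, size=cap_per_class, replace=False))
        rows_x.append(flat[idx])
        rows_y.append(np.full(idx.size, cls, dtype=np.int64))
        counts[name] = int(idx.size)
    return TrainingTable(
        X=np.concatenate(rows_x), y=np.concatenate(rows_y), class_counts=counts
    )


def train(table: TrainingTable, n_trees: int = 50, seed: int = 0) -> "SegmenterResults":
    """Train a forest on a prebuilt table (functional spelling of ``fit``)."""
    return PixelSegmenter._fit_table(table, n_trees=n_trees, seed=seed)


class PixelSegmenter:
    """Pixel-classification model bound to features and annotations.

    Parameters
    ----------
    features
        :class:`FeatureStack` (or (h, w, d) array) of the training image.
    annotations
        Trinary mask (0 unspecified / 1 negative / 2 positive), same
        height/width as the features.
    encoder_config, histogram_config
        The configs the features were built with; stored on the results so
        whole images can be segmented end-to-end and config mismatches can
        be refused.
    cap_per_class
        Training-pixel cap per class (seeded subsample above it).
    """

    def __init__(
        self,
        features,
        annotations,
        encoder_config: EncoderConfig | None = None,
        histogram_config: HistogramConfig | None = None,
        cap_per_class: int = 10_000,
    ):
        self.features = features
        self.annotations = np.asarray(annotations)
        self.encoder_config = encoder_config
        self.histogram_config = histogram_config
        self.cap_per_class = cap_per_class

    @classmethod
    def from_image(
        cls,
        image,
        annotations,
        encoder_config: EncoderConfig | None = None,
        histogram_config: HistogramConfig | None = None,
        cap_per_class: int = 10_000,
    ) -> "PixelSegmenter":
        """Encode a grayscale image and bind it to its annotation mask."""
        encoder_config = encoder_config or EncoderConfig()
        histogram_config = histogram_config or HistogramConfig()
        feats = encode(image, encoder_config, histogram_config)
        return cls(feats, annotations, encoder_config, histogram_config, cap_per_class)

    def fit(self, n_trees: int = 50, seed: int = 0) -> "SegmenterResults":
        """Build the training table and fit the random forest."""
        table = build_training_set(
            self.features, self.annotations, self.cap_per_class, seed
        )
        return self._fit_table(
            table,
            n_trees=n_trees,
            seed=seed,
            encoder_config=self.encoder_config,
            histogram_config=self.histogram_config,
        )

    @staticmethod
    def _fit_table(
        table: TrainingTable,
        n_trees: int = 50,
        seed: int = 0,
        encoder_config: EncoderConfig | None = None,
        histogram_config: HistogramConfig | None = None,
    ) -> "SegmenterResults":
        if n_trees < 1:
            raise InvalidParameterError("n_trees must be >= 1")
        if len(table) == 0 or len(np.unique(table.y)) < 2:
            raise InsufficientAnnotationError(
                "training table must contain both classes"
            )
        model = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            bootstrap=True,
            oob_score=True,
            random_state=int(seed),
            n_jobs=1,
        )
        model.fit(table.X, table.y)
        return SegmenterResults(
            model=model,
            encoder_config=encoder_config,
            histogram_config=histogram_config,
            seed=int(seed),
            class_counts=dict(table.class_counts),
        )


class SegmenterResults:
    """A trained pixel classifier plus the configs it was trained under.

    Prediction is deterministic for a fixed trained model: the per-pixel
    class is the majority vote of the trees (fully grown trees have
    one-hot leaves, so the averaged leaf distributions equal the vote
    fraction), and an exact 50/50 tie goes to background.
    """

    def __init__(self, model, encoder_config, histogram_config, seed, class_counts):
        self.model = model
        self.encoder_config = encoder_config
        self.histogram_config = histogram_config
        self.seed = seed
        self.class_counts = class_counts
        self.class_order = CLASS_ORDER

    @property
    def n_trees(self) -> int:
        return self.model.n_estimators

    @property
    def n_features(self) -> int:
        return int(self.model.n_features_in_)

    @property
    def oob_accuracy(self) -> float:
        return float(self.model.oob_score_)

    def predict_mask(self, features) -> np.ndarray:
        """Binary (h, w) uint8 mask: 1 = cell, 0 = background."""
        data = features.data if isinstance(features, FeatureStack) else np.asarray(features)
        if data.ndim != 3:
            raise InvalidInputError("expected an (h, w, d) feature array")
        if data.shape[2] != self.n_features:
            raise ModelMismatchError(
                f"model expects {self.n_features} features per pixel, "
                f"got {data.shape[2]} (encoder/histogram config mismatch?)"
            )
        proba = self.model.predict_proba(data.reshape(-1, data.shape[2]))
        cell_col = int(np.flatnonzero(self.model.classes_ == 1)[0])
        mask = (proba[:, cell_col] > 0.5).astype(np.uint8)
        return mask.reshape(data.shape[:2])

    def segment(self, image, min_object_px: int = 0) -> np.ndarray:
        """Encode a grayscale image with the stored configs and predict.

        ``min_object_px`` optionally removes 8-connected components
        smaller than the given area (off by default).
        """
        if self.encoder_config is None or self.histogram_config is None:
            raise ModelMismatchError(
                "this model was trained without stored configs; "
                "use predict_mask on precomputed features"
            )
        feats = encode(image, self.encoder_config, self.histogram_config)
        mask = self.predict_mask(feats)
        if min_object_px > 0:
            mask = remove_small_objects(mask, min_object_px)
        return mask

    # spec spelling
    segment_image = segment

    def summary(self) -> str:
        """Human-readable training summary."""
        lines = [
            "Random-forest pixel segmenter",
            "=============================",
            f"trees:               {self.n_trees}",
            "features per split:  sqrt(n_features)",
            f"feature length:      {self.n_features}",
            f"training pixels:     "
            + ", ".join(f"{k}={v}" for k, v in self.class_counts.items()),
            f"out-of-bag accuracy: {self.oob_accuracy:.4f}",
            f"seed:                {self.seed}",
            f"class order:         {self.class_order}",
        ]
        if self.encoder_config is not None:
            lines.append(f"scales (sigma, px):  {self.encoder_config.scales}")
            lines.append(f"epsilon:             {self.encoder_config.epsilon}")
        if self.histogram_config is not None:
            lines.append(f"histogram window:    {self.histogram_config.window_side}")
        return "\n".join(lines)

    def save(self, path):
        """Persist model + configs + seed as a single archive."""
        payload = {
            "version": _ARCHIVE_VERSION,
            "model": self.model,
            "encoder_config": asdict(self.encoder_config) if self.encoder_config else None,
            "histogram_config": asdict(self.histogram_config)
            if self.histogram_config
            else None,
            "seed": self.seed,
            "class_counts": self.class_counts,
            "class_order": self.class_order,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path) -> "SegmenterResults":
        payload = joblib.load(path)
        enc = payload.get("encoder_config")
        hist = payload.get("histogram_config")
        return cls(
            model=payload["model"],
            encoder_config=EncoderConfig(**{**enc, "scales": tuple(enc["scales"])})
            if enc
            else None,
            histogram_config=HistogramConfig(**hist) if hist else None,
            seed=payload.get("seed", 0),
            class_counts=payload.get("class_counts", {}),
        )


def predict_mask(classifier: SegmenterResults, features) -> np.ndarray:
    """Functional spelling of :meth:`SegmenterResults.predict_mask`."""
    return classifier.predict_mask(features)


def segment_image(image, classifier: SegmenterResults, min_object_px: int = 0) -> np.ndarray:
    """Functional spelling of :meth:`SegmenterResults.segment`."""
    return classifier.segment(image, min_object_px=min_object_px)


def remove_small_objects(mask: np.ndarray, min_object_px: int) -> np.ndarray:
    """Drop 8-connected components smaller than ``min_object_px`` pixels."""
    mask = np.asarray(mask).astype(bool)
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask.astype(np.uint8)
    areas = np.bincount(labeled.ravel())
    keep = areas >= min_object_px
    keep[0] = False
    return keep[labeled].astype(np.uint8)
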