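"""File I/O and run configuration.

Images travel as TIFF (8/16-bit, written 16-bit) or PNG; trinary
annotation masks as indexed PNG with the documented palette
0 = unspecified (black), 1 = negative (red), 2 = positive (green);
tables as UTF-8 CSV with "." decimals; configs and tile manifests as
JSON.  A run manifest is the software stand-in for a recorded list of
stage positions: it maps each timepoint to its per-tile image files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from PIL import Image

from .bif import EncoderConfig, to_grayscale
from .errors import InvalidInputError, InvalidParameterError
from .features import HistogramConfig
from .quantify import TileLayout

#: RGB palette of annotation PNGs, indexed by label value.
ANNOTATION_PALETTE = [(0, 0, 0), (220, 40, 40), (40, 220, 40)]


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest training section of a run config."""

    n_trees: int = 50
    cap_per_class: int = 10_000

    def __post_init__(self):
        if self.n_trees < 1:
            raise InvalidParameterError("n_trees must be >= 1")


@dataclass(frozen=True)
class QuantifyConfig:
    """Mask post-processing / measurement section."""

    min_object_px: int = 0


@dataclass(frozen=True)
class SynthConfig:
    """Synthetic-scene section of a run config (shape + study knobs)."""

    shape: tuple = (256, 256)
    target_confluency: float = 0.30
    n_colonies: int = 2
    n_frames: int = 5
    growth_rate: float = 0.25
    capacity: float = 0.60
    drift: float = 1.0


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable configuration of a pipeline run.

    All randomness in a run flows from ``seed``; a run is reproducible
    from its config plus inputs, and every output carries the config
    hash.  Unknown keys in a JSON config are rejected.
    """

    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    histogram: HistogramConfig = field(default_factory=HistogramConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["encoder"]["scales"] = list(self.encoder.scales)
        d["synth"]["shape"] = list(self.synth.shape)
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sections = {
            "encoder": EncoderConfig,
            "histogram": HistogramConfig,
            "forest": ForestConfig,
            "quantify": QuantifyConfig,
            "synth": SynthConfig,
        }
        kwargs = {}
        for name, typ in sections.items():
            sub = dict(d.pop(name, {}))
            _reject_unknown(sub, typ, name)
            if name == "encoder" and "scales" in sub:
                sub["scales"] = tuple(sub["scales"])
            if name == "synth" and "shape" in sub:
                sub["shape"] = tuple(sub["shape"])
            kwargs[name] = typ(**sub)
        for scalar in ("seed", "log_level"):
            if scalar in d:
                kwargs[scalar] = d.pop(scalar)
        if d:
            raise InvalidInputError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def hash(self) -> str:
        """Short stable digest of the canonical JSON form."""
        canon = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:12]


def _reject_unknown(sub: dict, typ, section: str):
    known = {f.name for f in dataclasses.fields(typ)}
    unknown = set(sub) - known
    if unknown:
        raise InvalidInputError(
            f"unknown config keys in section {section!r}: {sorted(unknown)}"
        )


def read_image(path) -> np.ndarray:
    """Read a TIFF/PNG image to a [0, 1] grayscale float array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return to_grayscale(arr)


def write_image(path, image: np.ndarray):
    """Write a [0, 1] float image: 16-bit TIFF or 8-bit PNG by extension."""
    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.round(arr * 65535).astype(np.uint16))
    else:
        iio.imwrite(path, np.round(arr * 255).astype(np.uint8))


def write_mask(path, mask: np.ndarray):
    """Write a binary mask as an 8-bit PNG (0/255)."""
    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def read_mask(path) -> np.ndarray:
    """Read a binary mask PNG back to 0/1 uint8."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 0).astype(np.uint8)


def write_annotation(path, annotation: np.ndarray):
    """Write a trinary annotation mask as an indexed (palette) PNG."""
    ann = np.asarray(annotation)
    if not np.isin(np.unique(ann), (0, 1, 2)).all():
        raise InvalidInputError("annotation values must be in {0, 1, 2}")
    img = Image.fromarray(ann.astype(np.uint8), mode="P")
    palette = []
    for rgb in ANNOTATION_PALETTE:
        palette.extend(rgb)
    palette.extend([0] * (768 - len(palette)))
    img.putpalette(palette)
    img.save(Path(path))


def read_annotation(path) -> np.ndarray:
    """Read a trinary annotation PNG (palette indices 0/1/2)."""
    img = Image.open(Path(path))
    if img.mode == "P":
        arr = np.asarray(img)
    else:
        arr = np.asarray(img.convert("L"))
    arr = arr.astype(np.uint8)
    if arr.max() > 2:
        raise InvalidInputError(
            f"annotation PNG has indices outside 0/1/2: {path}"
        )
    return arr


@dataclass
class TimePoint:
    """One manifest entry: hours since seeding and tile-id -> image path."""

    time_h: float
    tiles: dict


@dataclass
class RunManifest:
    """Per-timepoint image listing plus the tile-grid layout."""

    timepoints: list
    layout: TileLayout | None = None

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        path = Path(path)
        d = json.loads(path.read_text())
        layout = None
        if d.get("layout"):
            ld = d["layout"]
            layout = TileLayout(
                rows=ld["rows"],
                cols=ld["cols"],
                tile_shape=tuple(ld["tile_shape"]),
                overlap=ld.get("overlap", 0),
            )
        tps = []
        for entry in d["timepoints"]:
            tiles = {
                tid: str((path.parent / p).resolve())
                for tid, p in entry["tiles"].items()
            }
            tps.append(TimePoint(time_h=float(entry["time_h"]), tiles=tiles))
        manifest = cls(timepoints=tps, layout=layout)
        manifest.validate()
        return manifest

    def validate(self):
        for tp in self.timepoints:
            for tid, p in tp.tiles.items():
                if not Path(p).exists():
                    raise FileNotFoundError(
                        f"manifest references missing file: {p} (tile {tid})"
                    )

    def to_json(self, path):
        path = Path(path)
        d = {
            "layout": None
            if self.layout is None
            else {
                "rows": self.layout.rows,
                "cols": self.layout.cols,
                "tile_shape": list(self.layout.tile_shape),
                "overlap": self.layout.overlap,
            },
            "timepoints": [
                {"time_h": tp.time_h, "tiles": tp.tiles} for tp in self.timepoints
            ],
        }
        path.write_text(json.dumps(d, indent=2))


def load_images(manifest: RunManifest) -> list:
    """Decode every manifest image, ordered by (time, tile id).

    Returns a list of (time_h, tile_id, gray image) tuples.
    """
    manifest.validate()
    out = []
    for tp in sorted(manifest.timepoints, key=lambda t: t.time_h):
        for tid in sorted(tp.tiles):
            out.append((tp.time_h, tid, read_image(tp.tiles[tid])))
    return out


def write_sidecar(output_path, config: RunConfig, extra: dict | None = None):
    """Record the producing config hash next to an output file."""
    meta = {"config_hash": config.hash(), "seed": config.seed}
    if extra:
        meta.update(extra)
    Path(str(output_path) + ".meta.json").write_text(json.dumps(meta, indent=2))
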