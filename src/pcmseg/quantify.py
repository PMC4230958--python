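"""Culture-level measurements derived from segmentation masks.

Confluency — the fraction of the culture area occupied by cells — is the
headline growth readout; it is computed per field of view and, for tile
scans covering a whole culture chamber, over the stitched area with
overlap margins counted once.  Colony-level records (connected components
with area/centroid/bounding box) and frame-to-frame association expose the
qualitative events observed under perfusion: colonies migrate (move),
merge, appear (split-offs, debris) or wash out (disappear).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import IncompleteScanError, InvalidInputError, InvalidParameterError

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class ConfluencyRecord:
    """One confluency measurement: hours since seeding, fraction, field."""

    time: float
    confluency: float
    field_id: str = "whole"


@dataclass
class ColonyObject:
    """A connected component of a binary mask in one frame."""

    id: int
    frame: int
    area: int
    centroid: tuple
    bounding_box: tuple  # (top, left, height, width)


@dataclass
class TrackEvent:
    """A frame-to-frame association event.

    ``participants`` holds the object ids involved, predecessors (frame t)
    then successors (frame t+1); ``displacement`` is the centroid travel in
    pixels for 1:1 (move) events.
    """

    kind: str  # appear | disappear | merge | split | move
    frames: tuple
    participants_t: tuple
    participants_t1: tuple
    displacement: float | None = None


@dataclass
class TileLayout:
    """Grid geometry of a whole-culture tile scan."""

    rows: int
    cols: int
    tile_shape: tuple
    overlap: int = 0
    positions: dict | None = None

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise InvalidParameterError("layout must have at least one tile")
        if self.overlap < 0 or self.overlap >= min(self.tile_shape):
            raise InvalidParameterError(
                "overlap must be >= 0 and smaller than the tile dimensions"
            )


def confluency(mask) -> float:
    """Fraction of 1-pixels in a binary mask."""
    m = np.asarray(mask)
    if m.size == 0:
        raise InvalidInputError("mask is empty")
    vals = np.unique(m)
    if not np.isin(vals, (0, 1)).all():
        raise InvalidInputError("mask must be binary (0/1)")
    return float(np.count_nonzero(m)) / m.size


def whole_area_confluency(masks, layout: TileLayout, allow_partial: bool = False) -> float:
    """Confluency over a whole tiled culture area.

    ``masks`` maps grid position (row, col) to a tile mask (dict, or a
    row-major sequence).  Overlapping margins between neighboring tiles
    are cropped — split evenly between the two neighbors — so every
    physical pixel is counted once.  Missing tiles raise
    :class:`IncompleteScanError` unless ``allow_partial``.
    """
    grid = {}
    if isinstance(masks, dict):
        grid = dict(masks)
    else:
        seq = list(masks)
        if len(seq) != layout.rows * layout.cols:
            raise IncompleteScanError(
                [
                    (r, c)
                    for r in range(layout.rows)
                    for c in range(layout.cols)
                    if r * layout.cols + c >= len(seq)
                ]
            )
        for r in range(layout.rows):
            for c in range(layout.cols):
                grid[(r, c)] = seq[r * layout.cols + c]

    missing = [
        (r, c)
        for r in range(layout.rows)
        for c in range(layout.cols)
        if grid.get((r, c)) is None
    ]
    if missing and not allow_partial:
        raise IncompleteScanError(missing)

    v = layout.overlap
    cells = 0
    total = 0
    for (r, c), mask in grid.items():
        if mask is None:
            continue
        m = np.asarray(mask)
        h, w = m.shape
        top = v // 2 if r > 0 else 0
        bottom = v - v // 2 if r < layout.rows - 1 else 0
        left = v // 2 if c > 0 else 0
        right = v - v // 2 if c < layout.cols - 1 else 0
        cropped = m[top : h - bottom or None, left : w - right or None]
        cells += int(np.count_nonzero(cropped))
        total += cropped.size
    if total == 0:
        raise InvalidInputError("no pixels to count")
    return cells / total


def _label(mask, min_object_px: int = 0):
    """8-connected labeling with optional small-object removal; relabels 1..n."""
    m = np.asarray(mask).astype(bool)
    labeled, n = ndimage.label(m, structure=_EIGHT)
    if min_object_px > 0 and n > 0:
        areas = np.bincount(labeled.ravel())
        keep = areas >= min_object_px
        keep[0] = False
        labeled = keep[labeled] * labeled
        # renumber to consecutive ids
        old = np.unique(labeled)
        lut = np.zeros(old.max() + 1 if old.size else 1, dtype=np.int64)
        lut[old] = np.arange(old.size)
        labeled = lut[labeled]
        n = old.size - 1
    return labeled, n


def extract_objects(mask, frame: int = 0, min_object_px: int = 0) -> list[ColonyObject]:
    """Connected components (8-connectivity) of a binary mask as colony records."""
    labeled, n = _label(mask, min_object_px)
    objects = []
    if n == 0:
        return objects
    slices = ndimage.find_objects(labeled)
    centroids = ndimage.center_of_mass(np.ones_like(labeled), labeled, range(1, n + 1))
    areas = np.bincount(labeled.ravel())
    for i, sl in enumerate(slices, start=1):
        top, left = sl[0].start, sl[1].start
        objects.append(
            ColonyObject(
                id=i,
                frame=frame,
                area=int(areas[i]),
                centroid=tuple(float(x) for x in centroids[i - 1]),
                bounding_box=(
                    top,
                    left,
                    sl[0].stop - top,
                    sl[1].stop - left,
                ),
            )
        )
    return objects


def track(
    mask_t,
    mask_t1,
    frames: tuple = (0, 1),
    min_object_px: int = 0,
) -> list[TrackEvent]:
    """Associate colonies between two consecutive frames by pixel overlap.

    Each object's primary partner is the object in the other frame with
    the largest overlap (ties by smaller id).  Successors claimed by two
    or more predecessors give a *merge*; a predecessor claimed by two or
    more successors a *split*; mutual 1:1 matches a *move* with centroid
    displacement; the rest *disappear* (wash-out candidates) or *appear*.
    Every object takes part in exactly one event.
    """
    if frames[1] != frames[0] + 1:
        raise InvalidInputError(f"frames {frames} are not consecutive")
    lab_t, n_t = _label(mask_t, min_object_px)
    lab_t1, n_t1 = _label(mask_t1, min_object_px)
    objs_t = extract_objects(mask_t, frames[0], min_object_px)
    objs_t1 = extract_objects(mask_t1, frames[1], min_object_px)
    cent_t = {o.id: o.centroid for o in objs_t}
    cent_t1 = {o.id: o.centroid for o in objs_t1}

    events: list[TrackEvent] = []
    if n_t == 0 and n_t1 == 0:
        return events

    # overlap[i, j] = pixels shared by object i+1 (frame t) and j+1 (frame t+1)
    joint = lab_t.ravel() * (n_t1 + 1) + lab_t1.ravel()
    counts = np.bincount(joint, minlength=(n_t + 1) * (n_t1 + 1))
    overlap = counts.reshape(n_t + 1, n_t1 + 1)[1:, 1:]

    primary_succ = {}
    for i in range(n_t):
        if n_t1 and overlap[i].max() > 0:
            primary_succ[i + 1] = int(np.argmax(overlap[i])) + 1
    primary_pred = {}
    for j in range(n_t1):
        if n_t and overlap[:, j].max() > 0:
            primary_pred[j + 1] = int(np.argmax(overlap[:, j])) + 1

    used_t: set[int] = set()
    used_t1: set[int] = set()

    # merges: >= 2 predecessors share one primary successor
    for j in range(1, n_t1 + 1):
        preds = [i for i, s in primary_succ.items() if s == j and i not in used_t]
        if len(preds) >= 2:
            events.append(
                TrackEvent("merge", tuple(frames), tuple(preds), (j,))
            )
            used_t.update(preds)
            used_t1.add(j)

    # splits: one predecessor is the primary of >= 2 remaining successors
    for i in range(1, n_t + 1):
        if i in used_t:
            continue
        succs = [
            j
            for j, p in primary_pred.items()
            if p == i and j not in used_t1
        ]
        if len(succs) >= 2:
            events.append(TrackEvent("split", tuple(frames), (i,), tuple(succs)))
            used_t.add(i)
            used_t1.update(succs)

    # mutual 1:1 matches -> move
    for i in range(1, n_t + 1):
        if i in used_t:
            continue
        j = primary_succ.get(i)
        if j is not None and j not in used_t1 and primary_pred.get(j) == i:
            d = float(
                np.hypot(
                    cent_t1[j][0] - cent_t[i][0], cent_t1[j][1] - cent_t[i][1]
                )
            )
            events.append(TrackEvent("move", tuple(frames), (i,), (j,), d))
            used_t.add(i)
            used_t1.add(j)

    # leftovers
    for i in range(1, n_t + 1):
        if i not in used_t:
            events.append(TrackEvent("disappear", tuple(frames), (i,), ()))
    for j in range(1, n_t1 + 1):
        if j not in used_t1:
            events.append(TrackEvent("appear", tuple(frames), (), (j,)))
    return events


def confluency_series(masks, times, field_id: str = "whole") -> list[ConfluencyRecord]:
    """Confluency at each timepoint of a mask sequence."""
    masks = list(masks)
    times = list(times)
    if len(masks) != len(times):
        raise InvalidInputError("masks and times differ in length")
    if any(b < a for a, b in zip(times, times[1:])):
        raise InvalidInputError("times must be non-decreasing")
    return [
        ConfluencyRecord(time=float(t), confluency=confluency(m), field_id=field_id)
        for t, m in zip(times, masks)
    ]


def aggregate_replicates(series_list: Sequence[Sequence[ConfluencyRecord]]) -> pd.DataFrame:
    """Across-replicate mean and sample (ddof=1) standard deviation.

    All replicate series must share the same timepoints; returns a frame
    with columns time_h, mean, sd, n.
    """
    if not series_list:
        raise InvalidInputError("no replicate series supplied")
    times0 = [r.time for r in series_list[0]]
    values = []
    for series in series_list:
        if [r.time for r in series] != times0:
            raise InvalidInputError("replicate series have differing timepoints")
        values.append([r.confluency for r in series])
    arr = np.asarray(values)  # (n_reps, n_times)
    return pd.DataFrame(
        {
            "time_h": times0,
            "mean": arr.mean(axis=0),
            "sd": arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1]),
            "n": arr.shape[0],
        }
    )


def series_to_dataframe(records: Sequence[ConfluencyRecord]) -> pd.DataFrame:
    """Confluency records as a CSV-ready frame (time_h, field_id, confluency)."""
    return pd.DataFrame(
        {
            "time_h": [r.time for r in records],
            "field_id": [r.field_id for r in records],
            "confluency": [r.confluency for r in records],
        }
    )


def events_to_dataframe(events: Sequence[TrackEvent]) -> pd.DataFrame:
    """Track events as a CSV-ready frame.

    Columns: frame_t, frame_t1, kind, participants (``"1+2->3"``),
    displacement_px (empty for non-move events).
    """
    rows = []
    for e in events:
        rows.append(
            {
                "frame_t": e.frames[0],
                "frame_t1": e.frames[1],
                "kind": e.kind,
                "participants": "+".join(map(str, e.participants_t))
                + "->"
                + "+".join(map(str, e.participants_t1)),
                "displacement_px": e.displacement,
            }
        )
    return pd.DataFrame(
        rows, columns=["frame_t", "frame_t1", "kind", "participants", "displacement_px"]
    )
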