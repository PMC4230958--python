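"""Confluency, whole-area stitching, colony objects and event tracking."""

import numpy as np
import pytest

from pcmseg.errors import IncompleteScanError, InvalidInputError
from pcmseg.quantify import (
    ConfluencyRecord,
    TileLayout,
    aggregate_replicates,
    confluency,
    confluency_series,
    events_to_dataframe,
    extract_objects,
    series_to_dataframe,
    track,
    whole_area_confluency,
)


class TestConfluency:
    def test_all_ones(self):
        assert confluency(np.ones((10, 10), dtype=np.uint8)) == 1.0

    def test_all_zeros(self):
        assert confluency(np.zeros((10, 10), dtype=np.uint8)) == 0.0

    def test_half_mask(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[:5] = 1
        assert confluency(mask) == 0.5

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidInputError):
            confluency(np.zeros((0, 0)))

    def test_nonbinary_rejected(self):
        with pytest.raises(InvalidInputError):
            confluency(np.full((4, 4), 3))


class TestWholeArea:
    def test_two_equal_tiles_average(self):
        layout = TileLayout(rows=1, cols=2, tile_shape=(8, 8))
        masks = [np.zeros((8, 8), np.uint8), np.ones((8, 8), np.uint8)]
        assert whole_area_confluency(masks, layout) == 0.5

    def test_single_tile_is_identity(self):
        mask = np.zeros((6, 6), np.uint8)
        mask[:3] = 1
        layout = TileLayout(rows=1, cols=1, tile_shape=(6, 6))
        assert whole_area_confluency([mask], layout) == confluency(mask)

    def test_uniform_masks_invariant_to_overlap_cropping(self):
        layout = TileLayout(rows=2, cols=2, tile_shape=(32, 32), overlap=10)
        masks = [np.ones((32, 32), np.uint8)] * 4
        assert whole_area_confluency(masks, layout) == 1.0

    def test_missing_tile_error_lists_positions(self):
        layout = TileLayout(rows=1, cols=2, tile_shape=(8, 8))
        masks = {(0, 0): np.ones((8, 8), np.uint8), (0, 1): None}
        with pytest.raises(IncompleteScanError) as err:
            whole_area_confluency(masks, layout)
        assert (0, 1) in err.value.missing

    def test_allow_partial_computes_present_tiles(self):
        layout = TileLayout(rows=1, cols=2, tile_shape=(8, 8))
        masks = {(0, 0): np.ones((8, 8), np.uint8), (0, 1): None}
        assert whole_area_confluency(masks, layout, allow_partial=True) == 1.0


class TestExtractObjects:
    def test_single_square(self):
        mask = np.zeros((10, 10), np.uint8)
        mask[3:7, 2:6] = 1
        objs = extract_objects(mask)
        assert len(objs) == 1
        o = objs[0]
        assert o.area == 16
        assert o.centroid == (4.5, 3.5)
        assert o.bounding_box == (3, 2, 4, 4)

    def test_diagonal_pixels_are_one_object(self):
        mask = np.zeros((5, 5), np.uint8)
        mask[1, 1] = mask[2, 2] = 1
        assert len(extract_objects(mask)) == 1

    def test_empty_mask(self):
        assert extract_objects(np.zeros((5, 5), np.uint8)) == []

    def test_min_object_filter(self):
        mask = np.zeros((20, 20), np.uint8)
        mask[1:3, 1:3] = 1  # area 4
        mask[10:16, 10:16] = 1  # area 36
        objs = extract_objects(mask, min_object_px=10)
        assert len(objs) == 1 and objs[0].area == 36

    def test_areas_sum_to_mask_count(self):
        rng = np.random.default_rng(0)
        mask = (rng.random((30, 30)) > 0.6).astype(np.uint8)
        objs = extract_objects(mask)
        assert sum(o.area for o in objs) == int(mask.sum())


def _square(at, size=4, shape=(32, 32)):
    m = np.zeros(shape, np.uint8)
    r, c = at
    m[r : r + size, c : c + size] = 1
    return m


class TestTrack:
    def test_identical_frames_are_zero_displacement_moves(self):
        mask = _square((4, 4)) | _square((20, 20))
        events = track(mask, mask)
        assert {e.kind for e in events} == {"move"}
        assert all(e.displacement == 0.0 for e in events)
        assert len(events) == 2

    def test_two_objects_merging_into_one(self):
        before = _square((10, 4)) | _square((10, 24))
        after = np.zeros((32, 32), np.uint8)
        after[10:14, 4:28] = 1  # spans both predecessors
        events = track(before, after)
        merges = [e for e in events if e.kind == "merge"]
        assert len(merges) == 1
        assert len(merges[0].participants_t) == 2
        assert len(merges[0].participants_t1) == 1

    def test_one_object_splitting_in_two(self):
        before = np.zeros((32, 32), np.uint8)
        before[10:14, 4:28] = 1
        after = _square((10, 4)) | _square((10, 24))
        events = track(before, after)
        splits = [e for e in events if e.kind == "split"]
        assert len(splits) == 1
        assert len(splits[0].participants_t1) == 2

    def test_washed_out_object_disappears(self):
        before = _square((4, 4)) | _square((20, 20))
        after = _square((4, 4))
        events = track(before, after)
        assert sum(e.kind == "disappear" for e in events) == 1
        assert sum(e.kind == "move" for e in events) == 1

    def test_new_object_appears(self):
        before = _square((4, 4))
        after = _square((4, 4)) | _square((20, 20))
        events = track(before, after)
        assert sum(e.kind == "appear" for e in events) == 1

    def test_nonconsecutive_frames_rejected(self):
        mask = _square((4, 4))
        with pytest.raises(InvalidInputError):
            track(mask, mask, frames=(0, 2))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_every_object_participates_exactly_once(self, seed):
        """Conservation: the events partition both frames' object sets."""
        rng = np.random.default_rng(seed)
        a = (rng.random((40, 40)) > 0.75).astype(np.uint8)
        b = (rng.random((40, 40)) > 0.75).astype(np.uint8)
        events = track(a, b)
        ids_t = [i for e in events for i in e.participants_t]
        ids_t1 = [j for e in events for j in e.participants_t1]
        assert sorted(ids_t) == list(range(1, len(extract_objects(a)) + 1))
        assert sorted(ids_t1) == list(range(1, len(extract_objects(b)) + 1))


class TestSeries:
    def test_constant_masks_give_constant_series(self):
        mask = _square((4, 4))
        records = confluency_series([mask] * 5, [0, 12, 24, 36, 48])
        assert len(records) == 5
        assert len({r.confluency for r in records}) == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            confluency_series([_square((0, 0))], [0, 1])

    def test_unsorted_times_rejected(self):
        with pytest.raises(InvalidInputError):
            confluency_series([_square((0, 0))] * 2, [2, 1])

    def test_replicate_mean_and_sample_sd(self):
        r1 = [ConfluencyRecord(0.0, 0.2)]
        r2 = [ConfluencyRecord(0.0, 0.4)]
        stats = aggregate_replicates([r1, r2])
        assert stats["mean"].iloc[0] == pytest.approx(0.3)
        assert stats["sd"].iloc[0] == pytest.approx(np.sqrt(0.02))

    def test_csv_frames_have_documented_columns(self):
        records = confluency_series([_square((0, 0))], [0.0], field_id="t0")
        assert list(series_to_dataframe(records).columns) == [
            "time_h",
            "field_id",
            "confluency",
        ]
        events = track(_square((4, 4)), _square((5, 4)))
        df = events_to_dataframe(events)
        assert list(df.columns) == [
            "frame_t",
            "frame_t1",
            "kind",
            "participants",
            "displacement_px",
        ]
        assert df["kind"].iloc[0] == "move"
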