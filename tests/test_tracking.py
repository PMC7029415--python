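"""Overlap tracking: identity propagation, divisions, gaps, oracle parity."""

import numpy as np
import pytest

import erktrace as ek
from erktrace.segmentation import LabelMap, _territories_from_labels


def label_map_from(labels: np.ndarray) -> LabelMap:
    labels = np.asarray(labels, dtype=np.int32)
    return LabelMap(labels=labels, territories=_territories_from_labels(labels))


def square_frame(shape, squares):
    """squares: list of (label, y0, x0, side)."""
    labels = np.zeros(shape, dtype=np.int32)
    for lab, y0, x0, side in squares:
        labels[y0 : y0 + side, x0 : x0 + side] = lab
    return label_map_from(labels)


def overlap_argmax_oracle(labels_t: np.ndarray, labels_t1: np.ndarray) -> dict[int, int]:
    """Exhaustive overlap-matrix argmax: {t+1 label -> best t label}."""
    out = {}
    for lab1 in np.unique(labels_t1):
        if lab1 == 0:
            continue
        best, best_ov = None, 0
        for lab0 in np.unique(labels_t):
            if lab0 == 0:
                continue
            ov = int(np.count_nonzero((labels_t1 == lab1) & (labels_t == lab0)))
            if ov > best_ov or (ov == best_ov and ov > 0 and lab0 < best):
                best, best_ov = int(lab0), ov
        out[int(lab1)] = best  # None when zero overlap everywhere
    return out


class TestPairwiseLinking:
    def test_identical_frames_identity_mapping(self):
        lm = square_frame((40, 40), [(1, 5, 5, 6), (2, 20, 20, 6)])
        tracker = ek.track_by_overlap(lm, lm)
        assert len(tracker.tracks) == 2
        for tr in tracker.tracks.values():
            assert tr.frames == [0, 1]

    def test_translation_inherits_all_ids_and_matches_oracle(self):
        a = square_frame((50, 50), [(1, 5, 5, 8), (2, 25, 25, 8), (3, 5, 30, 8)])
        b = square_frame((50, 50), [(1, 6, 6, 8), (2, 26, 26, 8), (3, 6, 31, 8)])
        tracker = ek.track_by_overlap(a, b)
        assert len(tracker.tracks) == 3  # no new ids
        # oracle parity: frame-1 label -> frame-0 label via overlap argmax
        oracle = overlap_argmax_oracle(a.labels, b.labels)
        df = tracker.to_dataframe()
        f0 = df[df.frame == 0].set_index("cell_id")["label"]
        f1 = df[df.frame == 1].set_index("cell_id")["label"]
        for cid in tracker.tracks:
            assert oracle[f1[cid]] == f0[cid]

    def test_new_object_gets_new_id(self):
        a = square_frame((40, 40), [(1, 5, 5, 6)])
        b = square_frame((40, 40), [(1, 5, 5, 6), (2, 25, 25, 6)])
        tracker = ek.track_by_overlap(a, b)
        assert len(tracker.tracks) == 2
        new = [t for t in tracker.tracks.values() if t.first_frame == 1]
        assert len(new) == 1

    def test_division_larger_claimant_keeps_id(self):
        parent = square_frame((40, 60), [(1, 10, 10, 12)])
        # two children over the parent: left child overlaps 12x8, right 12x4
        children = square_frame((40, 60), [(1, 10, 10, 8), (2, 10, 19, 8)])
        # child 1 overlap = 8x8=64 over old footprint cols 10..17 -> 8*8
        tracker = ek.track_by_overlap(parent, children)
        df = tracker.to_dataframe()
        winner = df[(df.frame == 1) & (df.cell_id == 1)]
        assert len(winner) == 1
        kids = [t for t in tracker.tracks.values() if "division_candidate" in t.flags]
        assert len(kids) == 1
        assert kids[0].parent_id == 1
        assert tracker.divisions[0].frame == 1

    def test_vanished_object_enters_gap_and_relinks(self):
        present = square_frame((40, 40), [(1, 5, 5, 8), (2, 25, 25, 8)])
        missing = square_frame((40, 40), [(1, 5, 5, 8)])
        tracker = ek.Tracker()
        tracker.step(present)
        tracker.step(missing)
        tracker.step(missing)
        tracker.step(present)  # reappears within 3 frames at same spot
        assert len(tracker.tracks) == 2
        reappeared = [t for t in tracker.tracks.values() if len(t.entries) == 2][0]
        assert reappeared.gap_frames() == [1, 2]

    def test_gap_longer_than_three_frames_retires_track(self):
        present = square_frame((40, 40), [(1, 5, 5, 8), (2, 25, 25, 8)])
        missing = square_frame((40, 40), [(1, 5, 5, 8)])
        tracker = ek.Tracker()
        tracker.step(present)
        for _ in range(4):
            tracker.step(missing)
        tracker.step(present)  # returns after a 4-frame gap -> new id
        assert len(tracker.tracks) == 3


class TestMovieInvariants:
    def test_static_movie_zero_gaps_zero_new_ids(self, quiet_movie, quiet_acq):
        truth, stack = quiet_movie
        frames = [
            ek.filter_small(ek.segment_nuclei(ek.denoise(stack.frame(0, "nuclear"))))
        ] * 5
        tracker = ek.track_movie(frames)
        assert len(tracker.tracks) == frames[0].n_labels
        for tr in tracker.tracks.values():
            assert tr.gap_frames() == []
            assert tr.first_frame == 0

    def test_ground_truth_id_agreement(self, quiet_result):
        """Tracked ids must match ground-truth ids for 100% of (cell, frame)
        pairs on a non-touching synthetic movie with step SD 1 px."""
        from conftest import match_tracks_to_truth

        truth, result = quiet_result
        mapping = match_tracks_to_truth(truth, result.tracks)
        assert len(mapping) == truth.cells.shape[0]
        merged = result.tracks.merge(
            truth.frames, left_on=["frame"], right_on=["frame"], suffixes=("", "_gt")
        )
        n_checked = 0
        for row in result.tracks.itertuples(index=False):
            gt = truth.frames[
                (truth.frames.cell_id == mapping[row.cell_id])
                & (truth.frames.frame == row.frame)
            ]
            assert len(gt) == 1
            d = np.hypot(
                gt.iloc[0]["y"] - row.centroid_y, gt.iloc[0]["x"] - row.centroid_x
            )
            assert d < 2.0  # correct identity: centroid on the right cell
            n_checked += 1
        assert n_checked == len(result.tracks)
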