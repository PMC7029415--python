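"""Frame-to-frame cell tracking by maximum area overlap.

Cell identifiers are inherited from frame t to frame t+1 by assigning each
nucleus at t+1 the identity of the t-nucleus with which it shares maximal
pixel overlap. When one t-cell is claimed by two t+1 nuclei (the signature
of a division), the larger-overlap claimant keeps the identity and the other
becomes a new cell flagged ``division_candidate``. Nuclei with no overlap
start new tracks; unclaimed t-cells enter a gap and may be re-linked by
overlap with their last known mask for up to 3 frames before being retired.

Ties are broken deterministically: equal overlaps resolve to the lower
pre-existing cell id (for a t+1 label choosing a parent) or the lower label
id (for a parent choosing among claimants). Links whose top-two overlaps
differ by less than 10% are flagged ``ambiguous_link`` — the automated
replacement for manual curation of unreliable reassignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import TrackingConfig
from .segmentation import LabelMap


@dataclass
class TrackEntry:
    frame: int
    label: int
    centroid_y: float
    centroid_x: float
    area: int


@dataclass
class CellTrack:
    """One cell's ordered observations, with gaps and QC flags."""

    cell_id: int
    entries: list[TrackEntry] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)
    parent_id: int = -1

    @property
    def frames(self) -> list[int]:
        return [e.frame for e in self.entries]

    @property
    def first_frame(self) -> int:
        return self.entries[0].frame

    @property
    def last_frame(self) -> int:
        return self.entries[-1].frame

    def gap_frames(self) -> list[int]:
        """Frames inside the observed span with no entry."""
        have = set(self.frames)
        return [f for f in range(self.first_frame, self.last_frame + 1) if f not in have]

    def areas(self) -> pd.Series:
        return pd.Series(
            [e.area for e in self.entries], index=self.frames, name=self.cell_id
        )


@dataclass
class DivisionEvent:
    parent_id: int
    frame: int
    child_id: int


class Tracker:
    """Stateful frame-by-frame tracker over a sequence of label maps."""

    def __init__(self, config: TrackingConfig | None = None):
        self.config = config or TrackingConfig()
        self.tracks: dict[int, CellTrack] = {}
        self.divisions: list[DivisionEvent] = []
        self._next_id = 1  # 0 is reserved for background in the mask image
        self._id_img: np.ndarray | None = None  # last known mask of each live track
        self._gap_count: dict[int, int] = {}
        self._frame = -1

    # -- helpers ----------------------------------------------------------

    def _new_track(self, frame: int, row, flags: Iterable[str] = (), parent: int = -1) -> int:
        cid = self._next_id
        self._next_id += 1
        tr = CellTrack(cell_id=cid, parent_id=parent)
        tr.flags.update(flags)
        if row.border_touch:
            tr.flags.add("border_touch")
        tr.entries.append(
            TrackEntry(frame, int(row.label), row.centroid_y, row.centroid_x, int(row.area))
        )
        self.tracks[cid] = tr
        self._gap_count[cid] = 0
        return cid

    def _extend(self, cid: int, frame: int, row, ambiguous: bool) -> None:
        tr = self.tracks[cid]
        if row.border_touch:
            tr.flags.add("border_touch")
        if ambiguous:
            tr.flags.add("ambiguous_link")
        tr.entries.append(
            TrackEntry(frame, int(row.label), row.centroid_y, row.centroid_x, int(row.area))
        )
        self._gap_count[cid] = 0

    def _paint(self, labels: np.ndarray, assignment: dict[int, int]) -> None:
        """Refresh the last-known-mask image for updated tracks."""
        img = self._id_img
        for label, cid in assignment.items():
            mask = labels == label
            img[(img == cid)] = 0
            img[mask] = cid

    # -- main step --------------------------------------------------------

    def step(self, label_map: LabelMap) -> dict[int, int]:
        """Advance one frame; returns {label at t+1 -> cell_id} assignment."""
        self._frame += 1
        frame = self._frame
        labels = label_map.labels
        table = label_map.table

        if self._id_img is None:  # first frame: every label founds a track
            self._id_img = np.zeros(labels.shape, dtype=np.int64)
            assignment = {}
            for row in table.itertuples(index=False):
                cid = self._new_track(frame, row)
                assignment[int(row.label)] = cid
            self._paint(labels, assignment)
            return assignment

        prev = self._id_img
        sel = (labels > 0) & (prev > 0)
        overlap: dict[int, dict[int, int]] = {}
        if sel.any():
            pairs, counts = np.unique(
                np.stack([labels[sel], prev[sel]]), axis=1, return_counts=True
            )
            for (lab, cid), c in zip(pairs.T, counts):
                overlap.setdefault(int(lab), {})[int(cid)] = int(c)

        rows = {int(r.label): r for r in table.itertuples(index=False)}
        # each t+1 label picks its best parent (max overlap, tie -> lower id)
        claims: dict[int, list[tuple[int, int, bool]]] = {}
        unmatched_labels: list[int] = []
        for lab in rows:
            cand = overlap.get(lab, {})
            if not cand:
                unmatched_labels.append(lab)
                continue
            ranked = sorted(cand.items(), key=lambda kv: (-kv[1], kv[0]))
            best_id, best_ov = ranked[0]
            ambiguous = (
                len(ranked) > 1
                and (best_ov - ranked[1][1]) < self.config.ambiguity_margin * best_ov
            )
            claims.setdefault(best_id, []).append((lab, best_ov, ambiguous))

        assignment: dict[int, int] = {}
        # resolve multiple claimants per parent: larger overlap keeps the id
        for cid, claimants in claims.items():
            claimants.sort(key=lambda t: (-t[1], t[0]))
            win_lab, _, win_amb = claimants[0]
            self._extend(cid, frame, rows[win_lab], win_amb)
            assignment[win_lab] = cid
            for lab, _, amb in claimants[1:]:
                flags = ["division_candidate"] + (["ambiguous_link"] if amb else [])
                child = self._new_track(frame, rows[lab], flags, parent=cid)
                self.divisions.append(DivisionEvent(cid, frame, child))
                assignment[lab] = child
        for lab in unmatched_labels:
            assignment[lab] = self._new_track(frame, rows[lab])

        # unclaimed live tracks enter (or deepen) a gap
        updated = set(assignment.values())
        for cid in list(self._gap_count):
            if cid in updated:
                continue
            self._gap_count[cid] += 1
            if self._gap_count[cid] > self.config.max_gap_frames:
                prev[prev == cid] = 0  # retire: stop offering this mask
                del self._gap_count[cid]
        self._paint(labels, assignment)
        return assignment

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks.values():
            for e in tr.entries:
                rows.append(
                    dict(
                        cell_id=tr.cell_id,
                        frame=e.frame,
                        label=e.label,
                        centroid_y=e.centroid_y,
                        centroid_x=e.centroid_x,
                        area=e.area,
                        parent_id=tr.parent_id,
                        border_touch="border_touch" in tr.flags,
                        ambiguous_link="ambiguous_link" in tr.flags,
                        division_candidate="division_candidate" in tr.flags,
                    )
                )
        return pd.DataFrame(rows).sort_values(["cell_id", "frame"]).reset_index(drop=True)


def track_movie(
    label_maps: Sequence[LabelMap] | Iterable[LabelMap],
    config: TrackingConfig | None = None,
) -> Tracker:
    """Track a whole movie of label maps; returns the finished tracker."""
    tracker = Tracker(config)
    for lm in label_maps:
        tracker.step(lm)
    return tracker


def track_by_overlap(
    labels_t: LabelMap,
    labels_t1: LabelMap,
    active_tracks: Tracker | None = None,
    config: TrackingConfig | None = None,
) -> Tracker:
    """Link two consecutive frames, updating (or creating) the track state.

    When ``active_tracks`` is None, tracks are initialised from ``labels_t``
    first; otherwise ``labels_t`` must already be the tracker's last frame
    and only ``labels_t1`` is consumed.
    """
    if active_tracks is None:
        active_tracks = Tracker(config)
        active_tracks.step(labels_t)
    active_tracks.step(labels_t1)
    return active_tracks
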