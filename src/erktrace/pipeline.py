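"""End-to-end movie processing: segment → track → rings → traces → QC.

The processing loop is streaming: frames can come from an in-memory
:class:`~erktrace.render.ImageStack` or from any iterator of (C, H, W)
arrays, so long movies never need to be held in memory at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .config import AcquisitionConfig, PipelineConfig
from .qc import heal_gaps, qc_filter
from .render import ImageStack
from .rings import measure_frame
from .segmentation import LabelMap, denoise, filter_small, segment_nuclei
from .tracking import Tracker


@dataclass
class MovieResult:
    """Everything the per-movie pipeline produces."""

    traces: pd.DataFrame  # tidy per-cell-per-frame ring measurements (raw)
    tracks: pd.DataFrame
    tracker: Tracker
    qc_log: pd.DataFrame
    traces_qc: pd.DataFrame  # pruned + healed traces


def _frame_iter(stack: ImageStack | Iterable[np.ndarray]) -> Iterator[np.ndarray]:
    if isinstance(stack, ImageStack):
        for t in range(stack.n_frames):
            yield stack.data[t]
    else:
        yield from stack


def process_movie(
    frames: ImageStack | Iterable[np.ndarray],
    acq: AcquisitionConfig,
    config: PipelineConfig | None = None,
) -> MovieResult:
    """Run the full single-movie analysis.

    Each frame's nuclear channel is median-denoised, thresholded and
    watershedded; debris below the area cutoff is discarded; nuclei are
    linked by maximum overlap; the perinuclear-ring acceptor/donor ratio is
    measured per cell inside its watershed territory; finally traces are
    pruned by the QC rules and surviving gaps healed.
    """
    config = config or PipelineConfig()
    i_nuc = acq.channel_index("nuclear")
    i_don = acq.channel_index("donor")
    i_acc = acq.channel_index("acceptor")
    dt = acq.frame_interval_min

    tracker = Tracker(config.tracking)
    rows: list[pd.DataFrame] = []
    for t, frame in enumerate(_frame_iter(frames)):
        nuc = denoise(frame[i_nuc])
        lm = segment_nuclei(nuc, config.segmentation)
        lm = filter_small(lm, config.segmentation.min_area_px)
        assignment = tracker.step(lm)
        meas = measure_frame(frame[i_don], frame[i_acc], lm, config.ring)
        if len(meas):
            meas = meas.reset_index()
            meas["cell_id"] = meas["label"].map(assignment)
            meas["frame"] = t
            meas["t_min"] = t * dt
            rows.append(meas)

    traces = (
        pd.concat(rows, ignore_index=True)[
            ["cell_id", "frame", "t_min", "donor_mean", "acceptor_mean", "ratio", "ring_px"]
        ]
        if rows
        else pd.DataFrame(
            columns=["cell_id", "frame", "t_min", "donor_mean", "acceptor_mean", "ratio", "ring_px"]
        )
    )
    # drop cells flagged unreliable before QC (automated stand-in for the
    # manual curation step)
    flagged = {
        cid
        for cid, tr in tracker.tracks.items()
        if tr.flags & {"border_touch", "ambiguous_link"}
    }
    clean = traces[~traces["cell_id"].isin(flagged)]
    kept, qc_log = qc_filter(clean, dt, config.qc)
    healed = heal_gaps(kept, dt, config.qc) if len(kept) else kept.assign(healed=False)
    return MovieResult(
        traces=traces,
        tracks=tracker.to_dataframe() if tracker.tracks else pd.DataFrame(),
        tracker=tracker,
        qc_log=qc_log,
        traces_qc=healed,
    )
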