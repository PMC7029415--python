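"""Trace quality control: pruning rules, then healing of surviving gaps.

Traces are pruned automatically when they are too short (< 10 h between
first and last observation), contain a contiguous gap longer than three
frames, or miss more than 5% of the frames in their observed span. All
three comparisons are strict, matching the stated rules literally: a trace
of exactly 10 h, a 3-frame gap, or exactly 5% missing frames survives.

Surviving short gaps are then healed with a local median filter with a
kernel of 6 time points: each missing sample is replaced by the median of
the 6 nearest observed values (3 on each side where available, shifted at
trace ends); observed samples are never modified. Pruning precedes healing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import QCConfig

TRACE_COLUMNS = ["cell_id", "frame", "t_min", "donor_mean", "acceptor_mean", "ratio", "ring_px"]


def _observed_frames(group: pd.DataFrame) -> np.ndarray:
    obs = group.loc[np.isfinite(group["ratio"]), "frame"].to_numpy()
    return np.sort(obs)


def _max_contiguous_gap(obs: np.ndarray) -> int:
    if len(obs) < 2:
        return 0
    return int(np.max(np.diff(obs)) - 1)


def qc_filter(
    traces: pd.DataFrame,
    frame_interval_min: float,
    config: QCConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Prune traces violating the length/gap rules.

    Parameters
    ----------
    traces:
        Tidy per-cell-per-frame table with at least ``cell_id``, ``frame``
        and ``ratio`` columns; gap frames may be absent rows or NaN ratios.
    frame_interval_min:
        Sampling interval in minutes (3 by default upstream).

    Returns
    -------
    (kept, log):
        ``kept`` restricted to surviving cells; ``log`` has one row per
        rejected cell with the triggering rule and measured value.
    """
    config = config or QCConfig()
    rejections = []
    keep_ids = []
    for cid, group in traces.groupby("cell_id"):
        obs = _observed_frames(group)
        if len(obs) == 0:
            rejections.append(dict(cell_id=cid, rule="no_observations", value=0.0))
            continue
        span_frames = int(obs[-1] - obs[0] + 1)
        span_hours = (obs[-1] - obs[0]) * frame_interval_min / 60.0
        gap = _max_contiguous_gap(obs)
        gap_fraction = (span_frames - len(obs)) / span_frames
        if span_hours < config.min_hours:
            rejections.append(dict(cell_id=cid, rule="too_short", value=span_hours))
        elif gap > config.max_contig_gap_frames:
            rejections.append(dict(cell_id=cid, rule="contiguous_gap", value=float(gap)))
        elif gap_fraction > config.max_gap_fraction:
            rejections.append(dict(cell_id=cid, rule="gap_fraction", value=gap_fraction))
        else:
            keep_ids.append(cid)
    kept = traces[traces["cell_id"].isin(keep_ids)].copy()
    log = pd.DataFrame(rejections, columns=["cell_id", "rule", "value"])
    return kept, log


def heal_series(values: np.ndarray, kernel: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Fill NaNs in a 1-D series with the median of nearby observed points.

    For each missing sample the ``kernel`` nearest observed values are
    gathered, 3 from each side where available, borrowing from the other
    side at the trace ends. Returns (healed values, healed-mask). Raises if
    a missing sample has no observed neighbour at all.
    """
    v = np.asarray(values, dtype=float)
    out = v.copy()
    missing = np.where(~np.isfinite(v))[0]
    obs_idx = np.where(np.isfinite(v))[0]
    healed = np.zeros(len(v), dtype=bool)
    if len(missing) == 0:
        return out, healed
    if len(obs_idx) == 0:
        raise ValueError("cannot heal: no observed samples")
    half = kernel // 2
    for g in missing:
        li = int(np.searchsorted(obs_idx, g))
        n_left = min(half, li)
        n_right = min(kernel - n_left, len(obs_idx) - li)
        n_left = min(kernel - n_right, li)  # borrow leftwards if right side short
        neighbors = obs_idx[li - n_left : li + n_right]
        if len(neighbors) == 0:
            raise ValueError(f"cannot heal sample {g}: no observed neighbours")
        out[g] = float(np.median(v[neighbors]))
        healed[g] = True
    return out, healed


def heal_gaps(
    traces: pd.DataFrame,
    frame_interval_min: float,
    config: QCConfig | None = None,
) -> pd.DataFrame:
    """Heal gap frames of every (already pruned) trace.

    Missing frames inside each cell's observed span gain rows with a healed
    ``ratio`` and ``healed=True``; observed rows pass through bit-identical
    with ``healed=False``.
    """
    config = config or QCConfig()
    pieces = []
    for cid, group in traces.groupby("cell_id"):
        group = group.sort_values("frame")
        obs = _observed_frames(group)
        if len(obs) == 0:
            continue
        full = np.arange(obs[0], obs[-1] + 1)
        g = group.set_index("frame").reindex(full)
        g.index.name = "frame"
        ratio = g["ratio"].to_numpy(dtype=float)
        healed_ratio, healed_mask = heal_series(ratio, config.heal_kernel)
        g["ratio"] = healed_ratio
        g["healed"] = healed_mask
        g["cell_id"] = cid
        g["t_min"] = g.index.to_numpy() * frame_interval_min
        pieces.append(g.reset_index())
    if not pieces:
        out = traces.copy()
        out["healed"] = False
        return out
    return pd.concat(pieces, ignore_index=True)
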