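"""Cohort simulation: per-cell fates, motion and ground-truth tables.

Each simulated cell draws a mitotic fate (Bernoulli with the preset's entry
probability within its analysis window), a G2 delay to mitotic entry and a
mitosis length, moves by a reflected Gaussian random walk, and carries an
independently sampled ERK activity series. Divided cells spawn two daughters
with lineage links.

Fate presets encode the experimentally observed mitotic-entry fractions:
~40% of untreated cells enter mitosis within 24 h; DNA damage (NCS) lowers
this to ~15%; MEK inhibition (U0126) on top of damage to <10%; sustained
mitogen (HRG) on top of damage raises the cycling fraction by 50% relative
to damage alone (scored in a 12-h window to discount late G1/S effects).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .programs import (
    ActivityProgram,
    basal_stochastic,
    damage_stochastic,
    sample_activity,
    sustained_gf,
    transient_gf,
)

PHASES = ("interphase", "mitosis", "divided")

# nuclear geometry defaults (px): interphase radius keeps mitotic area
# (40% of interphase) above the 100-px debris filter
NUCLEUS_RADIUS_PX = 10.0
MITOTIC_AREA_FRACTION = 0.40
MITOTIC_INTENSITY_GAIN = 2.0
DAUGHTER_RADIUS_PX = 8.0
CYTO_MARGIN_PX = 12.0  # cytoplasm radius = nucleus radius + margin


@dataclass
class FatePreset:
    """Condition-specific mitotic-fate parameters.

    ``p_mitosis`` is the probability of mitotic entry within ``window_hours``.
    G2 entry delays are lognormal (hours), truncated to the window; mitosis
    durations are normal (minutes), floored at ``mitosis_min_min``.
    """

    condition: str
    p_mitosis: float
    window_hours: float = 24.0
    g2_delay_mu_log: float = math.log(8.0)  # median 8 h
    g2_delay_sigma_log: float = 0.6
    mitosis_mean_min: float = 45.0
    mitosis_sd_min: float = 10.0
    mitosis_min_min: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_mitosis <= 1.0:
            raise ValueError("p_mitosis must be in [0, 1]")
        if self.window_hours <= 0:
            raise ValueError("window_hours must be > 0")

    def draw_entry_hours(self, rng: np.random.Generator) -> float:
        """G2 delay to mitotic entry, truncated to the analysis window."""
        for _ in range(1000):
            x = rng.lognormal(self.g2_delay_mu_log, self.g2_delay_sigma_log)
            if x <= self.window_hours:
                return float(x)
        return float(rng.uniform(0, self.window_hours))

    def draw_mitosis_minutes(self, rng: np.random.Generator) -> float:
        x = rng.normal(self.mitosis_mean_min, self.mitosis_sd_min)
        return float(max(x, self.mitosis_min_min))


FATE_PRESETS: dict[str, FatePreset] = {
    "control": FatePreset("control", p_mitosis=0.40, window_hours=24.0),
    "ncs": FatePreset("ncs", p_mitosis=0.15, window_hours=24.0),
    "ncs+u0126": FatePreset("ncs+u0126", p_mitosis=0.08, window_hours=24.0),
    "ncs+hrg": FatePreset("ncs+hrg", p_mitosis=0.225, window_hours=12.0),
    "egf": FatePreset("egf", p_mitosis=0.40, window_hours=12.0),
    "hrg": FatePreset("hrg", p_mitosis=0.40, window_hours=12.0),
}


def program_for_condition(condition: str) -> ActivityProgram:
    """Default ERK activity program associated with a treatment condition."""
    if condition == "control":
        return basal_stochastic()
    if condition == "ncs":
        return damage_stochastic()
    if condition == "ncs+u0126":
        # MEK inhibition suppresses pulses regardless of damage
        return damage_stochastic(pulse_amplitude=0.15)
    if condition in ("ncs+hrg", "hrg"):
        return sustained_gf()
    if condition == "egf":
        return transient_gf()
    raise KeyError(f"unknown condition {condition!r}")


@dataclass
class GroundTruthTable:
    """Per-cell-per-frame ground truth of a simulated movie.

    ``frames`` has one row per (cell, frame) with columns ``cell_id, frame,
    t_min, y, x, radius_px, cyto_radius_px, intensity_scale, activity, phase,
    parent_id, border_flag``. ``cells`` has one row per cell with its fate
    (``entered_mitosis, entry_hours, exit_hours, mitosis_duration_min,
    parent_id, condition``).
    """

    frames: pd.DataFrame
    cells: pd.DataFrame
    condition: str = ""

    def __post_init__(self) -> None:
        ids = self.cells["cell_id"]
        if ids.duplicated().any():
            raise ValueError("cell_ids must be unique within a movie")

    @property
    def n_frames(self) -> int:
        return int(self.frames["frame"].max()) + 1 if len(self.frames) else 0

    def frame_rows(self, frame: int) -> pd.DataFrame:
        return self.frames[self.frames["frame"] == frame]

    def activity_matrix(self) -> pd.DataFrame:
        """Wide cells x frames matrix of true activity (NaN where absent)."""
        return self.frames.pivot(index="cell_id", columns="frame", values="activity")

    def to_csv(self, frames_path, cells_path) -> None:
        self.frames.to_csv(frames_path, index=False)
        self.cells.to_csv(cells_path, index=False)


def _initial_positions(
    n: int, shape: tuple[int, int], margin: float, rng: np.random.Generator
) -> np.ndarray:
    """Jittered-grid placement keeping cells ``margin`` px from the border."""
    H, W = shape
    cols = int(math.ceil(math.sqrt(n * W / H))) or 1
    rows = int(math.ceil(n / cols))
    ys = np.linspace(margin, H - margin, rows)
    xs = np.linspace(margin, W - margin, cols)
    grid = np.array([(y, x) for y in ys for x in xs])[:n]
    jit_y = min((ys[1] - ys[0]) if rows > 1 else margin, 12.0) / 3.0
    jit_x = min((xs[1] - xs[0]) if cols > 1 else margin, 12.0) / 3.0
    grid = grid + rng.normal(0, [jit_y, jit_x], size=grid.shape)
    return np.clip(grid, margin, [H - margin, W - margin])


def _random_walk(
    start: np.ndarray,
    n_steps: int,
    step_sd: float,
    lo: np.ndarray,
    hi: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reflected Gaussian random walk; returns (n_steps, 2) positions."""
    pos = np.empty((n_steps, 2))
    pos[0] = start
    steps = rng.normal(0.0, step_sd, size=(n_steps - 1, 2)) if n_steps > 1 else None
    for i in range(1, n_steps):
        p = pos[i - 1] + steps[i - 1]
        # reflect into [lo, hi]
        for d in range(2):
            if p[d] < lo[d]:
                p[d] = 2 * lo[d] - p[d]
            elif p[d] > hi[d]:
                p[d] = 2 * hi[d] - p[d]
        pos[i] = np.clip(p, lo, hi)
    return pos


def simulate_cohort(
    n_cells: int,
    fate_preset: FatePreset,
    program: ActivityProgram,
    acq: AcquisitionConfig,
    seed: int,
    motion_sd_px: float = 1.0,
    nucleus_radius_px: float = NUCLEUS_RADIUS_PX,
) -> GroundTruthTable:
    """Simulate a ground-truthed cohort movie (no rendering).

    Each cell independently enters mitosis within the preset window with
    probability ``p_mitosis``; mitotic cells divide into two daughters with
    lineage links. Motion is a reflected Gaussian random walk with step SD
    ``motion_sd_px`` per frame.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    # fate Bernoullis come from a dedicated stream so equal seeds give
    # matched (common-random-number) fate draws across condition presets,
    # pairing cohorts for low-variance relative-change estimates
    fate_u = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFA7E])).random(
        n_cells
    )
    H, W = acq.image_size
    dt = acq.frame_interval_min
    T = acq.n_frames
    duration_h = (T - 1) * dt / 60.0
    r_cyto = nucleus_radius_px + CYTO_MARGIN_PX
    lo = np.array([r_cyto, r_cyto])
    hi = np.array([H - 1 - r_cyto, W - 1 - r_cyto])

    starts = _initial_positions(n_cells, (H, W), r_cyto + 2, rng)
    act_ss = np.random.SeedSequence(rng.integers(0, 2**31 - 1))
    act_children = iter(act_ss.spawn(4 * n_cells))

    frame_rows: list[dict] = []
    cell_rows: list[dict] = []
    next_id = n_cells  # daughter ids follow founder ids

    for i in range(n_cells):
        enters = fate_u[i] < fate_preset.p_mitosis
        entry_h = fate_preset.draw_entry_hours(rng) if enters else None
        mito_min = fate_preset.draw_mitosis_minutes(rng) if enters else None
        entry_f = int(round(entry_h * 60.0 / dt)) if enters else None
        exit_f = entry_f + max(1, int(round(mito_min / dt))) if enters else None

        activity = sample_activity(
            program, duration_h, dt, np.random.default_rng(next(act_children))
        )
        last_f = min(exit_f, T - 1) if enters and exit_f is not None else T - 1
        pos = _random_walk(starts[i], last_f + 1, motion_sd_px, lo, hi, rng)

        for f in range(last_f + 1):
            if enters and entry_f is not None and f >= entry_f:
                if exit_f is not None and f == exit_f:
                    phase = "divided"
                else:
                    phase = "mitosis"
            else:
                phase = "interphase"
            mitotic = phase in ("mitosis", "divided")
            radius = nucleus_radius_px * (
                math.sqrt(MITOTIC_AREA_FRACTION) if mitotic else 1.0
            )
            y, x = pos[f]
            frame_rows.append(
                dict(
                    cell_id=i,
                    frame=f,
                    t_min=f * dt,
                    y=y,
                    x=x,
                    radius_px=radius,
                    cyto_radius_px=r_cyto,
                    intensity_scale=MITOTIC_INTENSITY_GAIN if mitotic else 1.0,
                    activity=activity[f],
                    phase=phase,
                    parent_id=-1,
                    border_flag=bool(
                        y - radius < 0 or x - radius < 0 or y + radius > H - 1 or x + radius > W - 1
                    ),
                )
            )
        cell_rows.append(
            dict(
                cell_id=i,
                condition=fate_preset.condition,
                entered_mitosis=enters,
                entry_hours=entry_h if enters else np.nan,
                exit_hours=(exit_f * dt / 60.0) if enters and exit_f is not None else np.nan,
                mitosis_duration_min=mito_min if enters else np.nan,
                parent_id=-1,
                window_hours=fate_preset.window_hours,
            )
        )

        # daughters appear the frame after division, offset along a random axis
        if enters and exit_f is not None and exit_f < T - 1:
            theta = rng.uniform(0, 2 * np.pi)
            off = np.array([np.sin(theta), np.cos(theta)]) * (DAUGHTER_RADIUS_PX * 0.9)
            for sgn in (+1.0, -1.0):
                did = next_id
                next_id += 1
                d_start = np.clip(pos[exit_f] + sgn * off, lo, hi)
                d_act = sample_activity(
                    program, duration_h, dt, np.random.default_rng(next(act_children))
                )
                d_pos = _random_walk(
                    d_start, T - exit_f - 1, motion_sd_px, lo, hi, rng
                )
                for j, f in enumerate(range(exit_f + 1, T)):
                    y, x = d_pos[j]
                    frame_rows.append(
                        dict(
                            cell_id=did,
                            frame=f,
                            t_min=f * dt,
                            y=y,
                            x=x,
                            radius_px=DAUGHTER_RADIUS_PX,
                            cyto_radius_px=r_cyto,
                            intensity_scale=1.0,
                            activity=d_act[f],
                            phase="interphase",
                            parent_id=i,
                            border_flag=bool(
                                y - DAUGHTER_RADIUS_PX < 0
                                or x - DAUGHTER_RADIUS_PX < 0
                                or y + DAUGHTER_RADIUS_PX > H - 1
                                or x + DAUGHTER_RADIUS_PX > W - 1
                            ),
                        )
                    )
                cell_rows.append(
                    dict(
                        cell_id=did,
                        condition=fate_preset.condition,
                        entered_mitosis=False,
                        entry_hours=np.nan,
                        exit_hours=np.nan,
                        mitosis_duration_min=np.nan,
                        parent_id=i,
                        window_hours=fate_preset.window_hours,
                    )
                )

    frames = pd.DataFrame(frame_rows)
    cells = pd.DataFrame(cell_rows)
    return GroundTruthTable(frames=frames, cells=cells, condition=fate_preset.condition)
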