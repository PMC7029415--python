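"""Ready-made synthetic experiments exercising the whole pipeline.

These functions wire the generator to the analysis stages the way the
corresponding live-cell experiments were run: a damage-response cohort
imaged alongside an untreated control at 3-min resolution, segmented,
tracked, ring-quantified, QC'd, normalized and bootstrapped — with the
generator's ground truth retained so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import FatePreset, simulate_cohort
from .config import AcquisitionConfig, PipelineConfig
from .pipeline import MovieResult, process_movie
from .programs import ActivityProgram, basal_stochastic, damage_stochastic
from .render import activity_to_ratio, iter_frames
from .stats import CohortSummary, bootstrap_summary, normalize_to_control, normalize_to_t0, trace_matrix


@dataclass
class DamageExperiment:
    """Result bundle of a control-vs-damage imaging experiment."""

    treated_summary: CohortSummary
    control_summary: CohortSummary
    truth_curve: np.ndarray  # ground-truth standardized treated mean, per frame
    frames: np.ndarray
    times_h: np.ndarray
    coverage: float  # fraction of frames where truth_curve is inside the CI
    treated_result: MovieResult
    control_result: MovieResult


def _truth_standardized_curve(
    treated_truth, control_truth, t0_index: int = 0
) -> np.ndarray:
    """Ground-truth analogue of the measured standardization chain."""
    t_ratio = activity_to_ratio(treated_truth.activity_matrix().to_numpy())
    c_ratio = activity_to_ratio(control_truth.activity_matrix().to_numpy())
    t_norm = t_ratio / t_ratio[:, [t0_index]]
    c_norm = c_ratio / c_ratio[:, [t0_index]]
    control_mean = c_norm.mean(axis=0)
    return (t_norm / control_mean).mean(axis=0)


def run_damage_experiment(
    seed: int,
    n_cells: int = 100,
    hours: float = 12.0,
    image_size: int = 512,
    treated_program: ActivityProgram | None = None,
    control_program: ActivityProgram | None = None,
    acq: AcquisitionConfig | None = None,
    config: PipelineConfig | None = None,
) -> DamageExperiment:
    """Simulate, render and fully analyse a control-vs-damage experiment.

    Both cohorts are rendered as ``n_cells`` non-mitotic cells (the ratio
    analysis considers non-mitotic cells only) over ``hours`` at the default
    3-min interval, processed independently through segmentation, tracking,
    ring quantification and QC, then standardized and bootstrapped. The
    ground-truth standardized treated curve and its CI coverage are
    attached.
    """
    config = config or PipelineConfig()
    rng = np.random.SeedSequence(seed)
    s_ctrl, s_trt, s_rctrl, s_rtrt = [
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in rng.spawn(4)
    ]
    if acq is None:
        acq = AcquisitionConfig(
            n_frames=int(hours * 60 / 3) + 1,
            image_size=(image_size, image_size),
            seed=seed,
        )
    treated_program = treated_program or damage_stochastic()
    control_program = control_program or basal_stochastic()
    no_mitosis = lambda name: FatePreset(name, p_mitosis=0.0)

    truth_ctrl = simulate_cohort(n_cells, no_mitosis("control"), control_program, acq, s_ctrl)
    truth_trt = simulate_cohort(n_cells, no_mitosis("damage"), treated_program, acq, s_trt)
    res_ctrl = process_movie(iter_frames(truth_ctrl, acq, s_rctrl), acq, config)
    res_trt = process_movie(iter_frames(truth_trt, acq, s_rtrt), acq, config)

    cm, _ = normalize_to_t0(trace_matrix(res_ctrl.traces_qc), config.bootstrap.t0_index)
    tm, _ = normalize_to_t0(trace_matrix(res_trt.traces_qc), config.bootstrap.t0_index)
    tstd, cstd = normalize_to_control(tm, cm)
    boot_rng = np.random.default_rng(rng.spawn(1)[0])
    treated_summary = bootstrap_summary(
        tstd, config.bootstrap.n_resamples, config.bootstrap.ci_level, boot_rng
    )
    control_summary = bootstrap_summary(
        cstd, config.bootstrap.n_resamples, config.bootstrap.ci_level, boot_rng
    )

    truth_curve = _truth_standardized_curve(truth_trt, truth_ctrl, config.bootstrap.t0_index)
    frames = treated_summary.frames
    truth_on_grid = truth_curve[np.asarray(frames, dtype=int)]
    coverage = float(np.mean(treated_summary.covers(truth_on_grid)))
    return DamageExperiment(
        treated_summary=treated_summary,
        control_summary=control_summary,
        truth_curve=truth_on_grid,
        frames=np.asarray(frames, dtype=int),
        times_h=np.asarray(frames, dtype=float) * acq.frame_interval_min / 60.0,
        coverage=coverage,
        treated_result=res_trt,
        control_result=res_ctrl,
    )


def bootstrap_coverage(
    n_cohorts: int = 200,
    n_cells: int = 50,
    true_mean: float = 1.0,
    noise_sd: float = 0.3,
    n_resamples: int = 10_000,
    ci_level: float = 95.0,
    seed: int = 0,
) -> float:
    """Empirical CI coverage on i.i.d. Gaussian cohorts with known mean.

    Returns the fraction of cohorts whose default bootstrap CI (percentile,
    cell-resampled) contains the true mean at a single time point.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cohorts):
        values = rng.normal(true_mean, noise_sd, size=(n_cells, 1))
        s = bootstrap_summary(values, n_resamples=n_resamples, ci_level=ci_level, seed=rng)
        hits += bool(s.ci_low[0] <= true_mean <= s.ci_high[0])
    return hits / n_cohorts


def mitotic_fraction(
    condition_preset: FatePreset,
    program: ActivityProgram,
    n_cells: int,
    seed: int,
    window_hours: float | None = None,
) -> float:
    """Simulate a cohort and report its summarized mitotic-entry fraction.

    Runs the generator at truth level (no rendering; image-based mitosis
    detection is validated separately against ground truth) and pushes the
    records through the fate summarizer.
    """
    from .fates import records_from_truth, summarize_fates

    acq = AcquisitionConfig(n_frames=2, image_size=(64, 64), seed=seed)
    truth = simulate_cohort(n_cells, condition_preset, program, acq, seed)
    records = records_from_truth(truth, window_hours)
    out = summarize_fates(records, window_hours)
    return float(out.iloc[0]["fraction_mitotic"])
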