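"""Cohort normalization and bootstrap population statistics.

Single-cell FRET traces are first normalized to their time-zero values,
then every trace (treated and control alike) is divided, per time point, by
the control cohort's mean — so the control cohort is standardized to unity
at each time point and the treated cohort reads as fold-change over
control. The population average and its 95% confidence interval are then
computed by bootstrap, resampling whole cells with replacement 10,000
times and taking percentile intervals of the resample means.

Resampling whole cells (rows) preserves within-trace temporal dependence;
per-time-point value resampling is available via ``resample_unit="value"``
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import BootstrapConfig


def trace_matrix(traces: pd.DataFrame, value: str = "ratio") -> pd.DataFrame:
    """Pivot a tidy trace table into a cells x frames matrix."""
    return traces.pivot(index="cell_id", columns="frame", values=value)


def normalize_to_t0(
    matrix: pd.DataFrame, t0_index: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Divide each trace by its value at time zero.

    Cells with a missing or nonpositive time-zero value are excluded and
    logged. ``t0_index`` defaults to the first column of the matrix (the
    first common imaging frame after treatment).

    Returns (normalized matrix, exclusion log).
    """
    if t0_index is None:
        t0_index = matrix.columns[0]
    if t0_index not in matrix.columns:
        raise ValueError(f"time-zero frame {t0_index} not in matrix")
    t0 = matrix[t0_index]
    bad = ~np.isfinite(t0) | (t0 <= 0)
    log = pd.DataFrame(
        {
            "cell_id": matrix.index[bad],
            "reason": [
                "t0_missing" if not np.isfinite(v) else "t0_nonpositive"
                for v in t0[bad]
            ],
        }
    )
    kept = matrix.loc[~bad]
    return kept.div(kept[t0_index], axis=0), log


def normalize_to_control(
    treated: pd.DataFrame, control: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Divide both cohorts, per time point, by the control cohort's mean.

    Both matrices must already be t0-normalized and share a time grid.
    A nonpositive control mean at any time point is an error (the
    standardization would be meaningless there).
    """
    common = treated.columns.intersection(control.columns)
    treated = treated[common]
    control = control[common]
    cmean = control.mean(axis=0, skipna=True)
    bad = ~np.isfinite(cmean) | (cmean <= 0)
    if bad.any():
        t = common[np.asarray(bad)][0]
        raise ValueError(f"control mean nonpositive or undefined at frame {t}")
    return treated.div(cmean, axis=1), control.div(cmean, axis=1)


@dataclass
class CohortSummary:
    """Bootstrapped cohort mean and confidence band over time."""

    frames: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_cells: int
    n_resamples: int
    ci_level: float
    resample_unit: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "mean": self.mean,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def covers(self, truth: np.ndarray) -> np.ndarray:
        """Per-time-point indicator that ``truth`` lies inside the CI."""
        truth = np.asarray(truth, dtype=float)
        return (truth >= self.ci_low) & (truth <= self.ci_high)


def bootstrap_summary(
    matrix: pd.DataFrame | np.ndarray,
    n_resamples: int = 10_000,
    ci_level: float = 95.0,
    seed: int | np.random.Generator = 0,
    resample_unit: str = "cell",
    chunk: int = 1000,
) -> CohortSummary:
    """Bootstrap the cohort mean trace with percentile confidence intervals.

    The resampling unit is the whole cell (rows resampled with replacement,
    same n) by default; ``resample_unit="value"`` resamples each time
    point's values independently. NaNs are ignored within each resample
    (cells in a gap at a time point simply do not contribute there).
    """
    if isinstance(matrix, pd.DataFrame):
        frames = matrix.columns.to_numpy()
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        frames = np.arange(values.shape[1])
    n, T = values.shape
    if n < 1:
        raise ValueError("empty cohort")
    if resample_unit not in ("cell", "value"):
        raise ValueError("resample_unit must be 'cell' or 'value'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    means = np.empty((n_resamples, T))
    done = 0
    while done < n_resamples:
        b = min(chunk, n_resamples - done)
        if resample_unit == "cell":
            idx = rng.integers(0, n, size=(b, n))
            means[done : done + b] = np.nanmean(values[idx], axis=1)
        else:
            idx = rng.integers(0, n, size=(b, n, T))
            sampled = np.take_along_axis(
                np.broadcast_to(values, (b, n, T)), idx, axis=1
            )
            means[done : done + b] = np.nanmean(sampled, axis=1)
        done += b

    alpha = (100.0 - ci_level) / 2.0
    lo, hi = np.nanpercentile(means, [alpha, 100.0 - alpha], axis=0)
    return CohortSummary(
        frames=frames,
        mean=np.nanmean(means, axis=0),
        ci_low=lo,
        ci_high=hi,
        n_cells=n,
        n_resamples=n_resamples,
        ci_level=ci_level,
        resample_unit=resample_unit,
    )


def cohort_response(
    treated_traces: pd.DataFrame,
    control_traces: pd.DataFrame,
    config: BootstrapConfig | None = None,
    seed: int = 0,
) -> dict:
    """Full normalization + bootstrap for a treated-vs-control experiment.

    Returns a dict with the standardized matrices, both cohort summaries,
    and the t0-exclusion logs.
    """
    config = config or BootstrapConfig()
    tm, tlog = normalize_to_t0(trace_matrix(treated_traces), config.t0_index)
    cm, clog = normalize_to_t0(trace_matrix(control_traces), config.t0_index)
    tstd, cstd = normalize_to_control(tm, cm)
    rng = np.random.default_rng(seed)
    treated_summary = bootstrap_summary(
        tstd, config.n_resamples, config.ci_level, rng, config.resample_unit
    )
    control_summary = bootstrap_summary(
        cstd, config.n_resamples, config.ci_level, rng, config.resample_unit
    )
    return dict(
        treated=tstd,
        control=cstd,
        treated_summary=treated_summary,
        control_summary=control_summary,
        excluded_treated=tlog,
        excluded_control=clog,
    )
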