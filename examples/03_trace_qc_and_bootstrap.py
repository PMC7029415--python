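"""Trace QC, gap healing, normalization and bootstrap cohort statistics.

Builds two synthetic trace cohorts (untreated control vs DNA-damage
response), applies the pruning rules (< 10 h span, contiguous gaps > 3
frames, total gaps > 5%), heals surviving gaps with the 6-point local
median, normalizes to time zero and to the control average, and prints the
bootstrapped population response with 95% confidence intervals.
"""

import numpy as np
import pandas as pd

import erktrace as ek

DT = 3.0  # minutes per frame
N_FRAMES = 241  # 12 h
rng = np.random.default_rng(0)


def synthetic_traces(program, n_cells, seed0):
    rows = []
    for i in range(n_cells):
        a = ek.sample_activity(program, 12.0, DT, seed0 + i)
        ratio = ek.activity_to_ratio(a) + rng.normal(0, 0.004, len(a))
        # knock out a few frames to exercise healing
        missing = rng.choice(N_FRAMES, size=4, replace=False)
        ratio[missing] = np.nan
        for f in range(N_FRAMES):
            rows.append(dict(cell_id=seed0 + i, frame=f, t_min=f * DT,
                             donor_mean=500.0, acceptor_mean=500.0 * ratio[f],
                             ratio=ratio[f], ring_px=300))
    return pd.DataFrame(rows)


control = synthetic_traces(ek.basal_stochastic(), 100, 0)
treated = synthetic_traces(ek.damage_stochastic(), 100, 1000)

kept_c, log_c = ek.qc_filter(control, DT)
kept_t, log_t = ek.qc_filter(treated, DT)
print(f"QC kept {kept_t['cell_id'].nunique()}/100 treated, "
      f"{kept_c['cell_id'].nunique()}/100 control traces "
      f"(rejections: {len(log_t)} treated, {len(log_c)} control)")

healed_c = ek.heal_gaps(kept_c, DT)
healed_t = ek.heal_gaps(kept_t, DT)
print(f"healed gap samples   : {int(healed_t['healed'].sum())} treated, "
      f"{int(healed_c['healed'].sum())} control")

out = ek.cohort_response(healed_t, healed_c, seed=42)
s = out["treated_summary"]
times_h = np.asarray(s.frames, dtype=float) * DT / 60.0
i2h = int(np.argmin(np.abs(times_h - 2.0)))
print(f"bootstrap            : {s.n_resamples} resamples, {s.ci_level:.0f}% CI, "
      f"{s.n_cells} treated cells")
print(f"treated/control at 2 h: {s.mean[i2h]:.4f} "
      f"[{s.ci_low[i2h]:.4f}, {s.ci_high[i2h]:.4f}]")
peak_h = ek.first_peak_time_hours(s.mean - 1.0, DT)
print(f"first peak of the standardized response: {peak_h:.2f} h "
      f"(programmed envelope peak: 2 h; single-cohort estimates at n=100 "
      f"carry ~0.3 h pulse-sampling jitter)")
# Values above 1 with a CI excluding 1 mean the damaged cohort's ERK
# activity is genuinely elevated over control at that time point. Peak
# *timing* converges on the programmed 2 h only as cohorts grow; the
# calibration suite measures it over >=300 cells.
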