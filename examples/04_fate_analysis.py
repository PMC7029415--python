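"""G2/M fate analysis: mitosis detection and per-condition entry fractions.

Part 1 detects mitoses on a small rendered movie (nuclear-area drop
followed by a tracked division) and compares entry times to the
generator's ground truth. Part 2 summarizes mitotic-entry fractions for
the built-in condition presets at cohort scale.
"""

import numpy as np
import pandas as pd

import erktrace as ek

# -- Part 1: detection on a rendered movie ---------------------------------
acq = ek.AcquisitionConfig(
    n_frames=120, image_size=(300, 300), noise=ek.NoiseModel(0.0, 0.0), seed=0
)
preset = ek.FatePreset(
    "demo", p_mitosis=1.0, window_hours=4.0,
    g2_delay_mu_log=float(np.log(2.0)), g2_delay_sigma_log=0.3,
)
truth = ek.simulate_cohort(8, preset, ek.basal_stochastic(), acq, seed=7)
stack = ek.render_frames(truth, acq, seed=None)
result = ek.process_movie(stack, acq)
records = ek.records_from_tracker(result.tracker, "demo", acq.frame_interval_min, 24.0)
detected = records[np.isfinite(records["entry_hours"])]
print(f"programmed mitoses  : {int(truth.cells['entered_mitosis'].sum())}")
print(f"detected entries    : {len(detected)} "
      f"(excluded as ambiguous: {(records['excluded_reason'] != '').sum()})")
print("detected entry times (h):", np.round(sorted(detected["entry_hours"]), 2))
print("true entry times (h)    :",
      np.round(sorted(truth.cells.loc[truth.cells.parent_id < 0, 'entry_hours'].dropna()), 2))

# -- Part 2: cohort-scale fractions per condition ---------------------------
rows = []
for cond in ("control", "ncs", "ncs+u0126", "ncs+hrg"):
    p = ek.FATE_PRESETS[cond]
    acq2 = ek.AcquisitionConfig(n_frames=2, image_size=(64, 64), seed=0)
    t = ek.simulate_cohort(2000, p, ek.program_for_condition(cond), acq2, seed=11)
    rows.append(ek.records_from_truth(t))
summary = ek.summarize_fates(pd.concat(rows, ignore_index=True))
print()
print(summary[["condition", "n_eligible", "n_entered", "fraction_mitotic",
               "window_hours", "mean_mitosis_min"]].to_string(index=False))
# Expected pattern: ~40% of untreated cells cycle within 24 h; DNA damage
# (ncs) drops this to ~15%; MEK inhibition on top of damage below 10%;
# sustained mitogen on top of damage raises it by ~50% relative (12-h window).
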