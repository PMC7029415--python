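"""Full in-silico damage experiment: render, analyse, score recovery.

Simulates a control and a DNA-damage cohort (100 cells each, 12 h at
3-min frames — the scale of the corresponding live-cell experiments),
renders both as noisy three-channel movies, pushes them through segmentation -> tracking ->
rings -> QC -> normalization -> bootstrap, and scores the result against
the generator's ground truth.
"""

import numpy as np

import erktrace as ek

exp = ek.run_damage_experiment(seed=5, n_cells=100, hours=12.0, image_size=512)  # ~2 min

s = exp.treated_summary
print(f"cells surviving tracking+QC : {s.n_cells} treated, "
      f"{exp.control_summary.n_cells} control")
print(f"truth curve inside 95% CI at {100 * exp.coverage:.1f}% of time points")
peak_h = ek.first_peak_time_hours(s.mean - 1.0, 3.0)
print(f"first peak of treated/control response: {peak_h:.2f} h (programmed: 2 h)")
sel = (exp.times_h >= 1.5) & (exp.times_h <= 2.5)
print(f"CI excludes unity around the peak: "
      f"{100 * float((s.ci_low[sel] > 1).mean()):.0f}% of the 1.5-2.5 h window")
i2h = int(np.argmin(np.abs(exp.times_h - 2.0)))
print(f"standardized response at 2 h: {s.mean[i2h]:.4f} "
      f"[{s.ci_low[i2h]:.4f}, {s.ci_high[i2h]:.4f}] "
      f"(ground truth {exp.truth_curve[i2h]:.4f})")
# The bootstrap band should contain the ground-truth standardized ratio
# curve nearly everywhere, and the damage cohort should rise significantly
# above the control baseline around the programmed 2-h pulse-rate peak.
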