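# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `erktrace`. Conventions throughout: coordinates are 0-based
(row, col); frame indices are 0-based; areas are whole pixels; times are
minutes within traces and hours for cohort-level quantities; the default
frame interval is 3 min and the default pixel size 0.55 µm (so the 100-px
debris cutoff corresponds to ~30 µm²).

## 1. Single-cell ERK-activity programs

A cell's ERK activity a(t) ≥ 0 (arbitrary units) is a baseline plus
regime-specific components:

- **basal_stochastic** — discrete pulses at constant rate λ0
  (default 0.5 events/h). Pulses are cos²-shaped, full width 30 min,
  amplitude 1.0, *centred* on their event times. Pulse onsets are drawn
  from a Poisson process; the expected pulse count over T hours is λ0·T.
- **damage_stochastic** — the same pulses under a damped-oscillation rate
  envelope λ(t) = λ0·(1 + A·e^(−t/τ)·max(0, sin(πt/P))²) with gain A = 6,
  decay τ = 2 h and period P = 5.5 h. The first envelope maximum sits at
  (P/π)·atan(2πτ/P) ≈ 2.03 h and the second ≈ 7.5 h, reproducing the
  population-level phosphorylation peak ~2 h after damage with a weaker
  echo 5–6 h later. Sampling uses Poisson thinning at λmax = λ0(1+A).
- **transient_gf** — one deterministic sin²-shaped response of duration
  30 min (EGF-like); activity returns *exactly* to baseline afterwards.
- **sustained_gf** — a plateau of +0.6 units lasting 8 h (HRG-like).

Centring pulses on their event times keeps the population-mean activity
phase-aligned with the rate envelope: the mean is baseline +
amplitude·(λ ⊛ kernel), and a symmetric kernel does not shift the peak.

**Why these pulse statistics.** The published cohort comparison separates
treated from control bootstrap bands at n ≈ 100–130 cells. With shot-noise
pulses, the standardized treated elevation at the peak is
k·Δλ·d/2 against a per-cell SD ≈ k·√(0.375·λ·d) (d = pulse width in
hours, k the ratio gain). The defaults (d = 0.5 h, λ peak ≈ 1.4/h) give a
~4.4-SE elevation at n = 100 — a clearly separated band, as observed —
while keeping single-pulse ratio excursions within the sensor's realistic
~25% dynamic range. These values were fixed from this power calculation;
no per-cell pulse statistics are published for this sensor/cell-line
combination, so they are stated assumptions, not fits.

## 2. Fate presets

Each condition preset draws mitotic entry as a Bernoulli with probability
p within its analysis window (24 h; 12 h for mitogen conditions, which can
also push G1 cells into cycle): control 0.40, damage (NCS) 0.15,
damage+MEK-inhibitor 0.08, damage+sustained-mitogen 0.225 (a 50% relative
increase over damage alone), egf/hrg alone 0.40. Entry delays are
lognormal (median 8 h, σ_log = 0.6) truncated to the window; mitosis
lengths are normal (45 ± 10 min, floored at 15 min). All distributions are
parametric and overridable.

Fate Bernoullis are drawn from a dedicated seed-derived stream, so two
cohorts simulated with the same seed under different presets have *paired*
fate draws (common random numbers). Relative-change estimates between
conditions then have roughly half the standard error of independently
seeded cohorts; with n = 2000 per arm the paired relative-increase
estimator has SD ≈ 5–6 percentage points.

## 3. Rendering

Cells are hard disks: nucleus radius 10 px (area ≈ 314 px), cytoplasm
radius 22 px. During mitosis the nuclear area contracts to 40% (radius
×√0.4, still above the 100-px debris filter by construction) and brightens
2×; at exit two daughter nuclei (radius 8 px) appear symmetrically about
the division site. Motion is a reflected Gaussian random walk, step SD
1 px/frame, so maximum-overlap tracking is valid at 3-min sampling.

The donor channel is uniform (500 units) over the cell disk and the
acceptor is 500·r(a) with r(a) = 1.0 + 0.25·a, so the acceptor/donor ratio
is exact per pixel; painting replaces rather than adds, so overlapping
cells do not mix ratios. Background (10 units) exists only outside cells.
With noise disabled, an ideal ring measurement recovers r(a(t)) to machine
precision — the key oracle for the measurement chain. Noise is Poisson
shot noise (counts ≈ intensity) plus Gaussian read noise (SD 2) by
default. Equal seeds give bit-identical truth tables and stacks.

## 4. Segmentation and tracking

The 2×2 median has no unique centre or median; this implementation fixes
the *lower* median (2nd smallest of 4), top-left anchor and replicate
padding. Thresholding is Otsu by default ("simple intensity thresholding"
leaves the method open; a fixed threshold is available in config).
Nuclei are split by watershed seeded at distance-transform maxima
(min seed distance 5 px). The territory image assigns every pixel to its
nearest nucleus — equivalently, the watershed of the nucleus distance map
over the whole frame — which guarantees nuclei lie inside their own
territories and territories partition the frame.

Tracking resolves, per frame pair: inheritance by maximal pixel overlap;
double-claimed parents (larger overlap keeps the id, the other claimant
becomes a new `division_candidate`); zero-overlap objects (new ids);
unclaimed parents (gap, re-linkable against the last known mask for up to
3 frames). Ties break to the lower id for determinism. Links whose top-two
overlaps differ by < 10% are flagged `ambiguous_link`; flagged and
border-touching cells are excluded from downstream quantification — the
automated stand-in for the original manual curation, with an auditable
log instead of interactive edits.

## 5. Ring quantification

The ring is the set of territory pixels whose Euclidean distance to the
nucleus lies in (1, 6] — "1 px away, 5 px thick" — excluding the nucleus;
a Chebyshev (chessboard) band is available behind a config switch since
the metric is not dictated by the phrase. Because territories are the
nearest-nucleus partition, a single distance transform of the all-nuclei
background yields every cell's ring at once; the batch path is exactly
equivalent to the per-cell definition (tested). Empty rings and
nonpositive donor means yield NaN ratios with flags, never exceptions.

## 6. Trace QC and healing

A trace is pruned iff (span < 10 h) OR (a contiguous gap > 3 frames) OR
(missing/span frames > 5%), with the span measured first-to-last
observation and all three comparisons strict — matching the stated
inequality directions literally, so a 10.0-h trace, a 3-frame gap and
exactly 5% missing all survive. Each rejection is logged with its
triggering rule. Healing replaces each missing sample with the median of
its 6 nearest observed neighbours (3 per side, borrowing across at trace
ends; even-length median = mean of the middle two). Observed samples are
never modified, and pruning always precedes healing.

## 7. Cohort statistics

Traces are divided by their time-zero value (cells missing t0 or with
nonpositive t0 are excluded and logged; "time zero" is the first common
frame, configurable). All traces are then divided per time point by the
control cohort's mean, making the control mean identically 1. The
bootstrap resamples whole cells with replacement (same n), 10,000 times,
and reports the mean of resample means with a percentile 95% CI.
Percentile (not BCa) is the simplest faithful reading of "95% confidence
intervals" and is seed-reproducible. Cell-wise resampling preserves
within-trace dependence; per-time-point value resampling is available via
`resample_unit="value"` for comparison. Empirical coverage on Gaussian
cohorts of 50 traces is ~93–96% (the familiar mild percentile-bootstrap
undercoverage at moderate n).

## 8. Peak timing

The "first peak" of a population-mean activity series is located on a
45-min moving mean (first local maximum with prominence ≥ 30% of range)
and then refined by a quadratic least-squares fit to the conventional
15-min-smoothed series within ±1 h. The two-stage estimator is needed
because pulse shot noise splits the broad population peak into spurious
local maxima: a plain argmax of the 15-min-smoothed mean jitters by
±0.3 h at n = 400 cells, while the refined estimator is stable to
±0.08 h at n = 400 and ±0.04 h at n = 1600.

## 9. Fate extraction

Mitotic entry is declared at the first frame where nuclear area falls
below 60% of its trailing 10-frame median AND a tracked division follows
within 20 frames; the split frame is the exit. Area drops without a
subsequent split are flagged ambiguous and excluded from fractions. The
thresholds are config entries validated only against synthetic ground
truth — the original study scored mitosis by eye, so this rule is this
package's operationalization. On noise-free synthetic movies, detected
entries and durations match programmed values within ±2 frames; mitoses
longer than the 20-frame split horizon (~7% at the default duration
distribution) are excluded as ambiguous rather than mis-scored.
Entry fractions are reported over eligible (unflagged) founder cells
within the window; shrinking the window can only decrease the fraction.

## 10. Problem sizes used in validation

The test suite exercises: oracle instances of a few hundred pixels
(exact, brute-force comparisons); a 6-cell noise-free 20-frame movie for
measurement exactness; an 8-cell 120-frame movie for mitosis detection;
200×50 Gaussian cohorts for CI calibration; 400–1600 cells for peak
timing; 1000–2000-cell truth-level cohorts for fate fractions; and a
rendered 2×100-cell, 12-h (241-frame, 512²) experiment for end-to-end
recovery. These sizes match the corresponding live-cell experiments
(n ≈ 100–130 cells per cohort) where the study reports them.

## 11. What the generator does and does not emulate

Emulated: bright nuclei on dim cytoplasm, 3-min sampling, stochastic
pulses with a damage-modulated rate, transient/sustained growth-factor
responses, cell motion, nuclear condensation + division, shot + read
noise, condition-dependent mitotic-entry probabilities. Not emulated:
photobleaching, spectral bleed-through, chromatic shift, 3-D effects,
uneven illumination, cell shape beyond disks, lineage beyond one
division, apoptosis/senescence. Passing tests therefore demonstrate the
*analysis chain* is correct and calibrated under these idealized imaging
physics; they do not certify segmentation robustness on real morphologies,
where thresholding and watershed parameters typically need retuning.

## 12. Numerical choices

Otsu on a constant frame would be undefined → empty label map, not an
error. Watershed plateaus can leave unclaimed foreground → kept as extra
labels. Lognormal entry delays are resampled (≤1000 draws) to truncate to
the window, falling back to uniform. Bootstrap resampling is chunked
(1000 resamples at a time) to bound memory. Renders are float64 in memory
(exactness oracles) and float32 on disk. All RNG flows through
`numpy.random.Generator` seeded from explicit integers or spawned
`SeedSequence` children; derived seeds stay below 2^31.
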