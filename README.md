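# erktrace

Single-cell analysis of FRET-biosensor time-lapse movies: nuclear
segmentation and overlap tracking, perinuclear-ring ERK-activity
quantification, trace quality control, bootstrap cohort statistics, and
G2/M checkpoint fate analysis — plus a ground-truthed synthetic movie
generator so every stage is testable without experimental data.

## Who this is for

Quantitative cell biologists analysing ratiometric kinase-activity
reporters (e.g. the EKAREV ERK sensor) in time-lapse microscopy: movies
with a nuclear marker channel (H2B-mCherry role) and a FRET donor/acceptor
pair (ECFP/YPet roles), acquired at a few minutes per frame. The package
reimplements, as a tested reusable library, the in-house analysis chain
used to study how MAPK/ERK signalling dynamics gate the DNA-damage G2
checkpoint: stochastic ERK pulses after damage (population-mean activity
peaking ~2 h post-treatment), transient (minutes) versus sustained (hours)
growth-factor responses, and condition-dependent mitotic-entry fractions.

## The pipeline

For each movie, per frame:

1. **Denoise** the nuclear channel with a gentle 2×2 median filter
   (lower median, fixed anchor and padding, so results are bit-reproducible).
2. **Segment** nuclei by intensity thresholding (Otsu by default) followed
   by watershedding; discard debris < 100 px (~30 µm²). Every pixel of the
   frame is also assigned to its nearest nucleus — the cell's *territory*.
3. **Track** by maximum area overlap: each nucleus at *t+1* inherits the
   identity of the *t*-nucleus it overlaps most; double-claimed cells mark
   division candidates; gaps up to 3 frames are re-linked.
4. **Quantify** ERK activity as the acceptor/donor ratio over a
   perinuclear ring 1 px away from the nucleus and 5 px thick, restricted
   to the cell's own territory.
5. **QC**: prune traces shorter than 10 h, with contiguous gaps > 3 frames
   or total gaps > 5%; heal surviving gaps with a 6-point local median.
6. **Cohort statistics**: normalize each trace to its time-zero value,
   then every trace to the control-cohort average per time point; report
   the bootstrap mean and 95% percentile CI from 10,000 cell-wise
   resamples. The control band sits at 1 by construction; the treated band
   reads as fold-change over control.
7. **Fates**: detect mitotic entry (nuclear area drop below 60% of its
   trailing median followed by a tracked division within 20 frames) and
   summarize the fraction of cells entering mitosis within a 24-h window
   (12 h for mitogen conditions).

The synthetic generator simulates single-cell activity programs
(`basal_stochastic`, `damage_stochastic`, `transient_gf`, `sustained_gf`),
draws per-cell fates from condition presets calibrated to the reported
fractions (~40% of untreated cells cycling within 24 h, ~15% after DNA
damage, <10% with MEK inhibition, +50% relative with sustained mitogen),
and renders three-channel movies in which the noise-free ring ratio equals
`r(a) = r0 + k·a` of the true activity exactly.

## Worked example

`examples/05_full_damage_experiment.py` simulates a control and a
DNA-damage cohort (100 cells each, 12 h at 3-min frames), renders both as
noisy movies, runs the full pipeline, and scores recovery against the
generator's ground truth:

```
$ python examples/05_full_damage_experiment.py
cells surviving tracking+QC : 95 treated, 87 control
truth curve inside 95% CI at 100.0% of time points
first peak of treated/control response: 1.87 h (programmed: 2 h)
CI excludes unity around the peak: 100% of the 1.5-2.5 h window
standardized response at 2 h: 1.0569 [1.0300, 1.0884] (ground truth 1.0576)
```

Reading: of 100 simulated cells per cohort, 95/87 survive tracking and
trace QC. The bootstrap band around the measured treated/control curve
contains the ground-truth standardized ratio at every time point; the
damage cohort's response rises ~5.7% above the control baseline around
2 h — significantly (the CI excludes 1) — and the detected peak time
matches the programmed 2-h pulse-rate maximum within pulse-sampling
jitter. The remaining examples each demonstrate one capability:
simulation + TIFF/CSV export (01), segmentation/tracking/ring exactness
(02), QC + bootstrap on trace cohorts (03), and fate analysis (04).

A thin CLI covers the two shell-facing workflows:

```bash
erktrace simulate --condition ncs --n-cells 50 --hours 12 --seed 1 --out out/
erktrace fates --records records.csv --window 24 --out out/
```

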