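# Methods

This note documents the models and procedures implemented in `zfscreen`,
the parameters that matter, what the synthetic phantoms do and do not
emulate, and the numerical choices made where the design was open.

## Cardiotoxicity video analysis

### Signal model

A heart video is a stack of T grayscale frames (T ≥ 64; the platform's
nominal acquisition is 512 frames at 30 fps). Frames are summarised by a
square tiling (default 8×8 px, remainder tiles at the bottom/right edges);
per-tile means suppress pixel noise while retaining chamber-scale motion.
With `m(t)` the tile-mean vector of frame *t* and `m̄` its temporal mean
("homogeneous zones" reference):

* **ED signal**: `ed[t] = ||m(t) − m̄||₂` — periodic at the heart rate for a
  beating heart, identically zero for a constant video, and linear in
  global intensity rescaling.
* **OF signal**: `of[t] = mean|m(t) − m̄|`, a brightness-movement measure;
  its max−min amplitude separates beating hearts (units of intensity,
  typically ≫ 1) from motionless ones (noise floor ≪ 1).

### Quality control

Embryos that drift or twitch during recording corrupt the rate estimate.
The mean-removed ED power spectrum is computed (plain rFFT, no window) and
the video is flagged not-analysable when more than `drift_threshold`
(default 0.5) of the total power lies below 0.3 Hz — slow whole-frame
motion incompatible with a stationary embryo. A motionless video passes QC;
arrest is decided downstream from the OF amplitude.

### Modified periodogram

The ED series is mean-removed, Hann-windowed, zero-padded to
`pad_factor × T` (default ×8, grid spacing `fps/(pad·T)` ≈ 0.0073 Hz at the
nominal acquisition) and restricted to the physiological embryonic band
0.5–8 Hz (power outside the band zeroed). Mean removal and the band's lower
edge suppress DC leakage and residual drift; the window bounds leakage from
strong lines; padding gives sub-bin peak localisation.

### Peak significance and classification

Candidate peaks are in-band local maxima with power ≥ `noise_mult` (8) times
the in-band median. A candidate is **significant** when it also reaches
`rel_thresh` (0.25) of the dominant in-band power *and* the spectrum is
concentrated: the dominant bin must hold ≥ `min_dominant_share` (1.5 %) of
the total in-band power. The concentration gate is required because the
largest bin of a featureless noise spectrum exceeds any fixed
median-multiple by extreme-value statistics in a sizeable fraction of
recordings (measured ≈ 48 % of seeds at `noise_mult = 8`), whereas a true
rhythm concentrates power into a narrow line: measured dominant-bin shares
are ≤ 1.1 % for pure noise and ≥ 1.9 % for the weakest phantom rhythms, so
1.5 % separates the two populations. Peaks at integer multiples (±3 %
relative) of the lowest significant frequency are pruned as harmonics
unless they independently reach `rel_thresh` of the dominant power — the
escape hatch that lets a genuine second rhythm at a 2:1 frequency ratio
survive pruning, resolving the ambiguity that a 2:1 pattern is formally a
harmonic series.

Classification precedence: OF amplitude below the arrest threshold →
cardiac arrest (rate 0); ≥ 2 significant frequencies → 2:1 arrhythmia; a
single significant frequency is the heart rate, bradycardia when
`15 × rate < 36.5` beats per 15 s (strict inequality; the ROC-derived
cutoff applies on the 15-second scale), else no effect. Motion above the
arrest threshold with no significant peak yields a NO_CALL flag and the
embryo is excluded from group statistics.

The **arrest threshold** is calibrated, not hand-set: 5× the OF amplitude
of a pure-noise video simulated at the configured noise SD (default 2.0 on
the 8-bit-like scale) with a fixed internal seed. At the defaults this is
≈ 0.65, against beating-phantom amplitudes of 5–7 — a margin of roughly an
order of magnitude on both sides.

### Known deviations from ideal invariances

With the Hann window the periodogram is not exactly invariant under a
circular time shift of the frames; the category is unchanged and the rate
estimate moves by at most one padded-DFT bin, which is how the test asserts
it.

## Angiogenesis image analysis

Embryos are imaged anterior-left, dorsal-up (a config flag can flip
left/right). The pipeline:

1. **Segmentation** — a 3-class multi-Otsu threshold (background / dim body
   fluorescence / bright vessels), taking everything above the lowest
   threshold as foreground, falling back to ordinary Otsu for bimodal
   images; closing (disk 3); largest 8-connected component. Length is the
   extent along the principal axis of the component's coordinate
   covariance.
2. **Head/tail split** — the column-wise thickness profile peaks at the
   yolk bulge; the tail ROI starts one column posterior to the (rightmost)
   global maximum and runs to the posterior tip. A profile without a clear
   bulge (peak < 1.15× the posterior-40 % median thickness, or peak in the
   last 10 % of columns) falls back to the posterior 60 % of the embryo
   with a logged warning.
3. **Vessel mask** — white top-hat (disk radius 12 px, just above vessel
   width) removes smooth body fluorescence; Otsu on the residual, with a
   floor of 6× the median absolute deviation so pure-noise ROIs binarise to
   (near-)empty; closing (disk 1); removal of specks ≤ 7 px; components are
   kept only if wide enough to be an axial vessel (≥ 25 % of ROI width —
   DA/PCV, DLAV, or a DLAV fragment) or 8-connected to one after 1-px
   dilation; everything else is stray fluorescence and discarded.
4. **Enclosed areas** — the holes of the vessel mask: 4-connected
   background components inside the ROI that do not touch the ROI border
   (4-connectivity for background against 8-connectivity for vessels, the
   standard complementary pairing). Incomplete ladders or a missing DLAV
   enclose nothing by construction.
5. **ISV counts** — rail bands are rows whose vessel occupancy spans ≥ 50 %
   of the ROI width; the topmost contiguous band is the DLAV, the
   bottommost the DA/PCV, and they must be separated by ≥ 4 rows (otherwise
   counts are reported missing and the embryo flagged). After removing the
   bands, remaining components are ISV candidates; *total* requires a
   vertical span ≥ 20 % of the rail separation, *complete* requires ≥ 90 %
   plus contact with the DLAV band. The 20 %/90 % cutoffs are not derived
   from data; they are exposed in the config.

Vessel width is not separately quantified; thinner vessels register
through their effect on the enclosed area (and, at the extreme, through
DLAV gaps).

**Group calls.** Enclosed-area means are compared by one-way ANOVA with
Dunnett's many-to-one adjustment against the vehicle control; a group is
INHIBITED when its adjusted p < α (default 0.05) and its mean is below
control. Mean total/complete ISV counts accompany the call as the deeper
per-vessel readout. Groups need ≥ 10 analysable embryos; smaller groups are
flagged and excluded from testing. Heart-rate comparisons use Mann–Whitney
instead, because embryonic heart rate is distinctly non-Gaussian
(left-skewed).

## Statistics layer

* **Mann–Whitney U** — exact null distribution when the smaller group has
  n ≤ 8 and the data are tie-free, otherwise the normal approximation with
  tie and continuity corrections (scipy backend). Verified against a full
  enumeration oracle for all group sizes ≤ 6.
* **Welch t** — unequal-variance t with Satterthwaite degrees of freedom;
  the zero-variance/equal-means degenerate case returns p = 1.
* **ANOVA + Dunnett** — omnibus F plus per-group two-sided many-to-one
  comparisons using the pooled ANOVA error. Adjusted p-values come from a
  Monte-Carlo sample of the max-|T| statistic of the correlated
  multivariate t (correlation λᵢλⱼ with λᵢ = √(nᵢ/(nᵢ+n₀))), 2×10⁵ draws
  with a fixed internal seed, cached per design, so results are
  reproducible and arbitrary group sizes are supported; adjusted p is
  floored at the raw p. Zero pooled variance is handled as a degenerate
  perfect separation. The k = 1 case reduces to the pooled two-sample t
  within Monte-Carlo tolerance, and the implementation is cross-checked
  against scipy's analytic Dunnett in the tests. Family-wise type-I error
  calibrates to 0.05 within simulation noise.
* **Four-parameter logistic (IC50)** — `bottom + (top−bottom)/(1+(d/ic50)^h)`
  fit by least squares on log-dose; starting values from the response range
  and the midpoint-crossing dose, slope sign from the dose–response
  correlation; ≥ 5 distinct positive doses required; non-convergence and
  flat (unidentifiable) responses return a flagged result instead of
  raising. IC50 standard error via the delta method from log-IC50.
* **ROC threshold** — empirical sweep over midpoints of adjacent pooled
  values plus the extremes, returning the Youden-optimal threshold with its
  sensitivity/specificity; the positive calling direction (below vs above
  threshold) is inferred from the sample means, matching the bradycardia
  use where low rates are positive.
* **Confusion summary** — TP/TN/FN/FP tallies with
  `detection_rate_positives = 100·TP/(TP+FN)` and
  `correct_rejection_rate = 100·TN/(TN+FP)`. The screening reports this
  package follows label the first "specificity" and the second
  "sensitivity" — opposite to the epidemiological convention — so both
  neutral names and conventional aliases are exposed. Rates with empty
  denominators are `None`, not 0. Verdict assignment uses an explicit
  match table transcribed from the validation panels (notably accepting a
  known bradycardia inducer observed as cardiac arrest as a true positive,
  while a QT-prolongation inducer observed only as bradycardia is a miss)
  rather than a general severity rule, because the panel itself defines the
  accepted cross-severity matches.

## Phantom generators

All phantoms are seeded (`numpy.random.default_rng`), bit-identical per
seed, and their ground truth is computed from the generator parameters —
never from the rendered pixels — so truth is an oracle independent of the
analysis path.

**Heart videos.** Two anti-aliased discs (atrium, ventricle) over a static
dim body; each disc's radius contracts by `motion_amp` (default 0.35) times
a contraction waveform — a cubed raised-cosine pulse (brief systole, long
diastole) plus a 0.5-weight second-harmonic overtone, with the ventricle
lagging the atrium by 0.18 of its cycle (the atrio-ventricular delay).
The waveform constants were fixed by direct spectral measurement at design
time so that the ED trace of a single-rhythm phantom is near-sinusoidal
(strongest harmonic < 15 % of the fundamental's periodogram power across
1–4 Hz and motion amplitudes 0.25–0.45), matching the near-sinusoidal ED
traces of healthy hearts, while a 2:1 phantom (atrium at 2f, ventricle at
f, comparable amplitudes) yields two significant components. Gaussian
sensor noise (default SD 2.0) and an optional whole-scene linear drift (for
QC tests) complete the model. Chamber motion is encoded as area
oscillation rather than translation so the ED signal responds the way real
cardiac videos do. Regimes: control (f_a = f_v), 2:1 block (f_a = 2 f_v),
arrest (`motion_amp = 0`).

**Vessel images.** 256×512 px canvas: head disc, horizontal trunk, ventral
yolk ellipse at `yolk_position_frac` of the embryo length (default 0.30);
bright vessels in the tail: DA/PCV band (8 px), DLAV rail (6 px, minus
configurable gaps), and `n_isvs` evenly spaced rungs (default width 4 px),
complete rungs spanning DA→DLAV and incomplete ones stopping at ~55 % of
the rail separation. Intensities: background 10, body 70, vessels 200, plus
Gaussian noise. Ground-truth enclosed-region count = number of consecutive
complete-ISV pairs whose DLAV span is gap-free (a dangling incomplete rung
does not split a 4-connected hole).

**Dose–response tables.** The 4PL curve plus Gaussian noise; at
`dose = ic50` the noiseless response is exactly the midpoint.

### What the phantoms do not emulate

No pigmentation, autofocus failures, optical blur, uneven illumination,
heart translation within the field (beyond the drift used for QC), chamber
shape change, vessel curvature or width variation, or body deformation.
Passing the phantom suites therefore demonstrates the correctness of the
signal path and the topological readout under controlled conditions, not
performance on real microscope data; the published real-video and
real-image agreement rates of such assays depend on embryo behaviour and
are outside what synthetic data can certify.

## Problem sizes

The test and acceptance suites use: 200 noiseless + 400 noisy heart videos
(512 frames, 64×64 px) for frequency recovery and 4-way classification;
exhaustive ladder topologies k = 1…15 plus 100 randomized vessel phantoms
(256×512 px); full Mann–Whitney enumeration for all group sizes ≤ 6; 500
null simulations for the Dunnett type-I calibration. The standalone
acceptance script runs scaled versions (50 recovery / 100 classification
videos, 50 vessel phantoms, 300 null simulations), sizes chosen to keep a
single-CPU run in the minutes range while leaving the binomial noise on the
reported rates well below the margins being checked.
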