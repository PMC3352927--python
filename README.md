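# zfscreen

Automated image analysis for zebrafish-embryo chemical screening: a
**cardiotoxicity assay** that turns fluorescence videos of beating embryonic
hearts into heart-rate and arrhythmia calls, and an **angiogenesis assay**
that quantifies intersegmental-vessel (ISV) development from trunk
fluorescence images — together with the screening statistics used to call
compounds and validate both assays.

It is written for screening groups using transgenic reporter lines
(cardiac-promoter GFP for the heart, vascular-promoter GFP for the trunk
vessels) who need a reproducible, scriptable readout per well of a
microtiter plate, plus seeded synthetic phantoms with exact ground truth for
testing every analysis stage without any real imaging data.

## The two readouts

**Cardio.** A video of the beating heart (nominally 512 frames at 30 fps)
is reduced to the Euclidean-distance (ED) signal: each frame is summarised
by the mean intensities of small square tiles, and

```
ed[t] = || m(t) − m̄ ||₂,    of[t] = mean |m(t) − m̄|
```

where `m(t)` is the tile vector of frame *t* and `m̄` the temporal-mean
reference. Cardiac motion makes `ed` periodic at the heart rate. A modified
periodogram (mean removal, Hann window, ×8 zero padding, physiological band
0.5–8 Hz) is scanned for significant peaks; the embryo is then classified:

| condition | call |
|---|---|
| OF amplitude below the arrest threshold | cardiac arrest |
| ≥ 2 significant frequencies | 2:1 atrio-ventricular arrhythmia |
| rate < 36.5 beats / 15 s | bradycardia |
| otherwise | no effect |

The 2:1 arrhythmia (atrium beating at twice the ventricular rate) is the
zebrafish signature of ERG potassium-channel blockade, the canonical
QT-prolongation mechanism. Videos where the embryo drifted during recording
are flagged not-analysable by a low-frequency ED-power criterion.

**Angio.** From a trunk image the embryo is segmented, the tail region of
interest is split off posterior to the yolk bulge, a vessel mask is
extracted (top-hat background subtraction, automatic threshold, removal of
debris not connected to the axial vessels), and the readout is the **area
enclosed** between the ISVs, the dorsal longitudinal anastomotic vessel
(DLAV) and the dorsal aorta / posterior cardinal vein — the topological
holes of the vessel mask. A ladder of *k* complete, contiguous ISVs under a
spanning DLAV encloses exactly *k − 1* cells; incomplete vessels or a
missing DLAV enclose nothing, which makes the measure sensitive to
anti-angiogenic effects. Total and complete ISV counts ride along, and
treated groups are called inhibited by ANOVA + Dunnett against the vehicle
control, with four-parameter-logistic IC50 fits over concentration series.

## Worked example

```python
from zfscreen.phantom_generator import HeartPhantomParams, make_heart_video
from zfscreen.cardio_analysis import (
    analyze_video, calibrate_arrest_threshold, CardioThresholds,
)

thr = CardioThresholds(arrest_of_amplitude=calibrate_arrest_threshold(2.0))
stack, truth = make_heart_video(HeartPhantomParams(
    f_atrial_hz=2.6, f_ventricular_hz=1.3, amp_ratio=0.7, noise_sd=2.0, seed=42,
))
res = analyze_video(stack, thr)
print(res.category.value, round(res.heart_rate_hz, 3), round(res.beats_per_15s, 1))
```

prints `Arrhythmia 2:1 1.304 19.6`: the phantom's atrium beats at 2.6 Hz and
its ventricle at 1.3 Hz, the periodogram shows two significant components,
and the reported rate is the first (ventricular) significant frequency —
1.304 Hz ≈ 19.6 beats per 15 s. For the angiogenesis side,

```python
from zfscreen.phantom_generator import VesselPhantomParams, make_vessel_image
from zfscreen.angio_analysis import analyze_image

img, _ = make_vessel_image(VesselPhantomParams(
    n_isvs=10, complete_flags=(True,) * 7 + (False,) * 3, seed=42,
))
q = analyze_image(img)
print(q.enclosed_area_px, q.n_enclosed_regions, q.total_isvs, q.complete_isvs)
```

prints `10555 6 10 7`: ten ISVs are present, seven reach the DLAV, and the
seven complete rungs enclose six cells totalling 10 555 px².

## Command line

```sh
zfscreen simulate plate --out demo --seed 1 --n 20   # phantom plate + layout
zfscreen cardio-run --video-dir demo --layout demo/layout.txt --out results
zfscreen angio-run  --plate-dir imgs --layout layout.txt --out results
zfscreen validate --table src/zfscreen/data/table2_cardio.csv
zfscreen stats cv --csv rates.csv --column beats_per_15s
```

Plate runs write a per-embryo CSV, a per-group summary CSV and a JSON
manifest carrying the configuration hash and seed. All tunables (tiling,
band, significance thresholds, the 36.5 beats/15 s bradycardia cutoff, the
angio morphology parameters, alpha) live in a plain-text key–value config
(`AssayConfig`).

## Validation panels

The package ships transcriptions of the assay-validation panels as CSV
fixtures (`zfscreen/data/`): a 35-compound cardiotoxicity panel with known
human cardiac effects, a 6-condition repeatability table of inter-assay
coefficients of variation, and a 28-compound angiogenesis panel (18 known
inhibitors, 10 inactive compounds). Every printed TP/TN/FN/FP verdict is
re-derivable from the (human effect, observed effect) label pair via
`plate_model.assign_verdict`, and `screen_stats.confusion_summary` reports
the detection and rejection rates under both naming conventions.

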