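# retinovis

Analysis pipeline for rodent visual-function studies combining three
measurement modalities:

- **Fourier retinotopy from intrinsic-signal optical imaging** — a bar
  drifting periodically across the visual field evokes a travelling wave of
  cortical reflectance change; the phase of each pixel's response at the
  stimulus frequency encodes that pixel's preferred visual-field position
  (plus a hemodynamic delay). Combining the maps from oppositely drifting
  stimuli cancels the delay and yields an *absolute* retinotopic map in
  visual degrees, which is then scored by three quality metrics: **map
  tilt** (orientation of the zero-phase line on the cortex), **phase
  scatter** (local smoothness), and **magnification factor** (visual degrees
  per millimeter of cortex).
- **Visually evoked potentials (VEPs)** — trial-averaged peak-to-trough
  amplitudes, the contralateral bias index (CBI), and normalized
  spatial-frequency / contrast response curves.
- **Electroretinograms (ERGs)** — a-wave (baseline-to-trough) and b-wave
  (trough-to-peak) amplitudes and their ratio.

A synthetic-data generator with known ground truth drives every stage, so
the whole pipeline is testable end-to-end by parameter recovery, without any
recorded animal data. Group comparisons (summary-based two-sample *t* tests
and a mixed repeated-measures ANOVA with a linear within-subject contrast)
close the loop from features to statistics.

## The core computations

For each pixel, after subtracting a centered boxcar moving average spanning
two stimulus cycles, the fundamental Fourier component at the stimulus
frequency *f* is

```
c(x) = (2/N) Σ_t  I(x, t) · exp(−2πi f t),     A = |c|,  φ = arg c,
```

so a trace `A·cos(2πft + φ)` returns amplitude `A` and phase `φ` exactly. A
constant bias vector, estimated as the mean (cos, sin) over a quiet
artifact-free reference region, is subtracted from all pixels. Opposite
sweep directions carry phases `δ + φ_pos` and `δ − φ_pos` (`δ` the common
hemodynamic delay, `φ_pos` the position phase), so per pixel

```
φ_out = wrap(φ_fwd − φ_rev) / 2 = φ_pos,       angle = φ_out / 7.2
```

with 7.2 the phase-degrees-per-visual-degree conversion (360° of phase over
a 50° sweep). Map tilt is the acute angle between the total-least-squares
fit of the zero-angle line and the mediolateral (elevation) or
anteroposterior (azimuth) axis. Phase scatter is the SD of
`angle(x) − mean(angle over the 25-pixel radius-2.9 neighborhood)` over the
≤ 20 000 highest-amplitude pixels. The magnification factor is
`10° / d(±5°)` where `d` is the cortical distance between the interpolated
−5° and +5° level crossings along the steepest-ascent line.

Group summaries printed as mean ± SEM with group size *n* are compared with

```
t = (m₁ − m₂) / √(sem₁² + sem₂²),      df = n₁ + n₂ − 2.
```

## Worked example

```python
from retinovis import *

gt = ImagingGroundTruth(tilt_deg=25.7, magnification_deg_per_mm=44.8,
                        noise_sd=0.0, drift_amplitude=0.0, seed=1)
session = generate_imaging_session(gt, SessionGeometry(axis="elevation"))
amap = compute_absolute_map(session)
m = compute_map_metrics(amap, session.ground_truth.roi_mask)
print(f"tilt          {m.tilt_deg:.2f} deg")
print(f"scatter SD    {m.scatter_sd:.3f} deg")
print(f"magnification {m.magnification_deg_per_mm:.2f} deg/mm")

res = t_from_summary(GroupSummary(197.16, 19.5, 12), GroupSummary(120.2, 8.6, 9))
print(f"t = {res.t:.2f}, df = {res.df}, p = {res.p:.4f}")

erg = generate_erg_trace(ErgGroundTruth(a_amp=216.0, b_amp=454.0))
f = erg_wave_amplitudes(erg.time, erg.trace, erg.flash_time)
print(f"a = {f.a_amplitude:.1f}, b = {f.b_amplitude:.1f}, a/b = {f.ab_ratio:.2f}")
```

prints

```
tilt          25.68 deg
scatter SD    0.561 deg
magnification 44.80 deg/mm
t = 3.61, df = 19, p = 0.0019
a = 216.0, b = 454.0, a/b = 0.48
```

The session was generated with a 25.7° tilt and 44.8 deg/mm magnification,
both recovered by the full filter → extract → combine → metrics chain (the
residual scatter reflects footprints straddling the ROI edge, where
neighborhoods include unresponsive pixels). The *t* test compares two
contralateral-eye VEP cohorts from their printed summaries; the ERG scorer
recovers the generating a/b amplitudes and their ratio.

The same stages are available from a shell:

```
retinovis simulate --kind imaging --seed 1 --tilt 25.7 --noise-sd 0 --drift 0 --out ses/
retinovis map --fwd ses/stack_fwd.tif --rev ses/stack_rev.tif --out map/
retinovis metrics --map map/ --roi ses/roi_mask.csv
```

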