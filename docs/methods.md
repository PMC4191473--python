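# Methods

## Generative model for imaging sessions

A session is a forward/reverse pair of reflectance stacks
`I(t, r, c) = B + 1_ROI(r,c) · A · cos(2πft + δ ± φ_pos(r,c)) + drift + noise`
with baseline `B = 1.0`, modulation depth `A = 0.01` (a ~1% intrinsic
signal), stimulus frequency `f`, hemodynamic delay `δ`, and a **planar**
position field: `φ_pos = (360/sweep) · M · p · ((r−r₀)u_r + (c−c₀)u_c)`,
where `M` is the magnification (deg/mm), `p` the pixel size (mm), and
`(u_r, u_c)` the unit gradient direction chosen so the zero-level line makes
the ground-truth tilt angle with the reference axis (mediolateral for
elevation maps, anteroposterior for azimuth). A plane is the minimal
structure that exercises all three map metrics: a line angle, a local
smoothness statistic, and a gradient magnitude.

Noise is i.i.d. Gaussian per pixel-frame; drift is a per-pixel quadratic in
time — the simplest trends the two-cycle boxcar high-pass must remove.
Optional "vessel" stripes add a static high-amplitude offset and are
excluded from the ROI, exercising the requirement that the bias-reference
region be artifact-free. Image convention: rows = anteroposterior, columns
= mediolateral, origin top-left, row-major; used identically everywhere.

Default geometry (configuration, not claims — the acquisition parameters of
the original recordings are not published): 80×80 pixels at 0.005 mm/pixel,
0.125 Hz stimulus (8 s sweep period), 5 Hz frame rate, 6 whole cycles
(240 frames), delay 60 phase-deg, sweep extent 50°. Two constraints shaped
these choices: the session must contain a whole number of stimulus cycles
(enforced, with 40 frames/cycle), and the position phase must stay within
±90 phase-deg across the ROI so that halving the wrapped phase difference
is unambiguous — at 44.8 deg/mm and 0.005 mm/pixel the default ROI (a
centered disk, radius 0.38 × field) spans ≈ ±7 visual degrees, safely
inside the ±12.5° alias-free range while still containing both ±5° levels
needed by the magnification metric.

The sweep extent and the analysis-side angle conversion factor are two
views of one constant (360/50 = 7.2 phase-deg per visual degree); the
generator and analyzer share it by default, so noiseless recovery is exact.
Whether that divisor acts on phase expressed in degrees or another unit is
a convention; it is exposed as configuration with 7.2 as default.

## Fourier analysis

*High-pass.* The two-cycle boxcar is implemented as a centered symmetric
moving average; for an even window of `w` frames the kernel has `w+1` taps
with half-weight endpoints. This trapezoidal form is exact in two useful
senses: any sinusoid whose period divides the window is removed entirely
(its windowed mean is zero), and a linear ramp maps to zero in the
interior. Edge frames with incomplete windows are dropped rather than
padded (no leakage from padding); with the default two-cycle window this
trims exactly one cycle per side, preserving the whole-cycle precondition
of the extraction.

*Fundamental extraction* computes `(2/N) Σ I·e^{−2πift}` per pixel and
requires the stimulus frequency to be an exact DFT harmonic of the stack;
amplitude and phase then follow the `A·cos(2πft+φ) → (A, φ)` convention
exactly. The phase of a zero trace is reported as 0.

*Bias removal* subtracts the mean (cos, sin) vector of a caller-supplied
reference region (no automatic artifact detection — region selection is an
experimenter judgement).

*Combination.* The phase difference fwd−rev is wrapped to (−180°, 180°]
**before** halving, keeping the monitor-center line at zero; amplitudes are
averaged. Halving is required for the delay to cancel while preserving the
position scale.

## Map metrics

*Tilt.* ROI pixels with |angle| ≤ 2% of the ROI's angle range define the
zero band; its total-least-squares principal axis is the zero line (TLS is
symmetric in the two image axes, unlike a regression of row on column). The
reported tilt is the acute angle to the reference axis, in [0°, 90°]; the
sign is discarded. Absence of a sign change in the ROI is an explicit
error.

*Phase scatter.* Neighborhood = integer offsets within Euclidean radius 2.9
of the center — exactly the full 5×5 square (25 pixels, center included).
Centers are the ≤ 20 000 highest-amplitude ROI pixels whose footprint lies
fully inside the map (incomplete footprints are excluded before ranking);
ties at the cutoff break by row-major order for determinism. The statistic
is the population SD of center-minus-neighborhood-mean deviations, computed
on the visual-angle field in visual degrees with plain arithmetic means:
after delay cancellation and conversion the values never approach the wrap
boundary, so circular statistics are unnecessary (a stated limitation if
maps ever span the full cycle). Because published scatter values carry no
explicit unit, no attempt is made to match their magnitudes; the convention
here (visual degrees) is recorded in the output schema. The radius is
interpreted in raw pixels.

*Magnification.* Along the steepest-ascent line (perpendicular to the
fitted zero line, through its centroid, oriented by a least-squares plane
fit), the map is sampled every 0.25 px by bilinear interpolation; the
−span/2 and +span/2 crossings (span 10° by default) are located by linear
interpolation between samples, and the metric is span / separation-in-mm.
Flat maps and unattained levels are explicit errors. On a planar map this
is exact to interpolation error (≪ the 2% test tolerance) and independent
of tilt.

## Electrophysiology

VEP epochs are a biphasic difference-of-Gaussians template (trough 70 ms,
peak 120 ms) normalized to unit peak-to-trough, scaled by each condition's
true amplitude, plus white noise; only the peak/trough geometry matters to
a peak-to-trough scorer. The analysis window defaults to 0–250 ms
post-reversal (configurable; no canonical value is published). Amplitude =
max − min of the trial-averaged trace in the window; CBI =
contralateral/ipsilateral amplitude; response curves divide by a reference
condition (lowest spatial frequency, or 100% contrast), and the blank
(equal-luminance gray) condition's amplitude is reported as the noise
floor.

The ERG a-wave is modelled as a smooth step to a sustained plateau of depth
`a` (complete by 15 ms) with a Gaussian b-wave of height `b` at 80 ms
riding on it. The scorer measures a baseline-to-trough a-amplitude
(baseline = mean of the 50 ms pre-flash) and a trough-to-peak b-amplitude —
the standard ERG convention; a baseline-to-peak alternative would simply be
`b − a` here and is not separately implemented. The plateau (rather than a
transient) makes the degenerate `b = 0` case well defined: the trace stays
at the trough and the measured b-amplitude is exactly zero, while the a/b
ratio is deliberately an error in that case. Negative excursions are
clipped to zero (no wave present).

## Group statistics

The summary-based t uses the SEM-quadrature denominator with
`df = n₁ + n₂ − 2` — the form consistent with published t/df pairs
recomputable from printed summaries; a pooled-variance variant is available
behind a flag. The raw-data route computes each cohort's mean/SEM/n and
delegates, so the two are identical by construction.

The repeated-measures ANOVA reports (a) the between-group F on subject
means and (b) the within-subject linear-trend F from projecting each
subject's (centered) condition profile onto orthonormal linear-contrast
coefficients, tested against the subject-level error with
`df = (1, N − groups)`. df = 1 contrasts need no sphericity correction.
p-values come from the t and F distributions (scipy) but comparisons are
made on the statistics themselves.

## What the synthetic data does and does not show

The generator covers planar retinotopy, common-mode delay, stationary
Gaussian noise, polynomial drift, static vascular stripes, and stereotyped
evoked waveforms. It does **not** emulate curved or discontinuous
retinotopy (area borders), breathing/heart-beat artifacts, eye movements,
non-stationary hemodynamics, or trial-to-trial latency jitter. Passing
closed-loop tests therefore demonstrates correctness of the analysis
algebra and its numerical implementation — not robustness to every
real-data pathology; the noise/drift tests bound only the modelled
disturbances.

## Problem sizes

Tests and the acceptance script run sessions of 48×48–80×80 pixels and
160–240 frames, scatter oracles up to 64×64, and 2 000 null replicates for
the type-I-error check — sizes at which every closed-loop recovery is
well-conditioned and the whole suite completes in seconds.
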