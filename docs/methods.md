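# Methods

`ppgbp` estimates systolic and diastolic blood pressure (SBP/DBP, mmHg) from a
single-channel finger photoplethysmogram (PPG) sampled at 50 Hz together with
simple biometrics, without per-subject calibration. This note documents the
estimation procedure, its constants, the synthetic cohort used to test it,
and the numerical and design choices that were genuinely open.

## 1. Estimation pipeline

**Beat detection.** The record is band-passed (0.5–10 Hz Butterworth,
zero-phase), steep upstrokes are found as first-derivative maxima (threshold
0.4 × the 98th percentile, minimum spacing 0.3 s), and each pulse foot is the
local minimum preceding its upstroke. Inter-foot intervals outside 0.3–2.0 s
(30–200 bpm) invalidate both bounding feet. Beats are foot-to-foot, closed on
both ends (adjacent beats share the boundary sample), so a beat of *n*
samples spans (*n* − 1)/fs seconds.

**Fiducial points.** The systolic peak is the global maximum in the first
60 % of the beat (a maximum on the window edge flags the beat unusable). The
dicrotic notch is the first local minimum of the 5-point-smoothed beat after
the peak whose prominence exceeds 1 % of beat amplitude, searched up to 90 %
of the beat; failing that, a damped-notch shoulder is accepted — an interior
local maximum of the (still negative) smoothed first derivative, confined to
the first 75 % of the beat. Beats with neither are flagged *notchless*; they
are excluded from stiff-index and area features.

**SDPTG.** The second derivative of the PPG (SDPTG) is computed with 5-point
quadratic (Savitzky–Golay) smoothing before each differentiation — raw double
differencing at 50 Hz is noise-dominated. The a-wave is the global maximum of
the first half; b–e are the following alternating local extrema. Beats with
fewer than five extrema, or with a ≤ 0 or b ≥ 0, are flagged and excluded.

**Beat-level quality control.** Per beat: perfusion index
PI = (max − min)/mean (AC over DC, raw device counts), stiff index
SI = height / Δt where Δt is the peak-to-notch lapse (m/s), heart rate
60/duration, and trapezoidal areas of (samples − beat minimum) on either side
of the notch. A beat is *abnormal* if any of the five features deviates from
the measurement median by more than 3 × a robust scale, or carries a fiducial
flag. The robust scale is the scaled MAD (1.4826 × MAD) floored at 5 % of the
|median|: at 50 Hz the SI and HR are quantized to a handful of values per
measurement, and without the floor a zero MAD flags every minority beat. A
separate noise test fails a beat when the SDPTG standard deviation between
the notch and the next foot exceeds (strictly) 15 % of |b|.

**Measurement-level rules.** A measurement is rejected when the abnormal
fraction exceeds (strictly) 20 %, or when fewer than 30 good cycles survive
all filters. Good beats are resampled to 32 points (linear interpolation),
baseline-shifted and peak-normalised (the coefficients encode shape, not
perfusion), a pointwise-median template is built, and the 30 beats closest
to it in Euclidean distance are kept (ties → earlier beat).

**Features.** Per training set, an SVD of the stacked 32-point beats yields
an orthonormal shape basis: 4 components for the PPG stream (P1–P4) and 8
for the max-abs-normalised SDPTG stream (S1–S8); counts are fixed, the
explained-variance fractions are reported as diagnostics. Component signs
are fixed so the largest-magnitude element is positive. Each beat's input
vector is [P1–P4, S1–S8, HR, b/a, c/a, d/a, e/a, SI, BMI] — 19 scalars.

**Model.** One cuff reference exists per measurement but 30 beat rows enter
training, so each reference is expanded into 30 targets by adding
independent uniform perturbations on ±0.5 mmHg. Two ensembles of 100
bootstrap-aggregated regression trees (minimum leaf size 30, random feature
subspace of 0.33 per split) are trained on the identical feature matrix, one
per pressure. Training rows are canonically sorted by (subject, measurement,
beat) before fitting, and all sub-seeds derive from the master seed via
CRC32 counters, so results are reproducible and independent of input
ordering. A measurement's prediction is the 20 % trimmed mean of its 30
per-beat predictions: like the median it ignores a wild minority beat, but
it averages the whole-sample quantization dither of the 50 Hz fiducials
(setting the trim to 0.5 recovers the median).

**Validation.** Leave-one-subject-out: all of a subject's measurements are
removed from both the SVD fit and the ensemble training (asserted per fold),
the fold model is trained on the remainder, and the held-out measurements
are predicted. **Personal calibration** subtracts, from each new prediction,
the median of that subject's previous fitting errors.

**Statistics.** Errors are (estimated − reference). Agreement: mean ± sample
SD, Pearson R, Bland–Altman bias ± 1.96 SD (plotted against reference BP).
Strata: age ≤ 50 y vs older; SBP groups I (90–120), II (120 ≤ SBP < 140),
III (≥ 140), with an explicit below-range bucket at ≤ 90 mmHg; PI < 0.01 vs
≥ 0.01. Significance: two-sample t-test between PI groups; one-sided paired
t-test that calibration shrinks absolute errors (a zero difference vector is
reported as p = 0.5 by convention). SBP and DBP are tested separately and
labelled.

## 2. Synthetic cohort

No public recording set accompanies the method, so the package ships a
generator whose output the full pipeline can consume; it defines the study
conditions for all end-to-end tests.

**Waveform.** Each beat is a skewed systolic Gaussian lobe (upstroke width
0.06 T, downstroke wider by the skew factor), a diastolic Gaussian lobe, and
a smoothly gated exponential diastolic runoff. The valley between the lobes
is the dicrotic notch; the SDPTG a–e waves emerge from the lobe curvatures.
Morphology is driven by the effective pressures SBP\*/DBP\* (true BP plus a
per-subject bias, sd 4 mmHg SBP, and a per-measurement perturbation, sd
3 mmHg — together the irreducible 5 mmHg floor that bounds any estimator):

| parameter | coupling | direction |
|---|---|---|
| peak→notch gap (s) | 0.34 − 0.0013 (SBP\* − 90), × √(T/0.83) | SI ↑ with SBP |
| downstroke skew | 1.65 − 0.0055 (SBP\* − 120) − 0.002 (age − 50) | b/a ↓ with SBP, age |
| diastolic amplitude | 0.33 + 0.004 (DBP\* − 70) | diastolic wave ↑ with DBP |
| diastolic width / T | 0.13 − 0.00035 (SBP\* − 90) | notch sharper at high SBP |

The √T factor is Bazett-like systolic timing; it also keeps the valley
resolvable at slow heart rates (a backstop further reduces the skew until
the dicrotic rebound reaches 4 % of the systolic peak). These couplings are
calibrated so the signal is recoverable at desk scale — 50 Hz sampling makes
the peak-to-notch lapse move one sample per ≈ 15 mmHg, and beat-to-beat
period jitter (sd 2 %) plus the trimmed-mean aggregate recover sub-sample
resolution.

**Cohort.** Biometrics emulate a community + in-hospital adult population:
young arm (≤ 50 y) age 36.0 ± 8.4, SBP 118.7 ± 17.0; older arm 69.3 ± 11.6,
SBP 130.5 ± 18.6; height ≈ 163 ± 8 cm; BMI ≈ 24 ± 4; pulse pressure larger
in the older arm. Arms are balanced 50/50 (the source population skews
older; balance gives both age strata usable n at 60 subjects). Truncated
normals are drawn by rejection, so no probability piles on the bounds.
Default: 60 subjects × 2 measurements of 60 s at 50 Hz, DC 2000 counts,
white noise 0.5 % of AC + 0.15 counts absolute, 5 % AC baseline drift.
10 % of older subjects get a damped dicrotic notch (smaller, broader
diastolic lobe), exercising the notchless path and the QC rejection route.

**Perfusion arms.** Low-perfusion status (PI < 0.01) is block-randomized
across the SBP-sorted cohort (one of every five subjects), so the low- and
high-PI arms carry comparable BP distributions — at n = 60, unblocked
assignment leaves the arms BP-imbalanced and the regression-to-mean of any
small-sample model can mask or invert a perfusion effect. PI levels are
drawn per arm with a margin around 0.01. Low-PI subjects' morphology reads
22 mmHg low (floored at 88 mmHg): poor perfusion distorts the waveform
toward apparent lower pressure, and the absolute noise floor weighs
relatively more in their weaker pulses. The planted value is deliberately
larger than the few-mmHg shifts reported in large cohorts, because the
ensemble partially re-identifies low-perfusion rows from their noisier
SDPTG texture and compensates much of it; 22 mmHg leaves a ≈ 7 mmHg
observed shift, detectable with > 0.8 power at this cohort size.

**Calibration arm.** 30 subjects × 5 measurements with a dominant
per-subject bias (sd 8 mmHg SBP), mirroring a month-long weekly follow-up
in which biometric-adjustment errors dominate; 3 measurements form the
calibration factor, 2 are held out.

**What the generator does not emulate.** Motion artifacts beyond the seeded
spike/dropout/drift corruptions, arrhythmia, respiratory modulation,
multi-wavelength or contact-pressure effects, and any hemodynamic
(Windkessel-type) physics. Passing tests therefore demonstrate that the
pipeline recovers a monotone morphology→BP mapping under realistic noise,
quantization and QC conditions — not clinical accuracy on real patients.

## 3. Numerical choices and degenerate inputs

- Strict inequalities for the 20 % and 15 %-of-b rules ("exceeded"); the
  SDPTG segment sd uses the population convention (ddof 0) and a 1e−12
  relative guard so an exactly-boundary segment passes.
- A beat whose SDPTG peak-to-peak is below 1e−9 × (beat amplitude + 1) × fs²
  is flagged incomplete rather than having "waves" located in float noise.
- Constant or linear beats: no feet (error), zero SDPTG (flagged).
- Zero-variance inputs to the t-tests are reported as undefined (NaN) or by
  the p = 0.5 / p = 0 conventions described above, never raised.
- SVD rank below the requested component count raises a named error; basis
  sign fixing makes serialized bases reproducible.
- Measurement sub-seeds use CRC32 of the measurement id mixed with the
  master seed: stable across platforms, processes and orderings.

## 4. Problem sizes

End-to-end checks run the default 60 × 2 cohort (~114 accepted measurements,
60 LOSO folds, ≈ 2 min) and the 30 × 5 calibration cohort (≈ 1.5 min); unit
tests use an 8-subject cohort. These sizes were chosen so the full study
remains a desk-scale computation while keeping every stratum populated.

## 5. Known limitations

- At 50 Hz the stiff index is quantized (~1 sample ≈ 1–2 m/s); per-beat SI
  is only meaningful in aggregate.
- The tree ensemble compresses the extremes of the BP range (low pressures
  over-, high pressures under-estimated), an expected small-sample behaviour
  of piecewise-constant learners; the synthetic studies reproduce it.
- The calibration factor is assumed stationary; no drift model.
- The generator's morphology couplings are linear with hard bounds; outside
  90–200 mmHg SBP they saturate.
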