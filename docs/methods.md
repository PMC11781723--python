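# Methods

## Model

The estimator treats the arterial tree between the heart and two
measurement sites (forehead, palm) as a single elastic tube per site. The
Moens–Korteweg relation gives the pulse wave velocity

    PWV² = E·h / (ρ·D)

with `E` the wall elastic modulus, `h` the wall thickness, `ρ` the blood
density and `D` the lumen diameter. Wall stiffening with pressure is
modelled exponentially, `E = E0·e^(α·BP)`. Writing `PWV = L/PTT` for the
difference `L` in arterial path length between the two sites and solving
for pressure:

    BP = −(2/α)·ln(PTT) + (1/α)·ln(ρ·L²·D / (h·E0))

SBP uses the peak-to-peak (systolic) transit time and the systolic diameter
`D_s`; DBP the valley-to-valley transit time and `D_d`. The closed form
inverts exactly:

    PTT = L·sqrt(ρ·D/(h·E0))·e^(−α·BP/2)

which the package exposes (`invert_ptt`) both as a test oracle — the
round trip is machine-exact, and every emitted estimate satisfies
`PWV²·ρ·D = h·E0·e^(αBP)` — and as the generator of model-consistent
synthetic cohorts.

**Model assumptions.** One effective straight vessel per site with constant
diameter; no wave reflections; elasticity depending on pressure only;
straight-line surface distances proportional to arterial path lengths; one
(SBP, DBP) pair per video (no beat-to-beat variation).

### Units

The published constant set (`E0 = 1005`, diameter/thickness regressions
producing values near 5.5 and 0.58) is not a dimensionally consistent SI
system. The module therefore adopts a *model-unit* contract: `L` in metres,
`ρ` in kg/m³, `α` per mmHg, and `D`, `h`, `E0` used exactly on the scale
their sources imply. The unit-exact identities above carry the verification
burden; the absolute pressure scale inherits the (unstated) units of the
constants. Consequences of this choice: cross-variant and cross-subject
*differences* are meaningful and exactly characterised
(`variant_offset_mmhg`), while the absolute calibration is only as good as
the published constants.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| ρ (blood density) | 1060 | kg/m³ | population constant |
| E0 (zero-pressure modulus) | 1005 | model units | population constant |
| α (elasticity exponent) | 0.017 | 1/mmHg | population constant |
| Fixed-variant L, D, h | 0.2, 0.01, 0.001 | m | literature constants |
| Band-pass | 0.25–15 | Hz | Butterworth, order 4, zero-phase |
| CHROM window | 1.6 s, 50% overlap | — | Hann-weighted overlap-add |
| CHROM internal band | 0.4–6.0 | Hz | see "Numerical choices" |
| Min inter-event distance | 0.4 | s | caps HR at 150 bpm |
| Peak prominence | 0.3·σ | signal units | σ = signal sd |
| Pairing max lag | 0.5·median IBI | s | prevents cross-beat pairing |
| Min pairs for a PTT | 5 | — | else a quality error |
| D_s/D_d ratio | 1.0 | — | single regression diameter |

Filter order 4 and zero-phase (forward–backward) application are design
choices: transit time is a *timing* quantity, and a causal filter's group
delay would bias it; one shared filter design is applied to both sites.
The 15 Hz cut-off equals Nyquist at the 30 fps minimum frame rate, so at
fs < 30.01 the cut-off is clipped to 0.45·fs with a warning rather than
rejected.

## Signal path decisions

- **Transit-time convention.** The sources never state which site leads;
  the model needs PTT > 0 paired with L > 0, so both are magnitudes (mean
  absolute paired difference; |distF − distH|). Signed averaging with a
  fixed face-minus-hand order is available behind `signed=True`.
- **Event pairing** is greedy nearest-neighbour within the lag window,
  each event used once, ties broken toward the earlier hand event.
- **Dropped frames.** Invalid-tracking frames are removed; traces are then
  linearly interpolated onto the uniform frame grid so sampling stays tied
  to the nominal fps. A contiguous untrackable gap over 2 s aborts with a
  quality error instead of silently shrinking the signal.
- **Anchor convention** (the heart is not a pose landmark): heart =
  shoulder midpoint displaced 1/8 of the shoulder-to-hip midline toward the
  hips; face anchor = eye midpoint raised by half the eye-to-eye distance;
  hand anchor = right wrist. 1/8 is an exactly representable binary
  fraction, so the anchor arithmetic adds no rounding — with integer pixel
  fixtures the camera-scale invariance of L is bit-exact, not approximate.
- **Forehead/palm ROI index tables** are documented constants per backend
  (canonical 10-point/6-point fixture layout; a MediaPipe table in the
  optional adapter). ROIs inherit the landmark scale, so their area tracks
  the subject's apparent size.

## Numerical choices

- CHROM's internal band is 0.4–6.0 Hz (heart-rate fundamentals plus
  harmonics). A conventional narrow pulse band (0.5–4 Hz) was measured to
  bias *valley* timing by several samples at 60 fps — it flattens the broad
  diastolic trough — which matters here because diastolic pressure is read
  from valley delays. 0.4–6.0 Hz keeps both peak and valley timing within
  one sample on clean synthetic video.
- A constant (zero-variance) RGB trace yields an all-zero pulse with a "no
  pulsatile component" warning, not an error; PTT = 0 and L = 0 are flagged
  (pressure undefined) rather than silently propagated.
- BP outside 20–300 mmHg is emitted with a quality flag, never clipped.
- All filtering is deterministic; identical inputs give bit-identical
  outputs.

## Synthetic data: what it emulates, and what it does not

The generator stands in for unavailable study recordings.

- **Pulse surrogate:** two Gaussians per beat (systolic peak at 0.18 T with
  σ = 0.08 T; dicrotic bump at 0.45 T, σ = 0.12 T, amplitude 0.35) at
  lognormally jittered intervals (3% CV), default 62 bpm. Defaults follow
  the study protocol where stated: 60 fps, 120 s recordings.
- **Video:** two non-overlapping skin patches whose tones are
  multiplicatively modulated by the site waveforms with the signed
  R:G:B ≈ −(0.33 : 0.77 : 0.53) pulsatile vector (systole darkens the
  skin); static Gaussian texture lets spatial averaging recover
  sub-quantisation modulation from 8-bit frames. The default clip for
  end-to-end checks is 16 s at 320×240 — long enough for >5 beat pairs,
  small enough to regenerate per session.
- **Cohort:** country (50/50 India / Sierra Leone), gender per country,
  then independent truncated normals per group for age, height, weight,
  SBP and DBP using the study's descriptive statistics; height–weight
  correlation is not modelled. Heart-to-face and heart-to-hand distances
  default to 0.25 and 0.42 of stature (≈40 cm and ≈66 cm at 158 cm,
  adult segment proportions) with 5% per-subject jitter; camera scale
  uniform in 3–9 px/cm. Transit times come from the model inversion, so
  the cohort is exactly model-consistent: the demographic variant
  reproduces truth identically, and the fixed variant's error is the
  analytic offset `(1/α)·ln[(L²D/h)/(L_f²D_f/h_f)]` per subject — on this
  geometry the fixed variant underestimates SBP by ≈30 mmHg on average.
- **Not modelled:** physically based skin reflectance (the modulation is
  multiplicative by construction), motion, occlusion dynamics, sensor
  noise models beyond additive Gaussian, heart-rate variability structure
  beyond interval jitter, and any mismatch between the pressure model and
  physiology. Passing tests therefore demonstrate correctness of the
  *pipeline and model algebra* under controlled conditions, not clinical
  accuracy on real subjects — the model-consistency of the cohort makes
  the demographic variant exact by construction.

## Known limitations

- Absolute BP depends on the model-unit contract above; no empirical
  recalibration against cuff references is attempted.
- A single regression diameter serves both branches (`D_s = D_d` unless the
  ratio knob is set); how distinct systolic/diastolic diameters should be
  obtained is an open question of the source model.
- PTT resolution is one frame; at short transit delays the exponential
  model amplifies this quantisation strongly (dBP = (2/α)·dPTT/PTT), so
  per-subject absolute estimates from video at 60 fps are coarse even when
  delay recovery is within one sample.
- No landmark detector of our own: real-video use requires an external
  tracker (MediaPipe adapter provided) or precomputed landmark files.
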