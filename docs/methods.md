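# Methods

This note documents the models, conventions and numerical choices behind
`vrloc`, and what the synthetic generators do and do not emulate.

## Coordinate conventions and array geometry

Azimuth is positive to the listener's right, in (−180°, 180°]; elevation
positive upward in [−90°, 90°]. The Cartesian listener frame is x forward,
y right, z up, so azimuth = atan2(y, x) and elevation = asin(z/r). Azimuth
differences are wrapped to (−180°, 180°], with the tie at exactly ±180°
resolved to +180°; elevation differences are never wrapped. At the poles
(|elevation| = 90°) azimuth is reported as 0 by convention.

The 27-loudspeaker frontal array sits at radius 2.4 m: thirteen speakers at
ear level from −90° to +90° azimuth in 15° steps, and seven each at ±28°
elevation in 30° steps. Speakers are numbered 1–13 from the left
(number = 1 + (azimuth + 90)/15; elevated rows therefore carry only odd
numbers) and color-coded per elevation row. Which color belongs to which
row is a rig configuration choice, not a geometric fact; the default map
(yellow = +28°, red = 0°, blue = −28°) is overridable.

Pointing responses are defined by intersecting the controller ray with the
sphere of the loudspeaker radius centered on the head
(`geometry.ray_sphere_intersection`); for an origin inside the sphere the
exit point is taken.

## Rigid calibration

`calibrate` implements the three-step alignment in order: (1) rotate the
virtual tracker triangle so its plane normal matches the real one, (2)
translate the chosen reference point onto its real counterpart, (3) rotate
about the real normal through the reference point by the in-plane angle to
a second point. The second point is the lowest-index non-reference point.

Two orientation conventions coexist deliberately. The public
`plane_normal` resolves the cross-product sign ambiguity toward positive z
(then x, then y), which is convenient for reporting and avoids spurious
flips for near-horizontal tracker planes. Inside `calibrate`, however,
normals are oriented by vertex order, (p2−p1)×(p3−p1): that orientation
commutes with every proper rigid transform, which is what makes the
procedure recover arbitrary rotations — a fixed world-axis convention can
pick opposite sides of the two planes and leave the in-plane step unable
to align oppositely-circulating congruent triangles. With vertex-order
normals, recovery of 1000 random rigid transforms of the 0°/±45° tracker
geometry leaves residuals at machine precision (~1e−15 m, asserted below
1e−6 m), and the result agrees with an independent least-squares (Kabsch)
registration on the same three points.

The residual monitor flags recalibration when any mapped tracker is more
than 2 cm from its true position (strictly greater). A worst-case-rotation
helper converts a positional offset and a lever arm into an angle; the
lever (which point pair pivots, and in which direction the offset acts) is
a modelling choice the caller controls, defaulting to half the shortest
inter-tracker chord. No specific printed value is asserted for it, since
the geometric model behind such a figure is not uniquely determined.

## Binaural cue extraction

**Truncation.** Impulse responses are cut to 128 samples (2.7 ms at
48 kHz) from sample 0, removing reflections from other loudspeakers;
shorter inputs are zero-padded with a warning.

**Filterbank.** 4th-order IIR gammatone filters (scipy's design) with
unity gain at their center frequencies, spaced one filter per ERB on the
ERB-number scale between 200 Hz and 16 kHz (34 filters at 48 kHz); density
is configurable. Region membership is decided by filter center frequency
with half-open boundaries [low, high), the final region closed at 16 kHz,
so every filter belongs to exactly one region.

**Band power.** The power in band i is the filter-weighted mean squared
spectrum, Σ W_i|X|² / Σ W_i, with W_i the squared gammatone magnitude
response on an rfft grid of at least 8192 points. The normalization by the
filter's own spectral energy makes a flat unit-magnitude input read
exactly 0 dB in every band and a broadband gain of g shift every band by
20·log10(g); it cancels entirely in the SD and ILD differences the
pipeline reports, so those are unaffected by the choice. Silence maps to a
floor of −120 dB re full scale rather than raising.

**SD and ILD.** SD takes the per-filter absolute dB difference between
conditions first and averages within regions second ("differences first"),
making it nonnegative and invariant to a common gain. ILD is the
per-region mean of left-minus-right filter powers. Cue *errors* follow the
magnitude convention, |cue_with| − |cue_without| — positive when the
device makes the cue larger — with the plain signed difference available
behind a flag.

**ITD.** Each ear's pure delay is the lag of the peak of the
cross-correlation between the impulse response and its minimum-phase
version; ties break toward the smallest lag, and the ITD is
(delay_left − delay_right)/fs, positive when the left ear lags (source on
the right). Delays are integer samples by design — no subsample
interpolation — because the quantities of interest are reported in whole
samples (21 µs at 48 kHz) and the synthetic head model quantizes its
delays to match.

**Minimum phase.** Computed by real-cepstrum folding on an FFT grid at
least 8× the input length, with spectral magnitudes floored at 1e−12 of
their maximum before the log. The full padded-length signal is returned,
so the output magnitude spectrum equals the input's on that grid to
machine precision. Cumulative-energy dominance (the defining front-loading
property) is exact for smooth-spectrum signals such as head-model IRs; for
signals with deep spectral notches (e.g. white noise) cepstral aliasing
admits sub-percent violations that shrink as the pad factor grows — the
delay estimator only uses the correlation peak and is insensitive to this.

## Synthetic generators

The generators define the study-scale conditions under which the pipeline
is exercised; they are first-class, tested code, not fixtures.

**Spherical head.** ITD follows the Woodworth frontal-incidence form
(a/c)(θ + sin θ) with a = 8.75 cm and c = 343 m/s — 656 µs at 90°,
quantized to integer samples (31 samples = 645.8 µs at 48 kHz, within one
sample of the formula). The contralateral ear is delayed, attenuated by up
to 6 dB broadband, and passed through a one-pole low-pass whose
coefficient grows with sin|azimuth|, so |ILD| grows monotonically with
laterality and is largest at high frequencies; a small elevation tilt on
the shadow gain keeps the three rows from being acoustically identical.
Both ears share a 16-sample lead-in so later zero-phase filtering stays
causal in effect. What this model omits: pinna and torso cues, room
reflections, and any elevation-dependent spectral notches — so elevation
*perception* cannot be simulated acoustically, and passing cue tests say
nothing about real HRTF fine structure.

**HMD perturbation.** Deterministic given direction and config; the seed
only sets the ripple phase. Three components, all with tent-shaped azimuth
profiles that vanish at 0° and 90° (the measured errors are smallest at
the front and at full lateral):

* an extra integer-sample delay of the contralateral ear, 62.5 µs
  (3 samples) at its 75° peak by default;
* zero-phase, flat-top band-shaped attenuation of the contralateral ear
  per region (peak 6 dB in mid/high with peaks at 60°/30°, 1 dB in the
  low region — keeping the low-region ILD error under 2 dB);
* a slow spectral ripple (0.25 cycles/ERB, peak 6.3 dB) over 1–16 kHz per
  ear, scaled by how contralateral the source is to that ear. The slow
  ripple keeps its time-domain kernel compact so the integer-lag delay
  estimate is unaffected.

The whole contralateral spectral perturbation is scaled by 0.4 below the
horizontal plane (the device sits in front of the face), which makes the
below-plane SD strictly smaller than above it for matched azimuth and
seed. Measured region-mean errors are necessarily somewhat below the
configured per-frequency peaks because regions average over the band
shape.

**Pink noise burst.** 240 ms at 48 kHz (11,520 samples), spectrally shaped
1/√f white noise (−3 dB/octave power slope, verified by regression over
200 Hz–16 kHz), Tukey-windowed with 20 ms raised-cosine ramps, a fresh
realization per call. The nominal 65 dB SPL presentation level is
interpreted against a configurable digital full-scale reference (default:
RMS 1.0 ≡ 100 dB SPL) since no absolute calibration constant is
meaningful in software; the per-call level rove is uniform in ±3 dB.

**Response cohort.** 10 subjects × 8 conditions × 27 sources × 5
repetitions = 10,800 trials. In the canonical (right-handed) frame,
response = target + subject bias + HMD lateral overshoot + Gaussian noise,
with a 0.003 lapse probability replacing the response by a draw uniform
over the frontal hemisphere's solid angle. Choices worth recording:

* Per-subject biases are drawn around the group means (−1.6° azimuth,
  +19.0° elevation; SDs 1.5°/5°) and re-centered so the realized group
  bias equals the configured one exactly — the generator's contract is the
  *group* bias, and with 10 subjects an uncentered draw would make the
  cohort's truth differ from the configured value by up to ±1.5°.
* The controller-shape bias is omitted in the laser-pointer condition:
  visible ray feedback is precisely what removes that bias, which is also
  why the analysis exempts the condition from correction.
* The HMD lateral overshoot (gain × azimuth, left gain 0.06 > right 0.03,
  motivated by the measured left-right asymmetry, with no claim about its
  acoustic vs. motor origin) applies only to acoustic-stimulus HMD
  conditions. Applying it to the visual-search conditions would leak a
  systematic azimuth offset into the pointing-bias estimate and conflate
  two distinct effects.
* Per-condition angular noise SDs are set via σ = E·√(π/2) so the
  post-pipeline mean absolute elevation errors land near the study-scale
  condition means they emulate (≈10.2° blind-folded with HMD, ≈8.4°
  without, ≈8.1° with room and hand visible, ≈6.6° with loudspeakers
  visible, ≈2.4° with the laser pointer); visual-search conditions use 5°
  in both dimensions.
* One left-handed subject is included by default; their *logged* data are
  the canonical data mirrored on the median plane, which the pipeline's
  handedness mirroring undoes exactly.

The cohort emulates effect structure, not human response distributions:
no motor noise correlations, no learning across blocks, no
front-back confusions, no compression of lateral responses. Passing
recovery tests therefore demonstrates that the pipeline's estimators are
unbiased and correctly ordered under the assumed model, not that the model
captures human behavior.

## Behavioral pipeline

Order of operations: mirror handedness → estimate bias → correct → filter
outliers → summarize. Whether outlier screening precedes or follows bias
correction is a genuine design choice; it is fixed here as
correction-first (errors are analyzed on corrected responses, so the
outlier rule should see them too) and the threshold comparison is strict
(an error of exactly 45° is kept, reading "farther than" literally).

Bias estimation uses the two visual-search conditions only, averaging the
wrapped signed errors per subject; the group bias is the unweighted mean
of subject biases, so re-estimating after correction returns exactly zero.
Quartiles and medians use linear interpolation (numpy's default) so
boxplot statistics are reproducible bit-for-bit; whiskers extend to the
most extreme datum within 1.5 IQR. The hemifield contrast reports
left-minus-right statistics at mirrored azimuths, skipping unmatched cells
with a warning and excluding 0°.

Inferential statistics (mixed-effects models, F-tests, post-hoc
adjustments) are out of scope by design; the long-format error tables are
the hand-off point to standard statistics tooling.

## Problem sizes

Defaults throughout are the study-scale sizes: 27 source directions,
128-sample IRs at 48 kHz, 1000 calibration recoveries, 10-subject cohorts
of 10,800 trials, and 100 cohort replicates for the condition-ordering
check. The full test suite and the acceptance script each run in well
under a minute on one core at these sizes.

## Known limitations

* The rigid-sphere model has no pinna/torso cues; synthetic elevation
  effects are injected behaviorally, not acoustically.
* ITD is integer-sample; sources between sample boundaries alias to the
  nearest sample by construction.
* The 45° outlier rule assumes targets away from the azimuth wrap; all
  array targets satisfy this.
* `minimum_phase` returns the padded-length signal; callers needing the
  original length may truncate, at a small cost in magnitude fidelity.
* Exact byte-determinism of WAV outputs holds for float32 data; integer
  WAV inputs are read as raw floats without rescaling.
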