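# Methods

This note documents the models, conventions and numerical choices
behind `eitsbt`, and what the synthetic test bed does and does not
establish about real recordings.

## Data model and conventions

All signals live on the EIT frame clock: frame *i* of a sequence with
sampling rate *fs* (typically 50.2 Hz) and start time *t₀* sits at
*t₀ + i/fs*; timestamps map to the nearest frame with ties broken
toward the earlier frame, which makes alignment deterministic and
order-preserving.  Impedance is carried in the device's arbitrary units
(AU) throughout; only the ventilator calibration attaches milliliters.
The reconstruction grid is read from the data (32×32 in all bundled
scenarios, but nothing assumes it), and every spatial index is
restricted to a user-supplied binary lung mask.  Orientation follows
the supine convention: row 0 is ventral, the last row dorsal, so
"dependent" means dorsal; the convention is explicit in the code and
can be adapted for prone positioning by reorienting the input grids.
Non-finite pixels are repaired by per-pixel temporal interpolation on
ingestion and the affected frames are flagged, never silently passed
on.

## Preprocessing chain

**Spike artifacts.** The global lung signal (sum of lung-pixel
impedance per frame) is compared with a 0.1 s rolling median; frames
deviating by more than `mad_k` (default 6) normal-consistent MADs —
with a floor of 5% of the robust tidal swing so clean recordings yield
zero flags — are repaired by temporal interpolation of every pixel.
The 0.1 s window is deliberately shorter than half a cardiac period:
with a longer window the curvature of the cardiac oscillation leaks
into the residual and produces false positives.  A recording with more
than half its frames flagged is rejected as unusable.

**Step artifacts.** Sudden sustained baseline shifts (belt re-gelling,
electrode contact changes) are detected as jumps of a 2 s rolling
median exceeding 1.5× the robust tidal swing (measured on the
detrended signal, so the step itself cannot inflate the estimate).
Steps are *recorded as segment boundaries*, never corrected: the
absolute baseline before and after such an event is not comparable, so
no stable period may span one.

**Cardiac filtering.** Respiratory and cardiac fundamentals are
estimated from Welch spectral peaks (0.08–0.8 Hz and 0.8–3.5 Hz; the
three lowest respiratory harmonics are excluded from the cardiac
search, and a candidate below 10⁻³ of the spectral maximum is treated
as absent, so leakage floors are not mistaken for a heartbeat).  Breath
*timing* uses a zero-phase order-8 Butterworth low-pass with the cutoff
midway between the two fundamentals (geometric mean, with a warning,
when they are closer than 0.2 Hz).  Breath *values* are then re-read
from a different signal: a narrowband zero-phase notch at the cardiac
fundamental and its second harmonic plus a generous 3.5 Hz low-pass,
with the extremum values refined by local quadratic fits.  The split
exists because the midway low-pass, while ideal for robust extremum
detection, attenuates respiratory harmonics differently at 15 vs
25 breaths/min and thereby biases epoch percent-changes of the tidal
swing by several points; the notch leaves the respiratory waveform
intact.

**Breath segmentation.** Alternating troughs (end-expiration) and
peaks (end-inspiration) are found by prominence-gated extremum
detection, the gate being `prominence_frac` (default 0.3) of the median
detected swing; troughs at the recording boundaries, which standard
peak finding cannot mark, are recovered explicitly.  Breaths shorter
than 1 s or longer than 15 s are discarded.  EELI is defined at the
end-expiratory trough of each breath; ΔZ is the trough-to-peak swing.

**Stable periods.** Maximal runs of consecutive breaths with
coefficients of variation of both ΔZ and duration ≤ `cv_max` (default
0.25), at least `min_breaths` (default 5) breaths, no step boundary,
and a repaired-frame density ≤ `artifact_frac_max`.  The default
density budget is 5%: repaired spikes are isolated 20 ms frames whose
interpolation demonstrably shifts breath amplitudes by far less than
the stability tolerances (the property suite bounds the effect at <5%
for spike rates up to 1%), so the budget guards against *dense* repair
regions rather than penalising each repaired frame.  A budget as tight
as the spike rate itself would empty the selection on recordings that
are, breath-wise, perfectly stable.  All thresholds are relative to
the signal's own swing, making the screen scale-invariant.

## Parameters

The tidal image of a breath is the raw frame difference
end-inspiration minus end-expiration on lung pixels (no per-pixel
filtering, so pixel indices are free of filter ringing; negative,
"paradoxical" pixels are retained).  GI uses the raw tidal image per
its definition; the centroid (CoV) and the silent-space maximum clip
negative pixels to zero, since centroid weights must be non-negative.
CoV is normalised to the lung-pixel bounding box (0% ventral/left,
100% dorsal/right).  Silent pixels (DI < 10% of max) are split at the
CoV row: ventral of it nondependent, dorsal dependent, pixels exactly
on the row split evenly with the odd remainder to the dependent side —
integer pixel counts guarantee NSS + DSS + FLS = 100 exactly, with FLS
computed as the complement of the silent percentage.  The calibration
factor is the mean of VT/ΔZ over stable pre-SBT breaths matched to
ventilator samples within the breath interval ±1 s (single-point mode
uses the first match); breaths straddling the SBT start are excluded —
a trough detected fractionally before the disconnection otherwise
pairs a pre-SBT volume with the first T-piece breath and corrupts the
factor.  Per-period values are means of per-breath values (medians via
config); GI may alternatively be computed once on the period-averaged
tidal image (`gi_mode="period_image"`), which trades breath-level
granularity for noise suppression — the default stays per-breath to
match the breath-by-breath analysis framing.

## Epochs and trends

Because trial length varies between patients, the SBT span is cut into
five equal-duration half-open intervals; stable breaths are assigned by
their end-expiration start time (boundary breaths to the later
interval), the pre- and post-SBT phases forming one epoch each.  An
equal-breath-count mode is available via config.  EELI and ΔZ epoch
means are expressed as 100·(mean − mean_pre)/|mean_pre|; the absolute
value keeps the sign meaning "decrease" even for negative baselines.
The post epoch starts at reconnection; breaths in its first 30 s are
counted separately (`n_breaths_first30s`) because the tidal swing
recovers within tens of seconds and a washout-sensitive analysis may
wish to drop them.  An empty pre epoch is a hard error (no baseline);
any other empty epoch is reported, not fatal.  Group statistics beyond
per-outcome means are deliberately out of scope: the cohort table is a
tidy long format for external mixed-model tooling.

## The synthetic test bed

Each scenario builds the pixel signal as
`share(x,y)·EELI(t) + amp(x,y)·wave(t) + cardiac(x,y,t) + noise +
artifacts` inside a two-ellipse lung mask.  The respiratory waveform is
a raised-cosine inspiration/expiration cycle (default inspiratory
fraction 0.40, optional end-expiratory pause), giving smooth,
artifact-free extrema rather than a pure sine.  The amplitude map is a
spatially smooth positive random field raised to the exponent `gamma`
and renormalised to the scenario's tidal swing: `gamma = 0` is exactly
uniform (GI = 0) and GI grows monotonically with `gamma` — a
controllable inhomogeneity dial, not a physiological claim.  Cardiac
activity is a pure sinusoid on a mediastinal Gaussian blob; EELI
follows a piecewise-linear track with 10 s ramps at phase changes;
spikes are single-frame multi-pixel outliers and steps are sustained
baseline shifts, both logged.  The ventilator log reports
`c_true · ΔZ_true` at 1 Hz while connected (pre/post phases only — a
T-piece patient is off the ventilator), making calibration recovery
exactly checkable.

Default conditions describe a typical adult weaning candidate:
15 breaths/min on support, 4 AU ≙ 400 ml tidal swing (c = 100 ml/AU,
so the baseline RSBI is ~38, matching the usual pre-SBT range), EELI at
10× the tidal swing, heart rate 90/min at 20% of the tidal swing, and
0.003 AU per-pixel noise (per-pixel tidal SNR ≈ 3.5).  The reference
trial scenario raises RR to 25/min, drops EELI by 20% (recovering only
to −10% after reconnection) and ΔZ by 15% (recovering fully), with 1%
spike frames.  The packaged "success" and "failure" scenarios differ in
`gamma` (0.4 vs 1.4 at every phase), RR response (20 vs 30/min), tidal
depression (−15% vs −30%) and a transcutaneous-CO₂-like channel (flat
vs rising 40→55 mmHg).

What the test bed does **not** emulate: reconstruction physics and
electrode artifacts, ventilation–perfusion structure, cardiac waveform
harmonics beyond a sinusoid, breath-to-breath physiological
variability in amplitude and timing, posture changes, or
weaning-induced pulmonary oedema.  Passing the recovery suite therefore
shows that the algorithms are correct under the stated signal model at
realistic SNR — not that the thresholds are clinically optimal; on
real recordings the config surface (`mad_k`, `cv_max`, `min_breaths`,
`prominence_frac`, breath duration limits, `artifact_frac_max`,
`step_thresh_au`) is the intended adaptation point.

## Problem sizes and determinism

Bundled scenarios use 120 s pre, 300 s SBT and 120 s post at 50.2 Hz on
a 32×32 grid (~27k frames), long enough for ≥25 stable breaths per
epoch while keeping a full pipeline run in seconds.  All scenario
randomness flows from a single seed through one named generator; fixed
configs reproduce bit-identical sessions.  Degenerate inputs are
handled explicitly: constant signals yield zero breaths (not an
error), a non-positive GI denominator or an all-silent tidal image is
flagged as missing with a warning rather than raising, and a
single-row/column bounding box pins the CoV at 50%.
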