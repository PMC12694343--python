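# Methods

This note documents the models, conventions and numerical choices behind
`wavescape`, and what the synthetic fixtures do and do not establish
about field data.

## Signal model and units

A clip is a mono series of linear pressure samples. Off disk, samples
are digital full-scale floats in [−1, 1) (int16 −32768 ↦ −1.0).
Calibration is optional: `CalibrationConfig(full_scale_db, "per_file_energy")`
rescales each file so its broadband mean square equals
p0²·10^(full_scale_db/10) — a flat per-file energy reference that fixes
the absolute dB scale while preserving all relative band-level structure
within the file. The default is no normalization: Leq values are then
relative to p0 = 20 µPa with one full-scale unit read as one pascal.
Under that convention a full-scale sine sits at ≈ 91 dB, and the
synthetic generator's `level_db` parameters are exact Leq targets.

Per-band Leq treats wavelet coefficients as pressure-like signals in the
input's units, so band levels and broadband levels share one dB axis.
All-zero windows yield a −∞ sentinel, which energetic means exclude
(with the count retained) rather than propagating NaNs.

## MODWT

Filters: d4 (4 taps, closed form), d8 and la8 (8 taps, canonical
published coefficients; validated in tests against pywavelets and
against their defining algebraic properties). MODWT rescaling divides
the orthonormal DWT scaling taps by √2, so the scaling taps sum to 1
with squared sum 1/2, and the wavelet taps are their quadrature mirror
(zero sum). d8 and la8 are spectral factorizations of the same half-band
polynomial, so their squared gains — and hence per-level energies — are
identical to machine precision; they differ only in phase.

Boundary rule: circular (periodic), the convention under which the
energy identity Σ_j‖W_j‖² + ‖V_J‖² = ‖x‖² is exact; a reflection
variant is available behind a flag for signals where wrap-around
artifacts matter more than exact energy accounting.

Implementation: the transform is evaluated in the frequency domain with
per-level equivalent transfer functions (the wavelet gain at stride
2^(j−1) times the accumulated scaling gains below it), algebraically
identical to the Percival–Walden time-domain pyramid, which the test
suite keeps as an independent oracle. Cost is one forward FFT plus J+1
inverse FFTs per clip; the multiplier table is cached per
(filter, J, length), since a duty-cycled session applies the same
multipliers to hundreds of equal-length clips. A 24 h day (240
one-minute 48 kHz files, J = 10) decomposes in a few minutes on one
core. Detail series are used as produced (no phase-alignment
shift is applied before computing band levels).

Nominal band of level j: (fs/2^(j+1), fs/2^j]. Short filters leak
across these edges — a 100 Hz tone at 48 kHz (nominally W8) spreads
visibly into W9 — so the package always reports the nominal dyadic bands
and leaves perceptual groupings ("biophony bands") to the analyst.

## Peak detection and lag statistics

A sample is a peak in mode (nups, ndowns) iff the nups differences
ending at it are all > 0 and the ndowns differences following it are all
< 0. Ties (zero differences) break runs by default, matching the
default of the widely used R `findpeaks` routine; a `zero_continues`
flag treats ties as run continuations and then reports only the first
sample of a flat top, again following that reference. No amplitude or
prominence thresholding is applied: the modes are purely run-length
based, so a (2–2) peak requires a structured, multi-second event while
(1–1) fires on any local maximum.

Lags are first differences of peak times within a single clip. They are
never taken across duty-cycle pauses, which would inject ≥ 300 s
artifacts into distributions whose medians sit near 10 s. Medians of
even-count integer lags use the lower order statistic so reported
medians stay on the 1 s grid (midpoint available via a flag). Pooling
for site summaries is over the full analyzed day per site × band.
Hourly peak rates are reported both as raw counts per recorded 10
minutes and extrapolated ×6 to a full hour, labelled, because the right
normalization depends on whether the process of interest is stationary
within the hour.

## ACF model and two-stage fit

The ACF estimator is mean-removed, biased (divide-by-n) and normalized
at lag 0 (statsmodels backend; verified against the direct definition).
For duty-cycled data the ACF is computed on the concatenated recorded
seconds — "recorded-time lags" — a deliberate simplification: the
default fit window (lags 1–100 s) is well below the 300 s gap scale,
but lags spanning a file boundary do mix samples 5 minutes apart.

The model y(t) = y0·t^(−γ)·e^(−t/β) is fit by nonlinear least squares in
linear ACF space. Log-space fitting would be variance-stabilizing but
cannot represent the γ ≈ 0 and γ < 0 cases that quiet or
noise-dominated bands genuinely produce, so γ is left unconstrained in
sign and non-positive ACF values are simply excluded from the fit
(fewer than 10 usable lags is an error). β is fit as log β and bounded
to [1, 10⁴] s: when no cutoff is visible inside the fit window the
likelihood is flat in β upward, and an unbounded fit would send β to
infinity and poison the across-site mean used by the two-stage
procedure. Starting values y0 = acf(1), γ = 0.1, β = 30 s, with
multi-start over γ ∈ {0.1, −0.1, 0.5}; fits are deterministic.

Stage 1 fits (y0, γ, β) freely per site; stage 2 fixes β at the
arithmetic mean of the stage-1 values and refits (y0, γ). Note that
stage 2 is a comparison device, not an estimator of the generating γ:
when a site's true β differs from the shared mean, its stage-2 γ
absorbs the mismatch. Recovery tests therefore check the stage-1
exponents; stage-2 output is what the cross-site tables report.

H = 1 − γ/2 is reported only for 0 < γ < 1 (persistent regime,
1/2 < H < 1); γ ≥ 1 is flagged random-walk-like with H = 1/2, and γ ≤ 0
is out of the relation's domain and carries no H.

## Synthetic scenes: what they emulate, and what they don't

The generator reproduces the recording regime of a duty-cycled woodland
deployment: 1-minute 16-bit WAV files at 48 kHz, 10 per hour, 24 h per
site, with an ISO-timestamped manifest. Components: Poisson or
fixed-spacing chirp trains (linear FM sweeps, default 3–8 kHz, Hann
envelope) standing in for bird vocalizations; band-limited 1/f^α
colored noise (α ∈ [0, 2], spectral synthesis, exact unit RMS) for
traffic/wind floors; broadband noise bursts for pass-by transients; and
pure tones for calibration. A 24-value diel gain curve (dB per hour)
modulates the biophony components; the default dawn profile is a
Gaussian bump (peak hour 6, depth 12 dB, width 3 h). All randomness
comes from numpy's PCG64 seeded per file from (scene seed, hour, clip
index), so fixed-seed scenes are bit-reproducible.

Default levels — chirps 70–75 dB, low-frequency floor 60 dB, broadband
full signal ≈ 60 dB — were chosen once to mirror a moderately quiet
woodland with audible nearby birds over a distant-traffic floor, and to
keep 16-bit headroom (clipping above 1% of samples triggers a warning
and peak normalization).

What passing tests show: the pipeline recovers constructed ground truth
(event spacing, diel maxima, band placement, generating ACF exponents)
through the full WAV → MODWT → Leq → peaks/ACF chain. What they do not
show: robustness to overlapping real sources, wind gusts, rain,
recorder self-noise, species-specific call structure, or
level-dependent peak morphology — real soundscapes are not sums of
stationary surrogates, and no synthetic pass substitutes for validation
against annotated field audio.

## Problem sizes and defaults

- Wavelet filter d4, J = 10 levels (dyadic bands down to ~23 Hz at
  48 kHz); d4 favours time localization of transient calls, d8/la8
  favour frequency resolution of tonal sources.
- Leq windows: 1 s for peak/ACF work; hourly aggregation over the 600
  recorded seconds of each hour.
- Peak modes (1–1) and (2–2); both always computed.
- ACF max lag 100 s, fit range 1–100 s (configurable; the power-law
  regime lives at short lags).
- The bundled end-to-end check runs one synthetic site-day at full
  scale: 240 one-minute 48 kHz files, rendered and analyzed in roughly
  four minutes on a single core. Unit and property tests use shorter
  clips and, for orchestration-only checks, a 16 kHz variant of the
  scene.

## Known limitations

- Circular boundary wraps each 1-minute file; the first/last samples of
  every level mix signal from both ends of the clip. At 48 kHz this
  touches well under the first second for J ≤ 10.
- The per-file energy normalization is a broadband (flat) reference; it
  does not implement any frequency-weighted reference.
- ACF gap closure (above) biases lags that straddle file boundaries.
- Stage-2 γ values are conditional on the shared β (see above).
- No resampling, denoising, frequency weighting, percentile levels, or
  ultrasonic-channel support.
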