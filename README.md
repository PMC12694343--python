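# wavescape

Multi-resolution soundscape analysis for passive acoustic monitoring
(PAM): frequency-resolved acoustic energy, peak-interval statistics, and
temporal fractal metrics, built on a self-implemented maximal-overlap
discrete wavelet transform (MODWT).

## Who this is for

Soundscape ecologists running duty-cycled field recorders (the typical
schedule: 1 minute of recording, 5 minutes of pause, 10 one-minute WAV
files per hour) who want physically interpretable, energy-based
descriptors of biophony, geophony and technophony instead of — or as a
complement to — composite eco-acoustic indices whose behaviour is hard
to standardize across recorders and sites.

## What it computes

**Equivalent continuous sound pressure level.** For a window of length τ,

    Leq_τ = 10 log10( ⟨p²⟩ / p0² ),   p0 = 20 µPa,

computed identically for the broadband signal and for each wavelet band,
at τ = 1 s, 1 min, 1 h (hourly values from duty-cycled data are
energetic means over the recorded minutes only).

**MODWT.** An undecimated, shift-equivariant wavelet transform with
Daubechies d4/d8 and least-asymmetric la8 filters. Every detail series
W1…WJ (default J = 10) keeps the input's time resolution, level j
nominally covers the dyadic band (fs/2^(j+1), fs/2^j], and band energies
sum exactly to the signal energy. At 48 kHz, W1–W4 hold the
biophony-rich range above 1.5 kHz; W8–W10 hold low-frequency
geophony/technophony.

**Peak statistics.** Run-length peaks on the 1 s Leq series in two
modes: (1–1) — one strict rise before and one strict fall after, catching
rapid fluctuations — and (2–2) — two consecutive rises and falls,
selecting structured, multi-second events. Inter-peak lags (never taken
across duty-cycle gaps) are pooled per site × band into mean/median/count
summaries, and sites are compared with

    R = 100 · (⟨lag⟩_larger − ⟨lag⟩_smaller) / ⟨lag⟩_smaller   [%]
    D = median_i − median_j   [s]

**Temporal fractal analysis.** The autocorrelation function of the 1 s
Leq series is fit with a power law under an exponential cutoff,

    y(t) = y0 · t^(−γ) · exp(−t/β),

using a two-stage procedure: free (y0, γ, β) fits per site, then a refit
of every site with β fixed at the across-site mean. The decay exponent
maps to a Hurst exponent H = 1 − γ/2, valid in the persistent regime
0 < γ < 1 (γ ≥ 1: short-ranged, H = 1/2; γ ≤ 0: the relation does not
apply).

**Synthetic scenes.** A seeded generator renders full duty-cycled
sessions — diel-modulated chirp trains (bird-call surrogates, 3–8 kHz),
1/f^α colored-noise technophony, broadband transients, calibration
tones — as 1-minute 16-bit WAV files with an ISO-timestamped manifest,
so every stage of the pipeline is testable without field data.

## Worked example

Pairwise comparison of the bundled three-site survey lag table at level
W2 (6–12 kHz at 48 kHz), where the largest between-site contrasts occur:

```python
from wavescape.datasets import field_survey_lag_summary
from wavescape.peaks import LagStats, compare_sites

table = field_survey_lag_summary()
w2 = table[table.level == "W2"]
stats = {r.site: LagStats(r.mean_lag_s, r.median_lag_s, r.n_peaks, 0)
         for r in w2.itertuples()}
for c in compare_sites(stats, band="W2"):
    print(f"{c.pair[0]} vs {c.pair[1]}: R = {c.R:.1f} %, D = {c.D:+.0f} s")
```

```
Site1 vs Site2: R = 15.0 %, D = +1 s
Site1 vs Site3: R = 12.7 %, D = +1 s
Site2 vs Site3: R = 2.0 %, D = +0 s
```

Site 1 (nearest the highway) has mean inter-peak lags 15.0 % and 12.7 %
longer than Sites 2 and 3 — i.e. sparser high-frequency acoustic events
near the disturbance.

Ground-truth recovery on one synthetic minute — chirp events every 10 s
in 3–6 kHz over a low-frequency noise floor:

```python
import numpy as np
from wavescape.synth import chirp_train, colored_noise
from wavescape.modwt import modwt
from wavescape.energy import leq_series
from wavescape.peaks import PeakMode, find_peaks, inter_peak_lags

clip = chirp_train(band=(3000, 6000), duration=60.0, fs=48000,
                   spacing=10.0, offset=5.5, event_duration=4.5,
                   level_db=75, seed=0)
clip.samples += colored_noise(1.0, (20, 375), 60.0, 48000,
                              seed=1, level_db=60).samples
dec = modwt(clip.samples, "d4", J=10)
w3 = [s for s in leq_series(clip, dec, tau=1.0) if s.band == "W3"][0]
peaks = find_peaks(w3, PeakMode(2, 2))
print(np.median(inter_peak_lags(peaks)))   # -> 10.0
```

The events land in W3 (3–6 kHz at 48 kHz) and the pooled median
inter-peak lag recovers the 10 s spacing exactly (the noise floor adds
an occasional extra peak, which the median absorbs).

## Command line

```sh
wavescape synth   --config scene.yaml --out audio/        # render a session
wavescape analyze --manifest audio/manifest.csv --out out/
wavescape compare --bundle out/S1 --bundle out/S2 --out cmp/
```

`analyze` writes, per site: `leq_1s.csv`, `leq_hourly.csv`, `peaks.csv`,
`lag_stats.csv`, `acf.csv`, `fits.csv` and a `run_log.json` (versions,
config hash). `compare` writes the cross-site lag table (R/D) and the
shared-β γ-by-level table.

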