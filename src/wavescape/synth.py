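"""Synthetic soundscape scenes for fixtures and validation.

Generates the ingredients of a duty-cycled woodland monitoring session:
diel-modulated high-frequency biophony (chirp trains standing in for bird
vocalizations, 3-8 kHz), band-limited low-frequency colored-noise
technophony (traffic/wind surrogate), broadband transient events (train
pass-bys), and pure calibration tones — written as 1-minute 16-bit WAV
files on a 1-min-on / 5-min-off duty cycle with an ISO-timestamped
manifest.

Level convention: ``level_db`` is the Leq (re p0 = 20 uPa) that the
component produces when the digital samples are read back and analyzed
without calibration, i.e. one full-scale unit is treated as one pascal.
Under this convention a full-scale sine sits at ~91 dB, so realistic
woodland levels (30-75 dB) leave ample headroom.  All randomness flows
from numpy's seeded PCG64 generator, spawned per file from
(seed, hour, clip index), so fixed-seed scenes are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import chirp as _chirp

from .audio_io import P0, AudioClip, write_wav

__all__ = [
    "SourceSpec",
    "SceneConfig",
    "pure_tone",
    "chirp_train",
    "colored_noise",
    "transient_events",
    "render_clip",
    "render_session",
    "dawn_diel_profile",
    "rms_for_level",
    "poisson_event_times",
]


def rms_for_level(level_db: float, p0: float = P0) -> float:
    """RMS (full-scale units == Pa under the synth convention) for a target Leq."""
    return p0 * 10.0 ** (level_db / 20.0)


def pure_tone(
    freq: float,
    duration: float,
    amplitude: float = 0.1,
    fs: float = 48000.0,
    site_id: str = "",
) -> AudioClip:
    """Zero-phase sine; Leq = 10*log10(A^2 / (2 p0^2))."""
    if not 0 < freq < fs / 2:
        raise ValueError(f"frequency {freq} Hz outside (0, Nyquist={fs / 2}) Hz")
    t = np.arange(int(round(duration * fs))) / fs
    return AudioClip(amplitude * np.sin(2 * np.pi * freq * t), fs, site_id=site_id)


def poisson_event_times(
    rate_per_min: float, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Sorted event times (s) of a homogeneous Poisson process."""
    if rate_per_min < 0:
        raise ValueError("rate must be >= 0")
    n_events = rng.poisson(rate_per_min * duration / 60.0)
    return np.sort(rng.uniform(0.0, duration, size=n_events))


def _chirp_event(fs: float, event_duration: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-peak linear FM sweep across ``band`` with a Hann envelope."""
    n = max(int(round(event_duration * fs)), 2)
    t = np.arange(n) / fs
    sweep = _chirp(t, f0=band[0], f1=band[1], t1=event_duration, method="linear")
    return sweep * np.hanning(n)


def chirp_train(
    rate_per_min: float = 6.0,
    band: tuple[float, float] = (3000.0, 8000.0),
    duration: float = 60.0,
    fs: float = 48000.0,
    seed: int | np.random.Generator | None = 0,
    event_duration: float = 0.2,
    level_db: float = 70.0,
    spacing: float | None = None,
    offset: float = 0.5,
    site_id: str = "",
) -> AudioClip:
    """Train of FM sweeps, Poisson-placed or at deterministic spacing.

    With ``spacing`` given, event centers sit at offset, offset+spacing,
    ... (deterministic ground truth for lag-recovery tests); otherwise
    event times are a Poisson process of the given rate.  ``level_db``
    sets the sine-equivalent level of an event at its envelope peak.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    x = np.zeros(n)
    if spacing is not None:
        centers = np.arange(offset, duration, spacing)
    else:
        centers = poisson_event_times(rate_per_min, duration, rng)
    amp = np.sqrt(2.0) * rms_for_level(level_db)
    event = amp * _chirp_event(fs, event_duration, band)
    half = len(event) // 2
    for c in centers:
        i0 = int(round(c * fs)) - half
        lo, hi = max(i0, 0), min(i0 + len(event), n)
        if hi > lo:
            x[lo:hi] += event[lo - i0 : hi - i0]
    return AudioClip(x, fs, site_id=site_id)


def colored_noise(
    spectral_exponent: float = 1.0,
    band: tuple[float, float] | None = None,
    duration: float = 60.0,
    fs: float = 48000.0,
    seed: int | np.random.Generator | None = 0,
    level_db: float | None = None,
    site_id: str = "",
) -> AudioClip:
    """Spectral-synthesis 1/f^alpha noise, optionally band-limited.

    Power spectral density is proportional to f^-alpha inside ``band``
    (whole spectrum when None) and zero outside.  Output RMS is 1.0
    unless ``level_db`` sets an absolute level.
    """
    alpha = spectral_exponent
    if not 0 <= alpha <= 2:
        raise ValueError("spectral_exponent must lie in [0, 2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    n_bins = n // 2 + 1
    df = fs / n
    # only the in-band bins carry power; synthesize just that slice
    lo = 1 if band is None else max(int(np.ceil(band[0] / df)), 1)
    hi = n_bins - 1 if band is None else min(int(np.floor(band[1] / df)), n_bins - 1)
    if hi < lo:
        raise ValueError("band contains no Fourier bins at this duration/rate")
    freqs = df * np.arange(lo, hi + 1)
    mag = freqs ** (-alpha / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=len(freqs))
    spec = np.zeros(n_bins, dtype=complex)
    spec[lo : hi + 1] = mag * np.exp(1j * phases)
    if n % 2 == 0 and hi == n_bins - 1:
        spec[-1] = mag[-1]  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise ValueError("band contains no Fourier bins at this duration/rate")
    x /= rms
    if level_db is not None:
        x *= rms_for_level(level_db)
    return AudioClip(x, fs, site_id=site_id)


def transient_events(
    rate_per_min: float = 1.0,
    duration: float = 60.0,
    fs: float = 48000.0,
    seed: int | np.random.Generator | None = 0,
    burst_duration: float = 1.0,
    level_db: float = 70.0,
    site_id: str = "",
) -> AudioClip:
    """Poisson-placed broadband noise bursts (train/pass-by surrogate)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    x = np.zeros(n)
    n_events = rng.poisson(rate_per_min * duration / 60.0)
    centers = np.sort(rng.uniform(0.0, duration, size=n_events))
    m = max(int(round(burst_duration * fs)), 2)
    env = np.hanning(m)
    target_rms = rms_for_level(level_db)
    for c in centers:
        burst = env * rng.standard_normal(m)
        burst *= target_rms / np.sqrt(np.mean(burst**2))
        i0 = int(round(c * fs)) - m // 2
        lo, hi = max(i0, 0), min(i0 + m, n)
        if hi > lo:
            x[lo:hi] += burst[lo - i0 : hi - i0]
    return AudioClip(x, fs, site_id=site_id)


@dataclass
class SourceSpec:
    """One scene component.

    ``diel`` components have the scene's hourly gain curve applied to
    their level (biophony); non-diel components are stationary across the
    day (technophony floor).
    """

    kind: str  # pure_tone | chirp_train | colored_noise | transient_event
    band: tuple[float, float] = (3000.0, 8000.0)
    level_db: float = 60.0
    rate_per_min: float = 6.0
    spectral_exponent: float = 1.0
    event_duration: float = 0.2
    spacing: float | None = None
    offset: float = 0.5
    freq: float = 1000.0
    diel: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError(f"invalid band {self.band}")


@dataclass
class SceneConfig:
    """A reproducible scene: components + diel gain curve + seed."""

    components: list[SourceSpec]
    duration: float = 60.0
    sample_rate: float = 48000.0
    seed: int = 0
    diel_profile: np.ndarray | None = None  # 24 hourly gains, dB

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.diel_profile is not None:
            self.diel_profile = np.asarray(self.diel_profile, dtype=float)
            if len(self.diel_profile) != 24:
                raise ValueError("diel_profile needs 24 hourly values")


def dawn_diel_profile(peak_hour: int = 6, depth_db: float = 12.0, width_h: float = 3.0) -> np.ndarray:
    """Gaussian dawn-chorus gain curve: 0 dB at the peak hour, -depth at night."""
    hours = np.arange(24)
    dist = np.minimum(np.abs(hours - peak_hour), 24 - np.abs(hours - peak_hour))
    return -depth_db * (1.0 - np.exp(-(dist**2) / (2.0 * width_h**2)))


def render_clip(scene: SceneConfig, hour: int, rng: np.random.Generator, site_id: str = "") -> AudioClip:
    """Render one clip: sum of components with the hour's diel gain."""
    fs, dur = scene.sample_rate, scene.duration
    gain_db = 0.0
    if scene.diel_profile is not None:
        gain_db = float(scene.diel_profile[hour % 24])
    x = np.zeros(int(round(dur * fs)))
    for comp in scene.components:
        level = comp.level_db + (gain_db if comp.diel else 0.0)
        if comp.kind == "pure_tone":
            clip = pure_tone(comp.freq, dur, np.sqrt(2.0) * rms_for_level(level), fs)
        elif comp.kind == "chirp_train":
            clip = chirp_train(
                comp.rate_per_min, comp.band, dur, fs, rng,
                comp.event_duration, level, comp.spacing, comp.offset,
            )
        elif comp.kind == "colored_noise":
            clip = colored_noise(comp.spectral_exponent, comp.band, dur, fs, rng, level)
        elif comp.kind == "transient_event":
            clip = transient_events(comp.rate_per_min, dur, fs, rng, comp.event_duration, level)
        else:
            raise ValueError(f"unknown source kind {comp.kind!r}")
        x += clip.samples
    return AudioClip(x, fs, site_id=site_id)


def render_session(
    scene: SceneConfig,
    site_id: str,
    out_dir: str | Path,
    hours: range | list[int] = range(24),
    clips_per_hour: int = 10,
    start_date: datetime = datetime(2021, 6, 1),
    pause_s: float = 300.0,
) -> pd.DataFrame:
    """Write a duty-cycled session of WAV files plus a manifest CSV.

    One clip every ``duration + pause`` seconds (default: 1 min on, 5 min
    off, 10 clips/hour).  If more than 1% of a clip's samples clip at
    full scale a warning is issued and the clip is peak-normalized.
    Returns the manifest (columns path, site_id, start_time).
    """
    import warnings

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    step = timedelta(seconds=scene.duration + pause_s)
    rows = []
    for hour in hours:
        for idx in range(clips_per_hour):
            child = np.random.default_rng(
                np.random.SeedSequence(entropy=scene.seed, spawn_key=(hour, idx))
            )
            clip = render_clip(scene, hour, child, site_id=site_id)
            n_clipped = int(np.sum(np.abs(clip.samples) >= 1.0))
            if n_clipped > 0.01 * len(clip):
                warnings.warn(
                    f"{site_id} h{hour:02d}c{idx}: {n_clipped} samples at full "
                    "scale; peak-normalizing"
                )
                clip.samples = clip.samples / np.max(np.abs(clip.samples)) * 0.99
            start = start_date.replace(hour=hour, minute=0, second=0) + idx * step
            name = f"{site_id}_{start:%Y%m%d_%H%M%S}.wav"
            write_wav(out_dir / name, clip)
            rows.append({"path": name, "site_id": site_id, "start_time": start.isoformat()})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
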