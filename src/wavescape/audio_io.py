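"""WAV input/output, calibration, and duty-cycled session assembly.

Field deployments here follow a 1-minute-on / 5-minutes-off duty cycle
(10 one-minute files per hour).  Clips are read as full-scale floats in
[-1, 1); an optional calibration assigns a dB SPL value to a full-scale
sine so that Leq values are absolute rather than relative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger(__name__)

__all__ = [
    "AudioClip",
    "CalibrationConfig",
    "SessionLayout",
    "read_wav",
    "write_wav",
    "normalize_energy",
    "assemble_session",
    "load_manifest",
]

#: reference sound pressure, 20 micropascal
P0 = 2.0e-5

_INT_SCALES = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31}


@dataclass
class AudioClip:
    """One mono recording.

    ``samples`` are linear pressure values: full-scale units in [-1, 1)
    straight off disk, or pascal once a calibration has been applied.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: datetime | None = None
    site_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("AudioClip holds a single mono channel")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class CalibrationConfig:
    """Maps digital full scale to sound pressure.

    ``full_scale_db`` is the SPL assigned to a full-scale sine (RMS
    1/sqrt(2) in digital units).  ``normalization_mode``:

    - ``"none"``: identity; Leq values are relative to digital full scale.
    - ``"per_file_energy"``: each file is rescaled so its broadband mean
      square equals the reference mean square implied by
      ``full_scale_db`` — a flat per-file energy reference that preserves
      all relative band-level structure within the file.
    """

    p0: float = P0
    full_scale_db: float | None = None
    normalization_mode: str = "none"

    def __post_init__(self) -> None:
        if self.p0 <= 0:
            raise ValueError("p0 must be positive")
        if self.normalization_mode not in ("none", "per_file_energy"):
            raise ValueError(f"unknown normalization_mode {self.normalization_mode!r}")


def read_wav(
    path: str | Path,
    site_id: str = "",
    start_time: datetime | str | None = None,
) -> AudioClip:
    """Read a PCM WAV file as full-scale floats.

    Integer samples are scaled by the type's full-scale magnitude (e.g.
    int16 -32768 maps to -1.0).  Stereo files keep channel 0 with a
    warning.  WAV carries no timestamp, so ``start_time`` comes from the
    caller (manifest or filename pattern).
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(path)
    except ValueError as exc:
        raise ValueError(f"cannot read {path} as PCM WAV: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"{path} contains no samples")
    if data.ndim > 1:
        warnings.warn(f"{path.name}: {data.shape[1]} channels, keeping channel 0")
        data = data[:, 0]
    if data.dtype in _INT_SCALES:
        samples = data / _INT_SCALES[data.dtype]
    elif data.dtype == np.dtype("uint8"):  # 8-bit WAV is offset binary
        samples = (data.astype(float) - 128.0) / 128.0
    else:  # 24-bit arrives as int32-like from scipy>=1.14, floats as-is
        samples = data.astype(float)
        if np.issubdtype(data.dtype, np.integer):
            samples /= float(2 ** (8 * data.dtype.itemsize - 1))
    if isinstance(start_time, str):
        start_time = datetime.fromisoformat(start_time)
    return AudioClip(samples=samples, sample_rate=float(fs), start_time=start_time, site_id=site_id)


def write_wav(path: str | Path, clip: AudioClip, subtype: str = "int16") -> None:
    """Write a clip as 16-bit PCM (full-scale floats quantized to int16)."""
    if subtype != "int16":
        raise ValueError("only 16-bit PCM output is supported")
    q = np.clip(np.round(clip.samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(clip.sample_rate), q)


def normalize_energy(clip: AudioClip, cal: CalibrationConfig) -> AudioClip:
    """Apply per-file energy normalization (a pure gain) per ``cal``.

    In ``per_file_energy`` mode the output mean square equals
    ``p0^2 * 10^(full_scale_db/10)``, so the file's broadband Leq becomes
    exactly ``full_scale_db``; the operation is idempotent.  In ``none``
    mode the clip is returned unchanged.
    """
    if cal.normalization_mode == "none":
        return clip
    if cal.full_scale_db is None:
        raise ValueError("per_file_energy normalization needs full_scale_db")
    ms = float(np.mean(clip.samples**2))
    if ms == 0.0:
        raise ValueError("all-zero clip: per-file energy gain is undefined")
    target_ms = cal.p0**2 * 10.0 ** (cal.full_scale_db / 10.0)
    gain = np.sqrt(target_ms / ms)
    return replace(clip, samples=clip.samples * gain)


@dataclass
class SessionLayout:
    """Clips of one site grouped by clock hour of their start time."""

    clips: list[AudioClip]
    hour_groups: dict[datetime, list[AudioClip]] = field(default_factory=dict)
    incomplete_hours: list[datetime] = field(default_factory=list)
    duty_cycle: tuple[int, int] = (60, 300)  # record_s, pause_s
    clips_per_hour: int = 10


def assemble_session(clips: list[AudioClip], clips_per_hour: int = 10) -> SessionLayout:
    """Group clips into hourly batches.

    Hours with fewer than ``clips_per_hour`` clips are flagged in
    ``incomplete_hours`` but kept.  Mixed sample rates are rejected.
    """
    if not clips:
        return SessionLayout(clips=[], clips_per_hour=clips_per_hour)
    rates = {c.sample_rate for c in clips}
    if len(rates) > 1:
        raise ValueError(f"clips mix sample rates: {sorted(rates)}")
    sites = {c.site_id for c in clips}
    if len(sites) > 1:
        raise ValueError(f"clips mix sites: {sorted(sites)}")
    if any(c.start_time is None for c in clips):
        raise ValueError("every clip needs a start_time to be placed in an hour")
    ordered = sorted(clips, key=lambda c: c.start_time)
    groups: dict[datetime, list[AudioClip]] = {}
    for c in ordered:
        hour = c.start_time.replace(minute=0, second=0, microsecond=0)
        groups.setdefault(hour, []).append(c)
    incomplete = [h for h, g in groups.items() if len(g) < clips_per_hour]
    for h in incomplete:
        logger.warning("hour %s has %d clips (nominal %d)", h, len(groups[h]), clips_per_hour)
    return SessionLayout(
        clips=ordered,
        hour_groups=groups,
        incomplete_hours=incomplete,
        clips_per_hour=clips_per_hour,
    )


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a session manifest CSV (columns: path, site_id, start_time)."""
    df = pd.read_csv(path)
    required = {"path", "site_id", "start_time"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    df["start_time"] = pd.to_datetime(df["start_time"])
    base = Path(path).parent
    df["path"] = [str(p) if Path(p).is_absolute() else str(base / p) for p in df["path"]]
    return df
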