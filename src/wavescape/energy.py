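"""Equivalent continuous sound pressure level (Leq) at any window length.

Leq over a window of length tau is 10*log10(<p^2>/p0^2), the dB level of
the time-averaged squared pressure relative to p0 = 20 uPa.  It is
computed identically for the broadband signal and for each MODWT detail
series (wavelet coefficients are treated as pressure-like signals in the
input's units, so band levels share the broadband dB axis).

Aggregation to coarser windows (e.g. 1 s -> 1 h) is energetic: dB values
are averaged as linear energies, never as decibels.  For duty-cycled
sessions an hourly value is the energetic mean over the recorded minutes
only (600 one-second windows for a 10-files-per-hour cycle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import P0, AudioClip
from .modwt import WaveletDecomposition

__all__ = ["LeqSeries", "leq", "leq_series", "leq_aggregate", "energetic_mean"]

#: sentinel for an all-zero (silent) window
SILENT = -np.inf


@dataclass
class LeqSeries:
    """Leq values on contiguous non-overlapping windows of length tau."""

    values: np.ndarray  # dB re p0; -inf marks silent windows
    tau: float
    band: str  # "FULL", "W1".."WJ", or "smooth"
    site_id: str = ""
    start_offset: float = 0.0  # s from clip start of first window

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def window_starts(self) -> np.ndarray:
        return self.start_offset + self.tau * np.arange(len(self.values))


def leq(segment: np.ndarray, p0: float = P0) -> float:
    """Leq of one segment: 10*log10(mean(p^2)/p0^2); silent -> -inf."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("empty segment")
    ms = float(np.mean(segment**2))
    if ms == 0.0:
        return SILENT
    return 10.0 * np.log10(ms / p0**2)


def _windowed_leq(x: np.ndarray, n_win: int, win: int, p0: float) -> np.ndarray:
    ms = np.mean(x[: n_win * win].reshape(n_win, win) ** 2, axis=1)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(ms / p0**2)


def leq_series(
    clip: AudioClip,
    dec: WaveletDecomposition | None = None,
    tau: float = 1.0,
    p0: float = P0,
) -> list[LeqSeries]:
    """Leq on windows of ``tau`` seconds for FULL and (if given) each band.

    All bands share the same windowing.  A trailing partial window is
    dropped.  Returns FULL first, then W1..WJ and the smooth series.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    win = int(round(tau * clip.sample_rate))
    if win < 1 or win > len(clip):
        raise ValueError(f"window of {tau} s does not fit a {clip.duration:.3f} s clip")
    n_win = len(clip) // win
    out = [
        LeqSeries(
            values=_windowed_leq(clip.samples, n_win, win, p0),
            tau=tau,
            band="FULL",
            site_id=clip.site_id,
        )
    ]
    if dec is not None:
        for name in dec.band_names():
            out.append(
                LeqSeries(
                    values=_windowed_leq(dec.band(name), n_win, win, p0),
                    tau=tau,
                    band=name,
                    site_id=clip.site_id,
                )
            )
    return out


def energetic_mean(values_db: np.ndarray) -> float:
    """Mean of dB values on the energy scale; silent sentinels excluded."""
    values_db = np.asarray(values_db, dtype=float)
    finite = values_db[np.isfinite(values_db)]
    if finite.size == 0:
        return SILENT
    return 10.0 * np.log10(np.mean(10.0 ** (finite / 10.0)))


def leq_aggregate(series: LeqSeries, target_tau: float) -> LeqSeries:
    """Aggregate to a coarser window by energetic averaging.

    ``target_tau`` must be an integer multiple of ``series.tau``; a
    trailing group shorter than the full factor is dropped.
    """
    factor = target_tau / series.tau
    if abs(factor - round(factor)) > 1e-9 or round(factor) < 1:
        raise ValueError("target_tau must be a positive multiple of series.tau")
    k = int(round(factor))
    n_out = len(series.values) // k
    if n_out == 0:
        return LeqSeries(np.array([]), tau=target_tau, band=series.band, site_id=series.site_id)
    grouped = series.values[: n_out * k].reshape(n_out, k)
    agg = np.array([energetic_mean(row) for row in grouped])
    return LeqSeries(
        values=agg,
        tau=target_tau,
        band=series.band,
        site_id=series.site_id,
        start_offset=series.start_offset,
    )
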