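"""Run-length peak detection on Leq time series and inter-peak statistics.

A position is a peak in mode (nups, ndowns) when the nups consecutive
first differences ending there are all strictly positive and the ndowns
differences that follow are all strictly negative.  The two modes used
for soundscape work are (1,1) — rapid fluctuations, short-lived events —
and (2,2), which acts as a low-pass filter emphasizing structured events.
Zero differences break a run by default (ties are neither rises nor
falls), matching the default of the widely used R ``findpeaks`` routine.

Inter-peak lags are first differences of peak times within a single clip;
they are never taken across the silent gaps of a duty cycle, which would
inject artificial >=300 s intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import LeqSeries

__all__ = [
    "PeakMode",
    "PeakSet",
    "LagStats",
    "LagComparison",
    "find_peaks",
    "inter_peak_lags",
    "lag_stats",
    "compare_sites",
    "hourly_peak_rate",
]


@dataclass(frozen=True)
class PeakMode:
    nups: int = 1
    ndowns: int = 1

    def __post_init__(self) -> None:
        if self.nups < 1 or self.ndowns < 1:
            raise ValueError("nups and ndowns must be >= 1")

    def __str__(self) -> str:
        return f"({self.nups}-{self.ndowns})"


@dataclass
class PeakSet:
    """Peak positions (window indices) of one series under one mode."""

    indices: np.ndarray
    mode: PeakMode
    band: str = ""
    tau: float = 1.0
    clip_ref: str = ""

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class LagStats:
    mean_lag: float  # s; nan when no lags
    median_lag: float  # s; lower-median on even counts (stays on the grid)
    n_peaks: int
    n_lags: int
    site_id: str = ""
    band: str = ""


@dataclass
class LagComparison:
    pair: tuple[str, str]
    band: str
    R: float  # percent, >= 0 by construction
    D: float  # s, median_i - median_j (sign follows pair order)


def find_peaks(
    series: LeqSeries | np.ndarray,
    mode: PeakMode = PeakMode(1, 1),
    zero_continues: bool = False,
) -> PeakSet:
    """Detect run-length peaks.

    With ``zero_continues`` a zero difference extends the current run
    instead of breaking it (the tie-tolerant variant).  A series shorter
    than nups + ndowns + 1 yields an empty PeakSet.
    """
    if isinstance(series, LeqSeries):
        x = series.values
        band, tau = series.band, series.tau
    else:
        x = np.asarray(series, dtype=float)
        band, tau = "", 1.0
    n = len(x)
    need = mode.nups + mode.ndowns + 1
    if n < need:
        return PeakSet(np.array([], dtype=int), mode, band=band, tau=tau)
    d = np.diff(x)
    if zero_continues:
        up = d >= 0
        down = d <= 0
    else:
        up = d > 0
        down = d < 0
    # run_up[i]: all of d[i-nups+1 .. i] are rises (valid from i = nups-1)
    up_ok = np.ones(n - 1, dtype=bool)
    down_ok = np.ones(n - 1, dtype=bool)
    for k in range(mode.nups):
        shifted = np.roll(up, k)
        shifted[:k] = False
        up_ok &= shifted
    for k in range(mode.ndowns):
        shifted = np.roll(down, -k)
        shifted[n - 1 - k :] = False
        down_ok &= shifted
    # peak at i needs up-run ending at diff i-1 and down-run starting at diff i
    candidates = np.arange(mode.nups, n - mode.ndowns)
    hits = candidates[up_ok[candidates - 1] & down_ok[candidates]]
    if zero_continues and len(hits):
        # a flat top satisfies the relaxed runs at every plateau sample;
        # report only the first (the convention of the R reference routine)
        keep = [hits[0]]
        for idx in hits[1:]:
            prev = keep[-1]
            if x[idx] == x[prev] and np.all(x[prev : idx + 1] == x[idx]):
                continue
            keep.append(idx)
        hits = np.array(keep, dtype=int)
    return PeakSet(hits, mode, band=band, tau=tau)


def inter_peak_lags(peaks: PeakSet) -> np.ndarray:
    """Lags (s) between consecutive peaks of one clip; <2 peaks -> empty."""
    if len(peaks) < 2:
        return np.array([])
    return np.diff(peaks.indices) * peaks.tau


def _lower_median(values: np.ndarray) -> float:
    ordered = np.sort(values)
    return float(ordered[(len(ordered) - 1) // 2])


def lag_stats(
    lags: np.ndarray,
    n_peaks: int | None = None,
    site_id: str = "",
    band: str = "",
    median: str = "lower",
) -> LagStats:
    """Pooled lag statistics for one site x band.

    ``median="lower"`` reports the lower order statistic on even counts so
    medians of integer-second lags stay integers; ``"midpoint"`` uses the
    conventional average of the two central values.
    """
    lags = np.asarray(lags, dtype=float)
    if n_peaks is None:
        n_peaks = len(lags) + 1 if len(lags) else 0
    if len(lags) == 0:
        return LagStats(np.nan, np.nan, n_peaks, 0, site_id, band)
    med = _lower_median(lags) if median == "lower" else float(np.median(lags))
    return LagStats(float(np.mean(lags)), med, int(n_peaks), len(lags), site_id, band)


def compare_sites(stats: dict[str, LagStats], band: str = "") -> list[LagComparison]:
    """Pairwise R and D statistics across sites sharing one band.

    R = 100 * (larger mean lag - smaller mean lag) / smaller mean lag
    (order-invariant, >= 0); D = median_i - median_j in the fixed pair
    order given by sorting the site labels, so D is antisymmetric.
    """
    sites = sorted(stats)
    if len(sites) < 2:
        raise ValueError("need at least two sites to compare")
    out = []
    for a_idx in range(len(sites)):
        for b_idx in range(a_idx + 1, len(sites)):
            a, b = sites[a_idx], sites[b_idx]
            m_a, m_b = stats[a].mean_lag, stats[b].mean_lag
            lo, hi = min(m_a, m_b), max(m_a, m_b)
            r = np.nan if lo == 0 else 100.0 * (hi - lo) / lo
            d = stats[a].median_lag - stats[b].median_lag
            out.append(LagComparison(pair=(a, b), band=band or stats[a].band, R=r, D=d))
    return out


def hourly_peak_rate(
    peaks_by_hour: dict,
    record_s_per_hour: float = 600.0,
) -> dict:
    """Peak counts per hour of recorded audio.

    ``peaks_by_hour`` maps an hour key to the list of PeakSets from that
    hour's clips.  Returns, per hour, the raw count over the recorded
    minutes and the count extrapolated to a full hour (labelled
    explicitly, since a 1-on/5-off duty cycle records only 10 min/h).
    """
    factor = 3600.0 / record_s_per_hour
    out = {}
    for hour, sets in peaks_by_hour.items():
        raw = int(sum(len(p) for p in sets))
        out[hour] = {"count_recorded": raw, "count_per_hour_extrapolated": raw * factor}
    return out
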