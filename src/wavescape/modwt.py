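"""Maximal-overlap discrete wavelet transform (MODWT).

The MODWT is an undecimated, shift-equivariant wavelet transform: every
detail series W1..WJ and the level-J smooth VJ have the same length as the
input, and their energies sum exactly to the input energy.  Level j
nominally covers the dyadic octave band (fs/2^(j+1), fs/2^j], so at
fs = 48 kHz the first four levels span the biophony-rich range above
1.5 kHz while W8-W10 hold low-frequency geophony/technophony.

Filters follow the standard convention: the MODWT scaling taps are the
orthonormal DWT scaling taps divided by sqrt(2) (so they sum to 1 and
their squares sum to 1/2) and the wavelet taps are the quadrature-mirror
image of the scaling taps.

The transform is computed with FFT-based circular convolution using the
per-level equivalent transfer functions.  This is algebraically identical
to the time-domain pyramid recursion

    W_j[t] = sum_l h_l V_{j-1}[(t - 2^(j-1) l) mod N]
    V_j[t] = sum_l g_l V_{j-1}[(t - 2^(j-1) l) mod N]

but runs in O(J N log N), which keeps a 24 h duty-cycled site (240 one-
minute files at 48 kHz) tractable on a single core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WaveletFilter",
    "WaveletDecomposition",
    "LevelBand",
    "get_filter",
    "modwt",
    "level_energies",
    "level_band",
    "max_level",
]

_SQRT3 = np.sqrt(3.0)
_DENOM = 4.0 * np.sqrt(2.0)

# Orthonormal DWT scaling (low-pass) taps.  d4 is exact; d8 (Daubechies
# extremal phase, 4 vanishing moments) and la8 (least asymmetric /
# Symlet, 4 vanishing moments) are the canonical published coefficients.
_DWT_SCALING_TAPS = {
    "d4": np.array(
        [
            (1.0 + _SQRT3) / _DENOM,
            (3.0 + _SQRT3) / _DENOM,
            (3.0 - _SQRT3) / _DENOM,
            (1.0 - _SQRT3) / _DENOM,
        ]
    ),
    "d8": np.array(
        [
            0.2303778133088965,
            0.7148465705529157,
            0.6308807679298589,
            -0.027983769416859854,
            -0.18703481171909309,
            0.030841381835560764,
            0.0328830116668852,
            -0.010597401785069032,
        ]
    ),
    "la8": np.array(
        [
            0.0322231006040427,
            -0.012603967262037833,
            -0.09921954357684722,
            0.29785779560527736,
            0.8037387518059161,
            0.49761866763201545,
            -0.02963552764599851,
            -0.07576571478927333,
        ]
    ),
}


@dataclass(frozen=True)
class WaveletFilter:
    """MODWT-rescaled filter pair.

    ``scaling_taps`` sum to 1 and have squared sum 1/2; ``wavelet_taps``
    are the quadrature mirror ``h_l = (-1)^l g_{L-1-l}`` and sum to 0.
    """

    name: str
    scaling_taps: np.ndarray
    wavelet_taps: np.ndarray

    @property
    def length(self) -> int:
        return len(self.scaling_taps)


def get_filter(name: str) -> WaveletFilter:
    """Return the d4, d8 or la8 filter pair rescaled for the MODWT."""
    try:
        g_dwt = _DWT_SCALING_TAPS[name]
    except KeyError:
        raise ValueError(
            f"unknown wavelet filter {name!r}; choose from {sorted(_DWT_SCALING_TAPS)}"
        ) from None
    g = g_dwt / np.sqrt(2.0)
    L = len(g)
    h = ((-1.0) ** np.arange(L)) * g[::-1]
    return WaveletFilter(name=name, scaling_taps=g, wavelet_taps=h)


@dataclass
class LevelBand:
    """Nominal dyadic passband of detail level j: (fs/2^(j+1), fs/2^j]."""

    level: int
    f_low: float
    f_high: float


def level_band(j: int, fs: float, J: int | None = None) -> LevelBand:
    """Nominal frequency band of detail level ``j`` at sample rate ``fs``."""
    if j < 1 or (J is not None and j > J):
        raise ValueError(f"level {j} out of range" + (f" 1..{J}" if J else ""))
    return LevelBand(level=j, f_low=fs / 2 ** (j + 1), f_high=fs / 2**j)


def max_level(n: int, filter_length: int) -> int:
    """Largest J such that the level-J equivalent filter fits n samples."""
    J = 0
    while (2 ** (J + 1) - 1) * (filter_length - 1) + 1 < n:
        J += 1
    return J


@dataclass
class WaveletDecomposition:
    """MODWT of one series: J same-length details plus the level-J smooth."""

    details: list[np.ndarray]
    smooth: np.ndarray
    filter: WaveletFilter
    boundary: str = "circular"
    J: int = field(init=False)

    def __post_init__(self) -> None:
        self.J = len(self.details)

    def band_names(self) -> list[str]:
        return [f"W{j}" for j in range(1, self.J + 1)] + ["smooth"]

    def band(self, name: str) -> np.ndarray:
        if name == "smooth":
            return self.smooth
        return self.details[int(name[1:]) - 1]


def _transfer(taps: np.ndarray, stride: int, n: int) -> np.ndarray:
    """DFT (rfft grid) of taps upsampled by ``stride`` on a length-n circle."""
    k = np.arange(n // 2 + 1)
    out = np.zeros(n // 2 + 1, dtype=complex)
    for l, c in enumerate(taps):
        out += c * np.exp(-2j * np.pi * ((stride * l) % n) * k / n)
    return out


_MULTIPLIER_CACHE: dict[tuple, np.ndarray] = {}


def _level_multipliers(filt: WaveletFilter, J: int, n: int) -> np.ndarray:
    """(J+1, n//2+1) rfft-grid gains: rows 0..J-1 map input to W1..WJ,
    row J maps it to VJ.  Cached: analysing a duty-cycled session applies
    the same multipliers to hundreds of equal-length clips."""
    key = (filt.name, tuple(filt.scaling_taps), J, n)
    cached = _MULTIPLIER_CACHE.get(key)
    if cached is not None:
        return cached
    # exp table for the whole circle lets each upsampled-filter DFT be a
    # gather instead of a fresh complex-exponential evaluation
    circle = np.exp(-2j * np.pi * np.arange(n) / n)
    k = np.arange(n // 2 + 1)
    out = np.empty((J + 1, n // 2 + 1), dtype=complex)
    cumulative = np.ones(n // 2 + 1, dtype=complex)
    for j in range(1, J + 1):
        stride = 2 ** (j - 1)
        base = circle[(stride * k) % n]
        term = np.ones(n // 2 + 1, dtype=complex)
        H = np.zeros(n // 2 + 1, dtype=complex)
        G = np.zeros(n // 2 + 1, dtype=complex)
        for h_l, g_l in zip(filt.wavelet_taps, filt.scaling_taps):
            H += h_l * term
            G += g_l * term
            term = term * base
        out[j - 1] = H * cumulative
        cumulative = cumulative * G
    out[J] = cumulative
    _MULTIPLIER_CACHE.clear()  # keep at most one (they are ~250 MB at 2.88 M samples)
    _MULTIPLIER_CACHE[key] = out
    return out


def modwt(
    x: np.ndarray,
    filt: WaveletFilter | str = "d4",
    J: int = 10,
    boundary: str = "circular",
) -> WaveletDecomposition:
    """Decompose ``x`` into J detail series and one smooth series.

    Parameters
    ----------
    x : one-dimensional signal (pressure samples or any series).
    filt : WaveletFilter or one of {"d4", "d8", "la8"}.
    J : number of decomposition levels (default 10, giving dyadic bands
        down to fs/2^11).
    boundary : "circular" (periodic, the convention under which the
        energy identity is exact) or "reflection" (the series is mirrored
        to length 2N before a circular transform; first N samples kept).
    """
    if isinstance(filt, str):
        filt = get_filter(filt)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("modwt expects a one-dimensional series")
    if J < 1:
        raise ValueError("J must be >= 1")
    n = len(x)
    min_n = (2**J - 1) * (filt.length - 1) + 1
    if n <= min_n:
        raise ValueError(
            f"series of length {n} too short for J={J} levels with the "
            f"{filt.name} filter (needs > {min_n} samples; max feasible "
            f"J = {max_level(n, filt.length)})"
        )
    if boundary == "reflection":
        ext = np.concatenate([x, x[::-1]])
        dec = modwt(ext, filt, J, boundary="circular")
        return WaveletDecomposition(
            details=[w[:n] for w in dec.details],
            smooth=dec.smooth[:n],
            filter=filt,
            boundary="reflection",
        )
    if boundary != "circular":
        raise ValueError(f"unknown boundary rule {boundary!r}")

    X = np.fft.rfft(x)
    mult = _level_multipliers(filt, J, n)
    details = [np.fft.irfft(mult[j] * X, n=n) for j in range(J)]
    smooth = np.fft.irfft(mult[J] * X, n=n)
    return WaveletDecomposition(details=details, smooth=smooth, filter=filt)


def level_energies(dec: WaveletDecomposition) -> dict[str, dict[str, float]]:
    """Per-band energies (sum of squared coefficients) and fractions.

    By the MODWT energy identity the band energies sum to the input
    energy, so fractions are taken with respect to their own total.
    """
    energies = {f"W{j + 1}": float(np.sum(w**2)) for j, w in enumerate(dec.details)}
    energies["smooth"] = float(np.sum(dec.smooth**2))
    total = sum(energies.values())
    fractions = {k: (v / total if total > 0 else 0.0) for k, v in energies.items()}
    return {"energy": energies, "fraction": fractions, "total": total}
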