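import numpy as np
import pytest

from wavescape.modwt import WaveletFilter


@pytest.fixture
def rng():
    return np.random.default_rng(20210601)


def brute_force_peaks(x, nups, ndowns, zero_continues=False):
    """Independent run-length peak scanner (direct definition, O(n*(nups+ndowns)))."""
    x = np.asarray(x, dtype=float)
    out = []
    for i in range(nups, len(x) - ndowns):
        if zero_continues:
            ups = all(x[i - k - 1] <= x[i - k] for k in range(nups))
            downs = all(x[i + k] >= x[i + k + 1] for k in range(ndowns))
        else:
            ups = all(x[i - k - 1] < x[i - k] for k in range(nups))
            downs = all(x[i + k] > x[i + k + 1] for k in range(ndowns))
        if ups and downs:
            out.append(i)
    return np.array(out, dtype=int)


def pyramid_modwt(x, filt: WaveletFilter, J: int):
    """Time-domain MODWT pyramid recursion (independent oracle for the FFT path)."""
    g, h = filt.scaling_taps, filt.wavelet_taps
    v = np.asarray(x, dtype=float).copy()
    details = []
    for j in range(1, J + 1):
        stride = 2 ** (j - 1)
        W = np.zeros_like(v)
        V = np.zeros_like(v)
        for l in range(len(g)):
            rolled = np.roll(v, stride * l)
            W += h[l] * rolled
            V += g[l] * rolled
        details.append(W)
        v = V
    return details, v
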