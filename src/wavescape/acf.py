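"""Temporal fractal analysis of Leq series via the autocorrelation function.

The normalized ACF of a 1 s Leq series is modeled as a power law with an
exponential cutoff,

    y(t) = y0 * t^(-gamma) * exp(-t / beta),

where gamma captures scale-invariant decay at short lags and beta the
crossover to short-range behavior.  The Hurst exponent follows
indirectly as H = 1 - gamma/2, valid in the persistent regime
0 < gamma < 1 (1/2 < H < 1, long memory); gamma >= 1 indicates
short-ranged correlations (H = 1/2, random-walk-like), and gamma <= 0 is
outside the domain of the relation (no H reported).

Fitting is nonlinear least squares in linear ACF space — log-space
fitting cannot represent the near-zero and negative gamma values that
quiet or noise-dominated bands produce — with lags of non-positive ACF
excluded.  The two-stage procedure first fits (y0, gamma, beta) freely
per site, then refits every site with beta fixed at the across-site mean,
reducing each site to two parameters and stabilizing gamma comparisons.

For duty-cycled sessions the ACF is computed over the concatenated
recorded seconds (gaps closed): lags are "recorded-time" lags, and the
usable fit range (~100 s) is well below the 300 s gap scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = [
    "AcfEstimate",
    "AcfFit",
    "HurstResult",
    "acf",
    "fit_acf_model",
    "two_stage_fit",
    "hurst_from_gamma",
    "acf_model",
]


@dataclass
class AcfEstimate:
    lags: np.ndarray  # 0..max_lag, s
    values: np.ndarray  # normalized; values[0] == 1
    n_obs: int
    site_id: str = ""
    band: str = ""


@dataclass
class AcfFit:
    y0: float
    gamma: float
    beta: float
    fit_range: tuple[float, float]
    residual_norm: float  # RMS of residuals over the fitted lags
    beta_fixed: bool
    n_used: int
    site_id: str = ""
    band: str = ""
    converged: bool = True


@dataclass
class HurstResult:
    H: float | None
    valid: bool
    regime: str  # persistent | random-walk-like | out-of-domain
    gamma: float


def acf(
    series: np.ndarray,
    max_lag: int = 100,
    site_id: str = "",
    band: str = "",
) -> AcfEstimate:
    """Mean-removed, biased (divide-by-n), lag-0-normalized ACF."""
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2 * max_lag:
        raise ValueError(f"series of {len(x)} usable points too short for max_lag={max_lag}")
    if np.ptp(x) == 0:
        raise ValueError("constant series has an undefined ACF")
    values = _sm_acf(x, nlags=max_lag, fft=True, adjusted=False)
    return AcfEstimate(
        lags=np.arange(max_lag + 1, dtype=float),
        values=values,
        n_obs=len(x),
        site_id=site_id,
        band=band,
    )


def acf_model(t: np.ndarray, y0: float, gamma: float, beta: float) -> np.ndarray:
    """Power law with exponential cutoff: y0 * t^-gamma * exp(-t/beta)."""
    t = np.asarray(t, dtype=float)
    return y0 * t ** (-gamma) * np.exp(-t / beta)


_GAMMA_STARTS = (0.1, -0.1, 0.5)


def fit_acf_model(
    est: AcfEstimate,
    fit_range: tuple[float, float] = (1.0, 100.0),
    beta_fix: float | None = None,
    weights: np.ndarray | None = None,
) -> AcfFit:
    """Least-squares fit of the cutoff power law on ``fit_range``.

    gamma is unconstrained in sign; beta is constrained positive.  With
    ``beta_fix`` only (y0, gamma) are free.  Lags with non-positive ACF
    are excluded; fewer than 10 usable lags is an error.
    """
    t_min, t_max = fit_range
    sel = (est.lags >= t_min) & (est.lags <= t_max) & (est.values > 0) & (est.lags > 0)
    t = est.lags[sel]
    y = est.values[sel]
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float)[sel])
    else:
        w = np.ones_like(t)
    if len(t) < 10:
        raise ValueError(f"only {len(t)} usable lags in fit range {fit_range} (need >= 10)")

    def make_residual(fixed_beta):
        if fixed_beta is None:

            def resid(p):
                return w * (acf_model(t, p[0], p[1], np.exp(p[2])) - y)

            return resid

        def resid(p):
            return w * (acf_model(t, p[0], p[1], fixed_beta) - y)

        return resid

    y0_start = float(y[0]) if y[0] > 0 else 1.0
    best = None
    for g0 in _GAMMA_STARTS:
        if beta_fix is None:
            # beta is fit as log(beta), bounded to [1, 1e4] s: an ACF with no
            # visible cutoff in the fit window would otherwise send beta to
            # infinity and poison the across-site mean of the two-stage fit
            p0 = [y0_start, g0, np.log(30.0)]
            bounds = ([1e-12, -10.0, 0.0], [1e3, 10.0, np.log(1e4)])
        else:
            p0 = [y0_start, g0]
            bounds = ([1e-12, -10.0], [1e3, 10.0])
        sol = least_squares(
            make_residual(beta_fix), p0, bounds=bounds, method="trf", max_nfev=5000
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost < 1e-20:
            best = sol
            break
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(f"ACF model fit failed for {est.site_id}/{est.band}")
    if beta_fix is None:
        y0_hat, gamma_hat, beta_hat = best.x[0], best.x[1], float(np.exp(best.x[2]))
    else:
        y0_hat, gamma_hat, beta_hat = best.x[0], best.x[1], float(beta_fix)
    rms = float(np.sqrt(np.mean((best.fun / w) ** 2)))
    return AcfFit(
        y0=float(y0_hat),
        gamma=float(gamma_hat),
        beta=beta_hat,
        fit_range=(float(t_min), float(t_max)),
        residual_norm=rms,
        beta_fixed=beta_fix is not None,
        n_used=len(t),
        site_id=est.site_id,
        band=est.band,
        converged=bool(best.success),
    )


def two_stage_fit(
    estimates: dict[str, AcfEstimate],
    fit_range: tuple[float, float] = (1.0, 100.0),
) -> tuple[dict[str, AcfFit], float]:
    """Shared-cutoff fitting across sites.

    Stage 1 fits (y0, gamma, beta) freely per site; stage 2 fixes beta at
    the arithmetic mean of the stage-1 betas and refits (y0, gamma).
    Sites whose stage-1 fit fails are excluded from the mean (warning)
    but still refit in stage 2.  Returns stage-2 fits and the shared beta.
    """
    import warnings

    if not estimates:
        raise ValueError("no ACF estimates supplied")
    stage1: dict[str, AcfFit] = {}
    for site, est in estimates.items():
        try:
            stage1[site] = fit_acf_model(est, fit_range)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"stage-1 fit failed for {site}: {exc}")
    if not stage1:
        raise RuntimeError("every stage-1 fit failed; no shared beta available")
    beta_shared = float(np.mean([f.beta for f in stage1.values()]))
    stage2 = {
        site: fit_acf_model(est, fit_range, beta_fix=beta_shared)
        for site, est in estimates.items()
    }
    return stage2, beta_shared


def hurst_from_gamma(fit: AcfFit | float) -> HurstResult:
    """Hurst exponent from the fitted decay exponent: H = 1 - gamma/2."""
    gamma = fit.gamma if isinstance(fit, AcfFit) else float(fit)
    if gamma <= 0:
        return HurstResult(H=None, valid=False, regime="out-of-domain", gamma=gamma)
    if gamma >= 1:
        return HurstResult(H=0.5, valid=False, regime="random-walk-like", gamma=gamma)
    return HurstResult(H=1.0 - gamma / 2.0, valid=True, regime="persistent", gamma=gamma)
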