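"""End-to-end orchestration: manifest -> MODWT -> Leq -> peaks -> ACF fits.

``run_site`` processes one site's duty-cycled day in hourly batches and
writes the standard CSV bundle (leq_1s, leq_hourly, peaks, lag_stats,
acf, fits) plus a machine-readable run log.  ``compare_run`` builds the
cross-site lag-comparison table (R/D statistics) and recomputes the
two-stage shared-cutoff ACF fits across the supplied sites.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acf import AcfEstimate, acf, fit_acf_model, hurst_from_gamma, two_stage_fit
from .audio_io import CalibrationConfig, load_manifest, normalize_energy, read_wav
from .energy import energetic_mean, leq_series
from .modwt import get_filter, modwt
from .peaks import PeakMode, compare_sites, find_peaks, inter_peak_lags, lag_stats

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SiteResult", "run_site", "compare_run", "load_bundle"]

_CSV_FLOAT = "%.6f"


@dataclass
class RunConfig:
    manifest: str
    out_dir: str
    wavelet_filter: str = "d4"
    levels: int = 10
    leq_tau: float = 1.0
    peak_modes: tuple[tuple[int, int], ...] = ((1, 1), (2, 2))
    acf_max_lag: int = 100
    acf_fit_range: tuple[float, float] = (1.0, 100.0)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    clips_per_hour: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cal = CalibrationConfig(**raw.pop("calibration", {}))
        if "peak_modes" in raw:
            raw["peak_modes"] = tuple(tuple(m) for m in raw["peak_modes"])
        if "acf_fit_range" in raw:
            raw["acf_fit_range"] = tuple(raw["acf_fit_range"])
        return cls(calibration=cal, **raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SiteResult:
    site_id: str
    leq_1s: pd.DataFrame
    leq_hourly: pd.DataFrame
    peaks: pd.DataFrame
    lag_stats: pd.DataFrame
    acf_table: pd.DataFrame
    fits: pd.DataFrame
    acf_estimates: dict[str, AcfEstimate]
    failures: list[str]


def _band_order(levels: int) -> list[str]:
    return ["FULL"] + [f"W{j}" for j in range(1, levels + 1)] + ["smooth"]


def run_site(config: RunConfig, site_id: str) -> SiteResult:
    """Analyze one site's clips from the manifest; write the CSV bundle."""
    out_dir = Path(config.out_dir) / site_id
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = load_manifest(config.manifest)
    rows = manifest[manifest["site_id"] == site_id]
    if rows.empty:
        logger.warning("manifest has no clips for site %s", site_id)
    filt = get_filter(config.wavelet_filter)
    modes = [PeakMode(*m) for m in config.peak_modes]

    ordered = rows.sort_values("start_time")

    leq_rows, peak_rows = [], []
    failures: list[str] = []
    # per band/mode lag pool and per band gap-closed Leq concatenation
    lag_pool: dict[tuple[str, str], list[np.ndarray]] = {}
    peak_counts: dict[tuple[str, str], int] = {}
    series_pool: dict[str, list[np.ndarray]] = {}
    n_clips = 0
    # clips are read, decomposed and released one at a time: a 24 h
    # duty-cycled day (240 one-minute files at 48 kHz) stays desk-scale
    for rec in ordered.itertuples():
        try:
            clip = read_wav(rec.path, site_id=site_id, start_time=rec.start_time.to_pydatetime())
            clip = normalize_energy(clip, config.calibration)
        except (ValueError, OSError) as exc:
            failures.append(f"{rec.path}: {exc}")
            logger.error("skipping clip %s: %s", rec.path, exc)
            continue
        n_clips += 1
        dec = modwt(clip.samples, filt, config.levels)
        clip_id = clip.start_time.isoformat()
        for ls in leq_series(clip, dec, tau=config.leq_tau, p0=config.calibration.p0):
            series_pool.setdefault(ls.band, []).append(ls.values)
            for offset, value in zip(ls.window_starts, ls.values):
                leq_rows.append(
                    {
                        "site_id": site_id,
                        "band": ls.band,
                        "tau_s": ls.tau,
                        "window_start": clip.start_time + pd.Timedelta(seconds=float(offset)),
                        "leq_db": value,
                    }
                )
            for mode in modes:
                ps = find_peaks(ls, mode)
                key = (ls.band, str(mode))
                lag_pool.setdefault(key, []).append(inter_peak_lags(ps))
                peak_counts[key] = peak_counts.get(key, 0) + len(ps)
                for idx in ps.indices:
                    peak_rows.append(
                        {
                            "site_id": site_id,
                            "band": ls.band,
                            "mode": str(mode),
                            "clip": clip_id,
                            "index_s": int(idx),
                        }
                    )

    bands = _band_order(config.levels)
    leq_1s = pd.DataFrame(leq_rows)
    if not leq_1s.empty:
        leq_1s["band"] = pd.Categorical(leq_1s["band"], categories=bands, ordered=True)
        leq_1s = leq_1s.sort_values(["band", "window_start"], kind="stable").reset_index(drop=True)

    hourly_rows = []
    if not leq_1s.empty:
        hours = leq_1s["window_start"].dt.floor("h")
        for (band, hour), grp in leq_1s.groupby(["band", hours], observed=True):
            hourly_rows.append(
                {
                    "site_id": site_id,
                    "band": band,
                    "hour": hour,
                    "leq_db": energetic_mean(grp["leq_db"].to_numpy()),
                    "n_windows": len(grp),
                }
            )
    leq_hourly = pd.DataFrame(hourly_rows)

    stat_rows = []
    for (band, mode), pools in sorted(lag_pool.items(), key=lambda kv: (bands.index(kv[0][0]), kv[0][1])):
        lags = np.concatenate(pools) if pools else np.array([])
        st = lag_stats(lags, n_peaks=peak_counts[(band, mode)], site_id=site_id, band=band)
        stat_rows.append(
            {
                "site_id": site_id,
                "band": band,
                "mode": mode,
                "mean_lag_s": st.mean_lag,
                "median_lag_s": st.median_lag,
                "n_peaks": st.n_peaks,
                "n_lags": st.n_lags,
            }
        )
    lag_table = pd.DataFrame(stat_rows)

    acf_rows, fit_rows = [], []
    estimates: dict[str, AcfEstimate] = {}
    for band in bands:
        if band not in series_pool:
            continue
        pooled = np.concatenate(series_pool[band])
        try:
            est = acf(pooled, max_lag=config.acf_max_lag, site_id=site_id, band=band)
        except ValueError as exc:
            failures.append(f"acf[{band}]: {exc}")
            continue
        estimates[band] = est
        for lag, val in zip(est.lags, est.values):
            acf_rows.append({"site_id": site_id, "band": band, "lag_s": lag, "acf": val})
        try:
            fit = fit_acf_model(est, config.acf_fit_range)
        except (ValueError, RuntimeError) as exc:
            failures.append(f"fit[{band}]: {exc}")
            continue
        hurst = hurst_from_gamma(fit)
        fit_rows.append(
            {
                "site_id": site_id,
                "band": band,
                "y0": fit.y0,
                "gamma": fit.gamma,
                "beta": fit.beta,
                "beta_fixed": fit.beta_fixed,
                "fit_tmin": fit.fit_range[0],
                "fit_tmax": fit.fit_range[1],
                "residual_norm": fit.residual_norm,
                "H": hurst.H if hurst.H is not None else np.nan,
                "H_valid": hurst.valid,
                "regime": hurst.regime,
            }
        )
    acf_table = pd.DataFrame(acf_rows)
    fits = pd.DataFrame(fit_rows)

    result = SiteResult(
        site_id=site_id,
        leq_1s=leq_1s,
        leq_hourly=leq_hourly,
        peaks=pd.DataFrame(peak_rows),
        lag_stats=lag_table,
        acf_table=acf_table,
        fits=fits,
        acf_estimates=estimates,
        failures=failures,
    )
    _write_bundle(result, out_dir, config)
    return result


def _write_bundle(result: SiteResult, out_dir: Path, config: RunConfig) -> None:
    result.leq_1s.to_csv(out_dir / "leq_1s.csv", index=False, float_format=_CSV_FLOAT)
    result.leq_hourly.to_csv(out_dir / "leq_hourly.csv", index=False, float_format=_CSV_FLOAT)
    result.peaks.to_csv(out_dir / "peaks.csv", index=False)
    result.lag_stats.to_csv(out_dir / "lag_stats.csv", index=False, float_format=_CSV_FLOAT)
    result.acf_table.to_csv(out_dir / "acf.csv", index=False, float_format="%.8f")
    result.fits.to_csv(out_dir / "fits.csv", index=False, float_format=_CSV_FLOAT)
    log = {
        "package": "wavescape",
        "version": __version__,
        "numpy": np.__version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "site_id": result.site_id,
        "n_windows": int(len(result.leq_1s)),
        "failures": result.failures,
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)


def load_bundle(bundle_dir: str | Path) -> SiteResult:
    """Reload a written CSV bundle (enough of it to feed ``compare_run``)."""
    bundle_dir = Path(bundle_dir)
    lag_table = pd.read_csv(bundle_dir / "lag_stats.csv")
    acf_table = pd.read_csv(bundle_dir / "acf.csv")
    fits = pd.read_csv(bundle_dir / "fits.csv")
    site_id = str(lag_table["site_id"].iloc[0]) if not lag_table.empty else bundle_dir.name
    estimates = {}
    for band, grp in acf_table.groupby("band"):
        grp = grp.sort_values("lag_s")
        estimates[band] = AcfEstimate(
            lags=grp["lag_s"].to_numpy(float),
            values=grp["acf"].to_numpy(float),
            n_obs=0,
            site_id=site_id,
            band=str(band),
        )
    empty = pd.DataFrame()
    return SiteResult(site_id, empty, empty, empty, lag_table, acf_table, fits, estimates, [])


def compare_run(
    results: dict[str, SiteResult],
    mode: str = "(2-2)",
    fit_range: tuple[float, float] = (1.0, 100.0),
) -> dict[str, pd.DataFrame]:
    """Cross-site comparison: lag R/D table plus shared-beta gamma table.

    The lag table follows the survey-summary schema (Site, Level, MeanLag,
    R, MedianLag, D, NPeaks): for each level the rows carry the pairwise
    statistics in the fixed order (1,2), (1,3), (2,3), so with three
    sites row i of a level holds R and D of the i-th pair.
    """
    if len(results) < 2:
        raise ValueError("need at least two site bundles to compare")
    sites = sorted(results)
    band_sets = [set(r.lag_stats["band"]) for r in results.values()]
    bands = set.intersection(*band_sets)
    if any(b - bands for b in band_sets):
        logger.warning("bundles disagree on bands; comparing the intersection")
    first = results[sites[0]].lag_stats
    ordered_bands = [b for b in first["band"] if b in bands]
    ordered_bands = list(dict.fromkeys(ordered_bands))

    lag_rows = []
    for band in ordered_bands:
        per_site = {}
        for site in sites:
            tbl = results[site].lag_stats
            row = tbl[(tbl["band"] == band) & (tbl["mode"] == mode)]
            if row.empty:
                continue
            row = row.iloc[0]
            per_site[site] = lag_stats(
                np.array([]), n_peaks=int(row["n_peaks"]), site_id=site, band=band
            )
            per_site[site].mean_lag = float(row["mean_lag_s"])
            per_site[site].median_lag = float(row["median_lag_s"])
        if len(per_site) < 2:
            continue
        comps = compare_sites(per_site, band=band)
        for i, site in enumerate(sites):
            tbl = results[site].lag_stats
            row = tbl[(tbl["band"] == band) & (tbl["mode"] == mode)].iloc[0]
            comp = comps[i] if i < len(comps) else None
            lag_rows.append(
                {
                    "Site": site,
                    "Level": band,
                    "MeanLag": float(row["mean_lag_s"]),
                    "R": comp.R if comp else np.nan,
                    "MedianLag": float(row["median_lag_s"]),
                    "D": comp.D if comp else np.nan,
                    "NPeaks": int(row["n_peaks"]),
                }
            )
    lag_comparison = pd.DataFrame(lag_rows)

    gamma_rows = []
    shared_betas = {}
    for band in ordered_bands:
        ests = {s: results[s].acf_estimates[band] for s in sites if band in results[s].acf_estimates}
        if len(ests) < 2:
            continue
        stage2, beta_shared = two_stage_fit(ests, fit_range)
        shared_betas[band] = beta_shared
        for site, fit in stage2.items():
            hurst = hurst_from_gamma(fit)
            gamma_rows.append(
                {
                    "Site": site,
                    "Level": band,
                    "gamma": fit.gamma,
                    "beta_shared": beta_shared,
                    "y0": fit.y0,
                    "H": hurst.H if hurst.H is not None else np.nan,
                    "regime": hurst.regime,
                }
            )
    gamma_table = pd.DataFrame(gamma_rows)
    return {"lag_comparison": lag_comparison, "gamma_table": gamma_table}
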