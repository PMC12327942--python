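"""Spectral analysis: multitaper PSD on a log grid, canonical band power,
task-vs-rest global effect, brain-behaviour correlation, ROI statistics.

The PSD is a multitaper (DPSS, time-bandwidth 4) estimate evaluated on a
fixed grid of 125 logarithmically spaced frequencies from 0.5 to 125 Hz.
Band power averages the grid points falling in each canonical band, with
half-open [lo, hi) edges (the shared 13 Hz and 50 Hz edges need a convention;
the 50-70 Hz gap between low gamma and HFa is preserved).

The global effect is the percent power change of task vs rest,
100 * (mean_task - mean_rest) / mean_rest, with significance from a
label-permutation over epochs; the behavioural coupling is the across-trial
Spearman correlation between band power and the verbal coordination index,
with significance from trial-label permutation. ROI-level statistics are
one-sample t-tests of channel values against zero with Benjamini-Hochberg
FDR across ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss
from scipy.stats import rankdata, ttest_1samp
from statsmodels.stats.multitest import multipletests

from .preprocess import EpochSet

#: the six canonical frequency bands (Hz), half-open [lo, hi)
BAND_SCHEME: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "low_gamma": (30.0, 50.0),
    "hfa": (70.0, 125.0),
}

BAND_NAMES = tuple(BAND_SCHEME)

PSD_GRID = np.logspace(np.log10(0.5), np.log10(125.0), 125)


@dataclass
class PsdResult:
    """Per-epoch PSD on the fixed log grid: (epochs, channels, 125 freqs)."""

    values: np.ndarray
    freqs: np.ndarray
    channel_table: pd.DataFrame


@dataclass
class BandPowerMatrix:
    """Band power per epoch x channel x band; strictly positive."""

    values: np.ndarray
    bands: tuple[str, ...]
    kind: str  # task | rest
    channel_table: pd.DataFrame

    def mean_over_epochs(self) -> np.ndarray:
        return self.values.mean(axis=0)


def compute_psd(
    epochs: EpochSet,
    grid: np.ndarray = PSD_GRID,
    time_bandwidth: float = 4.0,
) -> PsdResult:
    """Multitaper PSD of each epoch, interpolated onto the 125-point log grid.

    Uses 2*NW - 1 DPSS tapers (NW = time_bandwidth). Only the analysis
    portion of each epoch (t >= 0.5 s for task epochs) enters the estimate.
    Requires epochs of at least 2 s and a Nyquist above the top of the grid.
    """
    mask = epochs.analysis_mask
    data = epochs.data[:, :, mask]
    n_t = data.shape[2]
    fs = epochs.sample_rate
    if n_t / fs < 2.0:
        raise ValueError("epochs must be at least 2 s long for the PSD grid")
    if grid[-1] > fs / 2.0:
        raise ValueError(f"PSD grid extends above Nyquist ({fs / 2:g} Hz)")
    n_tapers = int(2 * time_bandwidth - 1)
    tapers = dpss(n_t, time_bandwidth, Kmax=n_tapers)  # (K, n_t)
    freqs = rfftfreq(n_t, d=1.0 / fs)
    n_ep, n_ch = data.shape[:2]
    out = np.empty((n_ep, n_ch, len(grid)))
    for e in range(n_ep):
        # (channels, tapers, freqs)
        spec = rfft(data[e][:, None, :] * tapers[None, :, :], axis=-1)
        psd = (np.abs(spec) ** 2).mean(axis=1) / (fs * np.sum(tapers[0] ** 2))
        for c in range(n_ch):
            out[e, c] = np.interp(grid, freqs, psd[c])
    return PsdResult(out, np.asarray(grid), epochs.channel_table)


def band_power(psd: PsdResult, bands: dict[str, tuple[float, float]] = BAND_SCHEME,
               kind: str = "task") -> BandPowerMatrix:
    """Average PSD grid points within each band's half-open [lo, hi) range."""
    names = tuple(bands)
    vals = np.empty(psd.values.shape[:2] + (len(names),))
    for bi, name in enumerate(names):
        lo, hi = bands[name]
        sel = (psd.freqs >= lo) & (psd.freqs < hi)
        if not np.any(sel):
            raise ValueError(f"band {name!r} covers no grid point")
        vals[:, :, bi] = psd.values[:, :, sel].mean(axis=-1)
    return BandPowerMatrix(vals, names, kind, psd.channel_table)


@dataclass
class GlobalEffectResult:
    """Percent power change vs rest per channel x band, with permutation p."""

    percent_change: np.ndarray  # (channels, bands)
    p_values: np.ndarray
    bands: tuple[str, ...]
    channel_table: pd.DataFrame
    n_perm: int

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.p_values <= alpha


def _percent_change(task_mean: np.ndarray, rest_mean: np.ndarray) -> np.ndarray:
    if np.any(rest_mean <= 0):
        raise ValueError("rest power must be strictly positive")
    return 100.0 * (task_mean - rest_mean) / rest_mean


def global_effect(
    task: BandPowerMatrix | np.ndarray,
    rest: BandPowerMatrix | np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> GlobalEffectResult:
    """Task-vs-rest percent power change with an epoch-label permutation test.

    The statistic is 100 * (mean_task - mean_rest) / mean_rest per channel and
    band. Under the null, task and rest epoch labels are exchangeable: labels
    are permuted over the pooled epochs (N = n_perm, seeded) and a two-sided
    p-value with the +1 correction is reported.
    """
    tv = task.values if isinstance(task, BandPowerMatrix) else np.asarray(task, dtype=float)
    rv = rest.values if isinstance(rest, BandPowerMatrix) else np.asarray(rest, dtype=float)
    if tv.ndim == 2:
        tv = tv[:, :, None]
    if rv.ndim == 2:
        rv = rv[:, :, None]
    if tv.shape[1:] != rv.shape[1:]:
        raise ValueError("task and rest channel/band shapes differ")
    n_task = tv.shape[0]
    pooled = np.concatenate([tv, rv], axis=0)  # (n_task + n_rest, ch, band)
    obs = _percent_change(tv.mean(axis=0), rv.mean(axis=0))
    rng = np.random.default_rng(seed)
    n_tot = pooled.shape[0]
    count = np.zeros(obs.shape)
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        pt = pooled[perm[:n_task]].mean(axis=0)
        pr = pooled[perm[n_task:]].mean(axis=0)
        null = _percent_change(pt, np.maximum(pr, 1e-300))
        count += np.abs(null) >= np.abs(obs)
    p = (1.0 + count) / (1.0 + n_perm)
    bands = task.bands if isinstance(task, BandPowerMatrix) else tuple(f"b{i}" for i in range(tv.shape[2]))
    table = task.channel_table if isinstance(task, BandPowerMatrix) else pd.DataFrame()
    return GlobalEffectResult(obs, p, bands, table, n_perm)


@dataclass
class CorrelationResult:
    """Across-trial Spearman rho per channel x band, with permutation p."""

    rho: np.ndarray  # (channels, bands)
    p_values: np.ndarray
    bands: tuple[str, ...]
    n_trials: int
    channel_table: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.p_values <= alpha


def _rank_standardize(x: np.ndarray, axis: int = 0) -> np.ndarray:
    r = np.apply_along_axis(rankdata, axis, x)
    r = r - r.mean(axis=axis, keepdims=True)
    denom = np.sqrt((r**2).sum(axis=axis, keepdims=True))
    denom = np.where(denom == 0, 1.0, denom)
    return r / denom


def brain_behaviour_correlation(
    task: BandPowerMatrix | np.ndarray,
    vci,
    n_perm: int = 1000,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman correlation across trials between band power and the VCI.

    rho is computed per channel and band as the Pearson correlation of ranks
    (exactly Spearman's rho with average ranks for ties); significance by
    permuting the trial labels of the VCI (N = n_perm, seeded, two-sided,
    +1-corrected). A constant VCI leaves rho undefined: flagged as NaN.
    """
    tv = task.values if isinstance(task, BandPowerMatrix) else np.asarray(task, dtype=float)
    if tv.ndim == 2:
        tv = tv[:, :, None]
    v = np.asarray(vci, dtype=float)
    n_trials = tv.shape[0]
    if len(v) != n_trials:
        raise ValueError("VCI length does not match trial count")
    if n_trials < 10:
        raise ValueError("need at least 10 trials for the across-trial correlation")
    bands = task.bands if isinstance(task, BandPowerMatrix) else tuple(f"b{i}" for i in range(tv.shape[2]))
    table = task.channel_table if isinstance(task, BandPowerMatrix) else pd.DataFrame()
    if np.std(v) == 0:
        warnings.warn("constant VCI: correlation undefined")
        nan = np.full(tv.shape[1:], np.nan)
        return CorrelationResult(nan, nan.copy(), bands, n_trials, table)

    pw = _rank_standardize(tv, axis=0).reshape(n_trials, -1)  # (trials, ch*band)
    rv = _rank_standardize(v[:, None], axis=0)[:, 0]
    obs = rv @ pw  # (ch*band,)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n_trials) for _ in range(n_perm)])
    null = rv[perms] @ pw  # (n_perm, ch*band)
    count = (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)
    p = (1.0 + count) / (1.0 + n_perm)
    shape = tv.shape[1:]
    return CorrelationResult(obs.reshape(shape), p.reshape(shape), bands, n_trials, table)


def roi_statistics(
    values: np.ndarray,
    roi_labels,
    min_channels: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-ROI one-sample t-tests of channel values against zero, FDR-corrected.

    ``values`` is one number per channel (e.g. HFa rho, or percent change);
    ROIs with fewer than ``min_channels`` channels are skipped with a warning.
    Benjamini-Hochberg correction runs across the tested ROIs.
    """
    vals = np.asarray(values, dtype=float)
    rois = np.asarray(roi_labels)
    rows = []
    for roi in pd.unique(rois):
        v = vals[rois == roi]
        v = v[np.isfinite(v)]
        if len(v) < min_channels:
            warnings.warn(f"ROI {roi!r} has fewer than {min_channels} channels; skipped")
            continue
        t, p = ttest_1samp(v, 0.0)
        rows.append(
            {"roi": roi, "n_channels": len(v), "mean": v.mean(), "t": float(t),
             "p": float(p), "direction": "positive" if v.mean() > 0 else "negative"}
        )
    df = pd.DataFrame(rows)
    if len(df):
        rej, p_adj, _, _ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
        df["p_fdr"] = p_adj
        df["significant"] = rej
    return df


def spectral_summary(
    global_res: GlobalEffectResult, corr_res: CorrelationResult
) -> pd.DataFrame:
    """Flat per-channel-per-band CSV-ready table of both analyses."""
    rows = []
    table = global_res.channel_table.reset_index(drop=True)
    for ci in range(global_res.percent_change.shape[0]):
        for bi, band in enumerate(global_res.bands):
            rows.append(
                {
                    "channel": table.loc[ci, "name"] if "name" in table else str(ci),
                    "roi": table.loc[ci, "roi"] if "roi" in table else "",
                    "band": band,
                    "percent_change": global_res.percent_change[ci, bi],
                    "p_global": global_res.p_values[ci, bi],
                    "rho": corr_res.rho[ci, bi],
                    "p_rho": corr_res.p_values[ci, bi],
                }
            )
    return pd.DataFrame(rows)
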