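"""Early-warning signals for collapse: landscape-based and trajectory-based.

The landscape signal is the relative barrier height (RBH) between the low
and intermediate basins computed along an increasing-kappa grid.  As the
system nears the tipping point the RBH sequence develops nonlinear
structure; the Brock-Dechert-Scheinkman (BDS) test applied to the residuals
of a linear fit over each growing prefix flags the first kappa at which the
i.i.d. null is rejected — the warning point.

Trajectory comparators are the classical critical-slowing-down metrics —
lag-1 autocorrelation AR(1), variance, coefficient of variation and Fano
factor — computed per species in rolling windows on Gaussian-detrended
Langevin trajectories, with a warning at the smallest kappa from which the
metric keeps rising through the tipping point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from statsmodels.tsa.stattools import bds as _bds_stat

from .dynamics import find_attractors
from .landscape import (
    barrier_report,
    mixture_from_attractors,
    reduce_bipartite,
    reduced_potential,
)


class InsufficientSequenceError(ValueError):
    """Raised when too few valid RBH points exist to test."""


def rbh_sequence(
    net,
    params,
    kappa_grid,
    projection=None,
    pair=("low", "intermediate"),
    d: float = 0.01,
    n_starts: int = 40,
    seed: int = 0,
    grid_size: int = 120,
    min_points: int = 10,
    **attractor_kw,
) -> pd.DataFrame:
    """RBH between a basin pair along a kappa grid.

    For each kappa the attractors, the Gaussian-mixture landscape and the
    reduced 2-D potential are recomputed with a shared projection (computed
    at the first kappa where both basins coexist, unless one is supplied),
    and RBH(pair) = BH(saddle, second member) - BH(saddle, first member) is
    read off the barrier report.  Kappas where either basin is missing give
    NaN gaps.  Returns a frame with columns ``kappa`` and ``rbh``.
    """
    i_lab, j_lab = pair
    rows = []
    proj = projection
    for k in kappa_grid:
        p = params.replace(kappa=float(k))
        aset = find_attractors(net, p, n_starts=n_starts, seed=seed,
                               **attractor_kw)
        labs = [a.label for a in aset]
        if i_lab not in labs or j_lab not in labs:
            rows.append({"kappa": float(k), "rbh": np.nan})
            continue
        mix = mixture_from_attractors(aset, net, p, d=d)
        if proj is None:
            proj = reduce_bipartite(mix, net)
        red = reduced_potential(mix, proj, grid_size=grid_size)
        rep = barrier_report(red, pairs=[(i_lab, j_lab)])
        i = red.labels.index(i_lab)
        j = red.labels.index(j_lab)
        if rep.merged[frozenset((i, j))]:
            # basins indistinguishable on the grid (e.g. at a fold): gap
            rows.append({"kappa": float(k), "rbh": np.nan})
        else:
            rows.append({"kappa": float(k), "rbh": rep.rbh(i, j)})
    df = pd.DataFrame(rows)
    if df["rbh"].notna().sum() < min_points:
        raise InsufficientSequenceError(
            f"only {int(df['rbh'].notna().sum())} valid RBH points "
            f"(< {min_points})"
        )
    return df


_NULL_CACHE: dict = {}


def _bds_null_table(n: int, max_dim: int, distance: float,
                    n_sim: int = 2000, seed: int = 987654321) -> np.ndarray:
    """Simulated null distribution of |BDS| statistics for i.i.d. series.

    The BDS statistic with proximity radius proportional to the sample SD is
    scale-free, so a standard-normal null is used.  The table is seeded and
    cached per series length, making p-values deterministic.
    """
    key = (n, max_dim, distance, n_sim)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed + n)
        stats = np.empty((n_sim, max_dim - 1))
        for i in range(n_sim):
            s, _ = _bds_stat(rng.standard_normal(n), max_dim=max_dim,
                             distance=distance)
            stats[i] = np.abs(np.atleast_1d(s))
        stats[~np.isfinite(stats)] = np.inf
        _NULL_CACHE[key] = np.sort(stats, axis=0)
    return _NULL_CACHE[key]


def bds_pvalues(x, max_dim: int = 3, distance: float = 0.5,
                method: str = "mc", n_sim: int = 2000) -> np.ndarray:
    """Two-sided BDS p-values for embedding dimensions 2..max_dim.

    The proximity radius is ``distance`` times the sample SD.  By default
    p-values come from a seeded Monte-Carlo null table of the statistic
    (``method='mc'``), which keeps the test exactly sized at the short
    series lengths this package tests (the asymptotic normal approximation,
    available as ``method='asymptotic'``, is badly oversized below a few
    thousand points, particularly at small proximity radii).
    """
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0:
        return np.full(max_dim - 1, np.nan)
    stat, p_asym = _bds_stat(x, max_dim=max_dim, distance=distance)
    if method == "asymptotic":
        return np.atleast_1d(p_asym)
    stat = np.abs(np.atleast_1d(np.asarray(stat, dtype=float)))
    table = _bds_null_table(len(x), max_dim, distance, n_sim=n_sim)
    p = np.empty(len(stat))
    for k, s in enumerate(stat):
        if not np.isfinite(s):
            p[k] = np.nan
            continue
        exceed = np.sum(table[:, k] >= s)
        p[k] = (1.0 + exceed) / (table.shape[0] + 1.0)
    return p


def detrended_residuals(y) -> np.ndarray:
    """Residuals of an ordinary least-squares linear trend fit."""
    y = np.asarray(y, dtype=float)
    t = np.arange(len(y), dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class BdsWarningResult:
    kappas: np.ndarray
    pvalues: np.ndarray          # min over embedding dimensions, per prefix
    warning_kappas: dict         # significance level -> kappa (or nan)
    min_len: int


def bds_warning(
    sequence,
    kappas=None,
    levels=(0.05, 0.01, 0.001),
    min_len: int = 15,
    max_dim: int = 3,
    distance: float = 0.5,
) -> BdsWarningResult:
    """First kappa at which the RBH prefix rejects the BDS i.i.d. null.

    Each prefix ending at kappa_k (length >= ``min_len``) is linearly
    detrended; the BDS statistic (m in {2..max_dim}, eps = ``distance`` x
    residual SD, asymptotic normal p-value, minimum over m) is evaluated on
    the residuals.  Zero-variance residuals make the test undefined and the
    point is skipped.  Warnings are monotone in the significance level.
    """
    y = np.asarray(sequence, dtype=float)
    valid = np.isfinite(y)
    y = y[valid]
    if kappas is None:
        kappas = np.arange(len(y), dtype=float)
    else:
        kappas = np.asarray(kappas, dtype=float)[valid]
    ps = np.full(len(y), np.nan)
    for k in range(min_len, len(y) + 1):
        resid = detrended_residuals(y[:k])
        if np.std(resid) < 1e-14:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = bds_pvalues(resid, max_dim=max_dim, distance=distance)
        if np.all(np.isnan(p)):
            continue
        ps[k - 1] = np.nanmin(p)
    warn = {}
    for lev in levels:
        hits = np.where(ps < lev)[0]
        warn[lev] = float(kappas[hits[0]]) if len(hits) else np.nan
    return BdsWarningResult(kappas=kappas, pvalues=ps, warning_kappas=warn,
                            min_len=min_len)


# -- trajectory-based metrics ---------------------------------------------

def trajectory_metrics(
    traj,
    window: int,
    bandwidth: float = None,
) -> dict:
    """Rolling critical-slowing-down metrics per species.

    ``traj`` has shape (T, N).  Each series is detrended by subtracting a
    Gaussian-kernel smooth (``bandwidth`` in samples, default 10% of the
    series length); AR(1) and variance are computed on the detrended series
    in rolling windows, while CV (= SD/mean) and Fano (= variance/mean) use
    the raw windows.  Values are aligned to the window's right edge;
    windows with (near-)zero mean leave CV/Fano masked as NaN.
    """
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    T, N = traj.shape
    if window >= T:
        raise ValueError("window must be shorter than the trajectory")
    if bandwidth is None:
        bandwidth = 0.1 * T
    smooth = gaussian_filter1d(traj, sigma=bandwidth, axis=0, mode="nearest")
    resid = traj - smooth
    out = {m: np.full((T, N), np.nan) for m in ("ar1", "var", "cv", "fano")}
    for s in range(N):
        r = pd.Series(resid[:, s])
        x = pd.Series(traj[:, s])
        var = r.rolling(window).var()
        ar1 = _rolling_ar1(resid[:, s], window)
        mean = x.rolling(window).mean()
        sd = x.rolling(window).std()
        rawvar = x.rolling(window).var()
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(np.abs(mean) > 1e-12, sd / mean, np.nan)
            fano = np.where(np.abs(mean) > 1e-12, rawvar / mean, np.nan)
        out["var"][:, s] = var.values
        out["ar1"][:, s] = ar1
        out["cv"][:, s] = cv
        out["fano"][:, s] = fano
    return out


def _rolling_ar1(x, window):
    """Vectorized rolling lag-1 autocorrelation (right-edge aligned)."""
    T = len(x)
    out = np.full(T, np.nan)
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(x, window)
    a, b = win[:, :-1], win[:, 1:]
    am = a - a.mean(axis=1, keepdims=True)
    bm = b - b.mean(axis=1, keepdims=True)
    num = np.sum(am * bm, axis=1)
    den = np.sqrt(np.sum(am**2, axis=1) * np.sum(bm**2, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(den > 0, num / den, np.nan)
    out[window - 1:] = vals
    return out


def metric_warning(
    metric_seq,
    kappas,
    tipping_kappa: float,
    smooth_sigma: float = 5.0,
) -> float:
    """Smallest kappa from which the metric is non-decreasing to the tipping.

    The metric sequence (indexed by the ramp's kappa) is lightly smoothed;
    the warning is the smallest kappa such that the smoothed metric never
    decreases from there up to ``tipping_kappa``.  Returns NaN when no such
    kappa exists (e.g. a strictly decreasing metric).
    """
    m = np.asarray(metric_seq, dtype=float)
    k = np.asarray(kappas, dtype=float)
    mask = np.isfinite(m) & (k <= tipping_kappa)
    m, k = m[mask], k[mask]
    if len(m) < 3:
        return np.nan
    ms = gaussian_filter1d(m, sigma=smooth_sigma, mode="nearest")
    diffs = np.diff(ms) >= -1e-12
    # last index before which some decrease still occurs
    warn = np.nan
    for i in range(len(diffs), -1, -1):
        if i == 0 or not diffs[i - 1]:
            if i < len(k):
                warn = k[i]
            break
    if np.isfinite(warn) and warn >= k[-1]:
        return np.nan
    return float(warn)


def false_positive_check(
    net,
    params,
    base_kappa: float,
    sigma: float = 0.01,
    rho: float = 0.5,
    n_points: int = 30,
    n_seeds: int = 10,
    seed: int = 0,
    level: float = 0.05,
    grid_step: float = 0.0025,
    **rbh_kw,
) -> int:
    """Warnings raised when kappa only fluctuates (no transition ahead).

    Draws ``n_seeds`` AR(1) kappa series of length ``n_points`` around
    ``base_kappa`` (inside a multistable window), evaluates the RBH at each
    visited kappa (rounded to ``grid_step``; repeated values are cached) and
    applies the BDS warning rule to each time-ordered sequence.  Returns the
    number of series with any significant point at ``level`` — ideally zero,
    since no tipping point is approached.
    """
    rng = np.random.default_rng(seed)
    cache: dict = {}

    def rbh_at(k):
        key = round(round(k / grid_step) * grid_step, 10)
        if key not in cache:
            df = rbh_sequence(net, params, [key], min_points=1, **rbh_kw)
            cache[key] = float(df["rbh"].iloc[0])
        return cache[key]

    n_warn = 0
    for _ in range(n_seeds):
        eps = np.empty(n_points)
        eps[0] = rng.standard_normal() * sigma
        for i in range(1, n_points):
            eps[i] = rho * eps[i - 1] + np.sqrt(1 - rho**2) * \
                rng.standard_normal() * sigma
        seq = np.array([rbh_at(base_kappa + e) for e in eps])
        res = bds_warning(seq, levels=(level,))
        if np.isfinite(res.warning_kappas[level]):
            n_warn += 1
    return n_warn


@dataclass
class EwsReport:
    """Landscape-based warning vs trajectory-metric warnings."""

    kappa_grid: np.ndarray
    rbh: np.ndarray
    bds: BdsWarningResult
    metric_warnings: dict = field(default_factory=dict)  # metric -> per-species kappas
    tipping_kappa: float = np.nan

    def rbh_warning(self, level: float = 0.05) -> float:
        return self.bds.warning_kappas.get(level, np.nan)

    def metric_median(self, metric: str) -> float:
        v = np.asarray(self.metric_warnings.get(metric, []), dtype=float)
        v = v[np.isfinite(v)]
        return float(np.median(v)) if len(v) else np.nan

    def comparison(self, level: float = 0.05) -> pd.DataFrame:
        rows = [{"signal": "RBH", "warning_kappa": self.rbh_warning(level)}]
        for m in sorted(self.metric_warnings):
            rows.append({"signal": m, "warning_kappa": self.metric_median(m)})
        df = pd.DataFrame(rows)
        df["earlier_than_tipping"] = df["warning_kappa"] < self.tipping_kappa
        return df.sort_values("warning_kappa").reset_index(drop=True)


def compare_ews(
    rbh_df: pd.DataFrame,
    traj,
    traj_kappas,
    tipping_kappa: float,
    window: int = 200,
    bandwidth: float = None,
    levels=(0.05, 0.01, 0.001),
    min_len: int = 15,
) -> EwsReport:
    """Assemble the warning comparison between RBH and trajectory metrics.

    ``rbh_df`` comes from :func:`rbh_sequence`; ``traj`` (T, N) from a
    ramped Langevin run with per-sample ``traj_kappas``.  The report holds
    the RBH/BDS warning kappas and, for each classical metric, the
    per-species warning kappas (median exposed for the headline
    comparison: smaller kappa = earlier warning).
    """
    bds_res = bds_warning(rbh_df["rbh"].values, kappas=rbh_df["kappa"].values,
                          levels=levels, min_len=min_len)
    metrics = trajectory_metrics(traj, window=window, bandwidth=bandwidth)
    mw = {}
    for name, M in metrics.items():
        per_species = [
            metric_warning(M[:, s], traj_kappas, tipping_kappa)
            for s in range(M.shape[1])
        ]
        mw[name] = np.array(per_species)
    return EwsReport(
        kappa_grid=rbh_df["kappa"].values,
        rbh=rbh_df["rbh"].values,
        bds=bds_res,
        metric_warnings=mw,
        tipping_kappa=tipping_kappa,
    )
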