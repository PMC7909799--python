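"""Series screening, standardisation and site-chronology statistics.

Raw ring widths carry an age/size trend: young trees lay wide rings, old
trees narrow ones.  Before any cross-tree comparison the widths are turned
into dimensionless indices by dividing by a slowly varying growth curve.
Three standardisations are provided:

* Baillie–Pilcher: per cent of the centred 5-year running mean — the
  classical high-pass index used for crossdating-style screening.
* Smoothing-spline: division by a stiffness-controlled smoothing curve
  whose frequency response is 50% at a chosen wavelength (default 0.67 ×
  series length).  Implemented as a second-difference penalised
  (Whittaker–Henderson) smoother, the discrete equivalent of the cubic
  smoothing splines conventional in dendrochronology.
* Double detrend: a modified negative exponential first, the spline second.

Chronology confidence uses the standard Wigley statistics: with mean
inter-series correlation rbar and n trees, EPS = n·rbar/(n·rbar + 1 − rbar)
and SNR = n·rbar/(1 − rbar); the reliable span is the longest run of
20-year windows (10-year overlap) with EPS ≥ 0.85.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import curve_fit
from scipy.sparse.linalg import spsolve

from .series import IndexBasis, IndexSeries, SiteCollection

logger = logging.getLogger(__name__)

MIN_OVERLAP = 10  # years required for a pairwise correlation


@dataclass
class ChronologyStats:
    """Inter-series agreement statistics over a window of years."""

    rbar: float
    eps: float
    snr: float
    n_trees: int
    window: tuple[int, int]


# ---------------------------------------------------------------------------
# standardisation

def _interpolate_gaps(w: np.ndarray) -> np.ndarray:
    """Linear interpolation across NaNs (edges held at nearest value)."""
    w = np.asarray(w, dtype=float).copy()
    bad = ~np.isfinite(w)
    if bad.any():
        idx = np.arange(len(w))
        if bad.all():
            raise ValueError("series is entirely undefined")
        w[bad] = np.interp(idx[bad], idx[~bad], w[~bad])
    return w


def baillie_pilcher_index(series, first_year: int | None = None) -> IndexSeries:
    """Per cent of the centred 5-year running mean (edges truncated).

    Index values are near 100 for smooth series; where the running mean is
    zero the index is undefined (NaN).
    """
    w, fy = _coerce(series, first_year)
    if len(w) < 5:
        raise ValueError("Baillie-Pilcher index requires length >= 5")
    rm = pd.Series(w).rolling(5, center=True, min_periods=1).mean().to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = 100.0 * w / rm
    idx[rm == 0] = np.nan
    return IndexSeries(fy, idx, IndexBasis.BAILLIE_PILCHER)


def _whittaker_smooth(w: np.ndarray, lam: float) -> np.ndarray:
    n = len(w)
    if n < 3:
        return w.copy()
    d = sp.eye(n, format="csc")
    d2 = d[2:] - 2 * d[1:-1] + d[:-2]
    a = sp.eye(n, format="csc") + lam * (d2.T @ d2)
    return spsolve(a.tocsc(), w)


def stiffness_to_lambda(wavelength_years: float) -> float:
    """Penalty weight giving a 50% frequency response at the wavelength.

    The second-difference penalty has squared frequency response
    16·sin⁴(ω/2); amplitude 0.5 at ω = 2π/λ gives λ_pen = 1/(16 sin⁴(π/λ)).
    """
    f = np.pi / wavelength_years
    return 1.0 / (16.0 * np.sin(f) ** 4)


def spline_detrend(
    series, stiffness: float | None = None, first_year: int | None = None
) -> IndexSeries:
    """Divide by a smoothing curve with 50% cutoff at ``stiffness`` years.

    ``stiffness`` ≤ 1 is interpreted as a fraction of the series length;
    default 0.67 × length.  The index is undefined (NaN) where the fitted
    curve is ≤ 0.
    """
    w, fy = _coerce(series, first_year)
    if len(w) < 10:
        raise ValueError("spline detrending requires length >= 10")
    if stiffness is None:
        stiffness = 0.67
    wl = stiffness * len(w) if stiffness <= 1 else float(stiffness)
    wl = max(wl, 2.0)
    smooth = _whittaker_smooth(_interpolate_gaps(w), stiffness_to_lambda(wl))
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = w / smooth
    idx[smooth <= 0] = np.nan
    return IndexSeries(fy, idx, IndexBasis.SPLINE)


def _neg_exp(t, a, b, k):
    return a * np.exp(-b * t) + k


def double_detrend(
    series, stiffness: float | None = None, first_year: int | None = None
) -> IndexSeries:
    """Modified negative exponential followed by spline detrending.

    The first pass divides by a·exp(−b·t) + k (a, b > 0, k ≥ 0); when the
    fit fails or is non-decreasing it falls back to a non-positive-slope
    linear fit, then to the series mean.  The second pass applies
    :func:`spline_detrend` to the first-pass index.
    """
    w, fy = _coerce(series, first_year)
    if len(w) < 20:
        raise ValueError("double detrending requires length >= 20")
    wi = _interpolate_gaps(np.where(np.isfinite(w), w, np.nan))
    t = np.arange(len(wi), dtype=float)
    curve = None
    try:
        span = max(wi[0] - wi[-1], 1e-3)
        p0 = (span, 2.0 / len(wi), max(wi[-1], 1e-3))
        popt, _ = curve_fit(
            _neg_exp,
            t,
            wi,
            p0=p0,
            bounds=([1e-12, 1e-12, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=5000,
        )
        fitted = _neg_exp(t, *popt)
        if np.all(fitted > 0):
            curve = fitted
    except (RuntimeError, ValueError):
        curve = None
    if curve is None:
        slope, intercept = np.polyfit(t, wi, 1)
        if slope <= 0:
            fitted = slope * t + intercept
            if np.all(fitted > 0):
                curve = fitted
    if curve is None:
        curve = np.full_like(wi, wi.mean())
    first_pass = w / curve
    out = spline_detrend(first_pass, stiffness=stiffness, first_year=fy)
    return IndexSeries(fy, out.values, IndexBasis.DOUBLE_DETREND)


def _coerce(series, first_year):
    """Accept an IndexSeries, a (values, first_year) pair, or a plain vector."""
    if isinstance(series, IndexSeries):
        return np.asarray(series.values, dtype=float).copy(), series.first_year
    arr = np.asarray(series, dtype=float).copy()
    return arr, 1 if first_year is None else int(first_year)


# ---------------------------------------------------------------------------
# cross-series statistics

def _aligned_matrix(indices: list[IndexSeries]) -> tuple[np.ndarray, int]:
    first = min(s.first_year for s in indices)
    last = max(s.last_year for s in indices)
    mat = np.full((last - first + 1, len(indices)), np.nan)
    for j, s in enumerate(indices):
        i0 = s.first_year - first
        mat[i0 : i0 + len(s.values), j] = s.values
    return mat, first


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return np.nan
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def leave_one_out_screen(
    collection: SiteCollection,
    r_min: float = 0.4,
    kind: str = "total",
    iterate: bool = True,
) -> tuple[SiteCollection, list[str], dict[str, float]]:
    """Reject series whose Baillie–Pilcher index correlates < ``r_min``
    with the mean of all other series.

    Each tree's index is compared (Pearson r, overlap ≥ 10 years) with the
    mean index of the remaining trees; the worst series below the threshold
    is dropped and, when ``iterate``, the screen is repeated to a fixed
    point.  Returns the retained collection, the rejected ids, and the
    final per-series correlations.
    """
    if len(collection) < 3:
        raise ValueError("screening requires at least 3 series")
    trees = list(collection.trees)
    rejected: list[str] = []
    r_final: dict[str, float] = {}
    while True:
        indices = [
            baillie_pilcher_index(t.fraction(kind), first_year=t.first_year)
            for t in trees
        ]
        mat, _ = _aligned_matrix(indices)
        r_now: dict[str, float] = {}
        for j, t in enumerate(trees):
            others = np.delete(np.arange(mat.shape[1]), j)
            mean_others = np.nanmean(mat[:, others], axis=1)
            ok = np.isfinite(mat[:, j]) & np.isfinite(mean_others)
            if ok.sum() < MIN_OVERLAP:
                logger.warning(
                    "tree %s overlaps the site mean by < %d years; retained",
                    t.tree_id,
                    MIN_OVERLAP,
                )
                r_now[t.tree_id] = np.nan
                continue
            r_now[t.tree_id] = _pearson(mat[:, j], mean_others)
        r_final = r_now
        below = [
            t for t in trees
            if np.isfinite(r_now[t.tree_id]) and r_now[t.tree_id] < r_min
        ]
        # a non-positive threshold is vacuous: nothing is ever dropped
        if r_min <= 0 or not below or len(trees) <= 3:
            break
        worst = min(below, key=lambda t: r_now[t.tree_id])
        trees.remove(worst)
        rejected.append(worst.tree_id)
        if not iterate:
            # one pass: drop every series below threshold, then stop
            for t in below:
                if t is not worst and t in trees and len(trees) > 3:
                    trees.remove(t)
                    rejected.append(t.tree_id)
            break
    retained = collection.replace(trees=trees)
    return retained, rejected, r_final


def site_chronology(
    indices: list[IndexSeries], robust: bool = False
) -> IndexSeries:
    """Per-year mean of the index series covering each year.

    With ``robust`` the Tukey biweight robust mean is used instead of the
    arithmetic mean.  Years inside the span covered by no series are NaN.
    """
    if not indices:
        raise ValueError("no index series given")
    mat, first = _aligned_matrix(indices)
    if robust:
        vals = np.array([_biweight(row) for row in mat])
    else:
        with np.errstate(invalid="ignore"):
            counts = np.isfinite(mat).sum(axis=1)
            vals = np.where(counts > 0, np.nansum(np.nan_to_num(mat), axis=1), np.nan)
            vals = np.where(counts > 0, vals / np.maximum(counts, 1), np.nan)
    if np.isnan(vals).any():
        logger.warning("site chronology has %d uncovered years", int(np.isnan(vals).sum()))
    basis = indices[0].basis
    return IndexSeries(first, vals, basis)


def _biweight(row: np.ndarray, c: float = 9.0) -> float:
    x = row[np.isfinite(row)]
    if x.size == 0:
        return np.nan
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return float(med)
    u = (x - med) / (c * mad)
    w = (1 - u**2) ** 2
    w[np.abs(u) >= 1] = 0
    if w.sum() == 0:
        return float(med)
    return float(np.sum(x * w) / np.sum(w))


def eps_snr(
    indices: list[IndexSeries], window: tuple[int, int] | None = None
) -> ChronologyStats:
    """Wigley expressed population signal and signal-to-noise ratio.

    rbar is the mean pairwise Pearson correlation over the window (pairs
    with < 10 overlapping years are skipped with a warning).  Negative
    rbar yields EPS = SNR = 0 with a warning; rbar = 1 yields SNR = +inf.
    """
    mat, first = _aligned_matrix(indices)
    if window is None:
        window = (first, first + mat.shape[0] - 1)
    i0 = max(window[0] - first, 0)
    i1 = min(window[1] - first + 1, mat.shape[0])
    sub = mat[i0:i1]
    cols = [j for j in range(sub.shape[1]) if np.isfinite(sub[:, j]).sum() >= 2]
    n = len(cols)
    if n < 2:
        raise ValueError("eps_snr requires >= 2 series overlapping the window")
    rs = []
    for a in range(n):
        for b in range(a + 1, n):
            x, y = sub[:, cols[a]], sub[:, cols[b]]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < MIN_OVERLAP:
                logger.warning("pair with overlap < %d years skipped", MIN_OVERLAP)
                continue
            r = _pearson(x, y)
            if np.isfinite(r):
                rs.append(r)
    if not rs:
        raise ValueError("no series pair with sufficient overlap in the window")
    rbar = float(np.mean(rs))
    if rbar <= 0:
        logger.warning("rbar = %.3f <= 0; EPS and SNR reported as 0", rbar)
        return ChronologyStats(rbar, 0.0, 0.0, n, (int(window[0]), int(window[1])))
    if rbar >= 1.0:
        return ChronologyStats(1.0, 1.0, np.inf, n, (int(window[0]), int(window[1])))
    eps = n * rbar / (n * rbar + 1 - rbar)
    snr = n * rbar / (1 - rbar)
    return ChronologyStats(rbar, float(eps), float(snr), n, (int(window[0]), int(window[1])))


def reliable_span(
    indices: list[IndexSeries],
    window_len: int = 20,
    overlap: int = 10,
    eps_min: float = 0.85,
) -> tuple[int, int] | None:
    """Longest contiguous run of moving windows with EPS ≥ ``eps_min``.

    Windows of ``window_len`` years slide by ``window_len − overlap``,
    anchored at the first year of the union span; a final right-aligned
    window covers any remainder.  Returns the union of the passing run, or
    None (with a warning) when no window passes.
    """
    first = min(s.first_year for s in indices)
    last = max(s.last_year for s in indices)
    if last - first + 1 < window_len:
        raise ValueError("total span shorter than the window length")
    step = window_len - overlap
    if step < 1:
        raise ValueError("overlap must be smaller than window_len")
    starts = list(range(first, last - window_len + 2, step))
    if starts and starts[-1] + window_len - 1 < last:
        starts.append(last - window_len + 1)
    passing = []
    for s0 in starts:
        win = (s0, s0 + window_len - 1)
        try:
            stats = eps_snr(indices, win)
            passing.append(stats.eps >= eps_min)
        except ValueError:
            passing.append(False)
    best_run: tuple[int, int] | None = None  # indices into starts
    run_start = None
    for i, ok in enumerate(passing + [False]):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            if best_run is None or i - run_start > best_run[1] - best_run[0] + 1:
                best_run = (run_start, i - 1)
            run_start = None
    if best_run is None:
        logger.warning("no moving window reaches EPS >= %.2f", eps_min)
        return None
    lo = starts[best_run[0]]
    hi = starts[best_run[1]] + window_len - 1
    return lo, hi


def detrend_collection(
    collection: SiteCollection,
    method: str = "spline",
    kind: str = "total",
    stiffness: float | None = None,
) -> list[IndexSeries]:
    """Detrend every tree's ``kind`` widths with the named method."""
    funcs = {
        "spline": spline_detrend,
        "baillie_pilcher": lambda w, first_year: baillie_pilcher_index(
            w, first_year=first_year
        ),
        "double_detrend": double_detrend,
    }
    if method not in funcs:
        raise ValueError(f"unknown detrending method {method!r}")
    out = []
    for t in collection.trees:
        w = t.fraction(kind).astype(float).copy()
        w[t.missing_flags] = np.nan  # interpolated inside the detrenders
        if method == "spline":
            out.append(spline_detrend(w, stiffness=stiffness, first_year=t.first_year))
        elif method == "double_detrend":
            out.append(double_detrend(w, stiffness=stiffness, first_year=t.first_year))
        else:
            out.append(baillie_pilcher_index(w, first_year=t.first_year))
    return out
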