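"""Independent-component detector (MICA).

The per-tree ring-width series are truncated to a common span, z-scored,
and decomposed with fixed-point ICA (FastICA).  A preliminary defoliation
signal is a run of at least ``lng`` consecutive years in which any
component stays below ``lim`` (standardised units); the run is confirmed
when the spline-detrended site chronology dips below its ``q``-quantile
within ``rng`` years of the run.  Confirmed runs are reported by their
first year.

ICA leaves component sign and scale undetermined; components are therefore
rescaled to unit variance and oriented to correlate positively with the
mean standardised series, which makes "below ``lim``" well-defined.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from ..chronology import detrend_collection, site_chronology
from ..series import IndexBasis, IndexSeries, SiteCollection
from .base import BaseRingDetector, DetectionResult

logger = logging.getLogger(__name__)

__all__ = ["standardize_matrix", "ica_decompose", "mica_detect", "ICADetector"]


def standardize_matrix(
    collection: SiteCollection, kind: str = "total", min_span: int = 30
) -> tuple[np.ndarray, tuple[int, int], int]:
    """Truncate to the common span and z-score each tree's series.

    Returns the year × tree matrix, the common span, and the number of
    early years removed (difference between the earliest tree start and
    the common start).
    """
    if len(collection) < 5:
        raise ValueError("standardize_matrix requires >= 5 trees")
    lo, hi = collection.common_span
    if hi - lo + 1 < min_span:
        raise ValueError(f"common span {lo}-{hi} shorter than {min_span} years")
    earliest = min(t.first_year for t in collection.trees)
    n_removed = lo - earliest
    n_years = hi - lo + 1
    mat = np.empty((n_years, len(collection)))
    for j, t in enumerate(collection.trees):
        w = t.window(lo, hi)
        col = w.fraction(kind).astype(float)
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(f"tree {t.tree_id!r} has zero variance on the common span")
        mat[:, j] = (col - col.mean()) / sd
    return mat, (lo, hi), n_removed


def n_components_80pct(mat: np.ndarray, cap: int = 5) -> int:
    """Smallest number of principal components explaining ≥ 80% variance."""
    # eigen-decomposition of the column covariance; columns are z-scores
    cov = np.cov(mat, rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0, None)
    cum = np.cumsum(eig) / eig.sum()
    k = int(np.searchsorted(cum, 0.80) + 1)
    return max(1, min(k, cap, mat.shape[1]))


def ica_decompose(
    mat: np.ndarray, n_components: int | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-point ICA of the standardised matrix.

    Returns (components, mixing): components is year × k, each component
    rescaled to unit variance and sign-oriented to correlate positively
    with the mean standardised series.  Deterministic given ``seed``.
    """
    if n_components is None:
        n_components = n_components_80pct(mat)
    if n_components > mat.shape[1]:
        raise ValueError("n_components exceeds the number of trees")
    comps = None
    # fixed-point iteration is sensitive to the random start on
    # near-Gaussian data; retry from a few derived starts before giving up
    for attempt in range(3):
        ica = FastICA(
            n_components=n_components,
            random_state=int(seed) + 7919 * attempt,
            max_iter=2000,
            tol=1e-3,
            whiten="unit-variance",
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("error", category=ConvergenceWarning)
            try:
                comps = ica.fit_transform(mat)
                break
            except ConvergenceWarning:
                continue
    if comps is None:
        raise RuntimeError(
            "FastICA did not converge; try another seed or fewer components"
        )
    mixing = ica.mixing_
    mean_series = mat.mean(axis=1)
    for k in range(comps.shape[1]):
        sd = comps[:, k].std(ddof=1)
        if sd > 0:
            comps[:, k] /= sd
            mixing[:, k] *= sd
        r = np.corrcoef(comps[:, k], mean_series)[0, 1]
        if np.isfinite(r) and r < 0:
            comps[:, k] *= -1
            mixing[:, k] *= -1
    return comps, mixing


def _component_runs(comp: np.ndarray, lim: float, lng: int) -> list[tuple[int, int]]:
    """Maximal runs (start, end indices, inclusive) of values < lim, length >= lng."""
    below = comp < lim
    runs = []
    start = None
    for i, b in enumerate(list(below) + [False]):
        if b and start is None:
            start = i
        elif not b and start is not None:
            if i - start >= lng:
                runs.append((start, i - 1))
            start = None
    return runs


def mica_detect(
    components: np.ndarray,
    site_index: IndexSeries,
    first_year: int,
    lim: float = -1.3,
    lng: int = 3,
    q: float = 0.2,
    rng: int = 2,
    site_id: str = "site",
) -> DetectionResult:
    """Confirm sustained component lows against site-chronology lows.

    ``components`` is the year × k matrix starting at ``first_year``;
    ``site_index`` must cover the same span.  A run is confirmed when the
    chronology has at least one year below its ``q``-quantile (computed
    over the analysed span) within [run_start − rng, run_end + rng].
    """
    if lng < 1 or not 0 < q < 1 or rng < 0:
        raise ValueError("require lng >= 1, 0 < q < 1, rng >= 0")
    n_years = components.shape[0]
    last_year = first_year + n_years - 1
    chron = np.array(
        [site_index.value_at(y) for y in range(first_year, last_year + 1)]
    )
    finite = np.isfinite(chron)
    if finite.sum() < 2:
        raise ValueError("site chronology does not cover the analysed span")
    qval = np.nanquantile(chron[finite], q)
    low_year = finite & (chron < qval)
    intervals = []
    for k in range(components.shape[1]):
        for s, e in _component_runs(components[:, k], lim, lng):
            lo = max(0, s - rng)
            hi = min(n_years - 1, e + rng)
            if low_year[lo : hi + 1].any():
                intervals.append((s, e, k))
    # merge overlapping confirmed runs, keeping the earliest start
    intervals.sort()
    merged: list[list[int]] = []
    for s, e, _k in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    events = [first_year + s for s, _e in merged]
    support = {
        first_year + s: {
            "run_start": int(first_year + s),
            "run_end": int(first_year + e),
        }
        for s, e in merged
    }
    return DetectionResult(
        site_id=site_id,
        method="mica",
        event_years=events,
        support=support,
        span=(first_year, last_year),
    )


class ICADetector(BaseRingDetector):
    """Full MICA pipeline: standardise → decompose → confirm.

    ``n_components=None`` selects the smallest number of principal
    components explaining ≥ 80% of the variance, capped at 5.  The site
    chronology for the confirmation step is the mean of the spline-detrended
    per-tree series over the common span.
    """

    method = "mica"

    def __init__(
        self,
        lim: float = -1.3,
        lng: int = 3,
        q: float = 0.2,
        rng: int = 2,
        n_components: int | None = None,
        seed: int = 0,
        stiffness: float | None = None,
    ):
        self.lim = lim
        self.lng = lng
        self.q = q
        self.rng = rng
        self.n_components = n_components
        self.seed = seed
        self.stiffness = stiffness

    def _detect(self, collection: SiteCollection) -> DetectionResult:
        mat, (lo, hi), n_removed = standardize_matrix(collection)
        comps, mixing = ica_decompose(mat, self.n_components, self.seed)
        indices = detrend_collection(
            collection, method="spline", kind="total", stiffness=self.stiffness
        )
        chron = site_chronology(indices)
        chron = IndexSeries(
            lo,
            [chron.value_at(y) for y in range(lo, hi + 1)],
            IndexBasis.SPLINE,
        )
        result = mica_detect(
            comps,
            chron,
            first_year=lo,
            lim=self.lim,
            lng=self.lng,
            q=self.q,
            rng=self.rng,
            site_id=collection.site_id,
        )
        self.components_ = comps
        self.mixing_ = mixing
        self.n_removed_years_ = n_removed
        self.common_span_ = (lo, hi)
        return result
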