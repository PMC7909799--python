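"""OUTBREAK-style detector: sustained, abrupt growth suppression.

The classical host-tree approach to outbreak reconstruction: a tree is
considered defoliated from year t when its spline-detrended ring-width
index stays at least ``std`` standard deviations below its mean for
``lng`` consecutive years and the suppression sets in abruptly (index
RGC at the onset year ≤ ``abrupt`` as a unit fraction).  The stand
records year t as a defoliation onset when at least ``min_tree_prop``
of the trees carry an onset flag there.

Because the signal is the total-ring-width decline — which peaks one to
two years after a late-season defoliation — this detector characteristically
lags the seasonal pointer-year method.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..chronology import detrend_collection
from ..series import IndexSeries, SiteCollection
from .base import BaseRingDetector, DetectionResult, merge_flagged_years

logger = logging.getLogger(__name__)


def outbreak_flag_tree(
    index: IndexSeries,
    std: float = 0.5,
    lng: int = 2,
    abrupt: float = 0.8,
) -> np.ndarray:
    """Per-year onset flags for one detrended tree index.

    Year t is flagged iff (a) the indices at t .. t+lng−1 all lie at or
    below mean − std·sd of the series and (b) the index-to-previous-index
    ratio at t is ≤ ``abrupt``.  A constant series (sd = 0) yields no
    flags; undefined index values fail both criteria.
    """
    vals = np.asarray(index.values, dtype=float)
    n = len(vals)
    flags = np.zeros(n, dtype=bool)
    if n < lng + 1:
        logger.warning("series shorter than lng + 1; no flags")
        return flags
    finite = np.isfinite(vals)
    if finite.sum() < 2:
        return flags
    mean = vals[finite].mean()
    sd = vals[finite].std(ddof=1)
    if sd == 0:
        return flags
    thr = mean - std * sd
    below = finite & (vals <= thr)
    # ratio of the index to the previous year's index, a unit fraction
    ratio = np.full(n, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio[1:] = vals[1:] / vals[:-1]
    ratio[1:][~finite[:-1] | (vals[:-1] <= 0)] = np.nan
    for t in range(1, n - lng + 1):
        if below[t : t + lng].all() and np.isfinite(ratio[t]) and ratio[t] <= abrupt:
            flags[t] = True
    return flags


class OutbreakDetector(BaseRingDetector):
    """Aggregate per-tree suppression-onset flags into stand events.

    Parameters follow the classical vocabulary: ``std`` (standard
    deviations below the mean), ``lng`` (minimum run length, years),
    ``abrupt`` (maximum onset index ratio, unit fraction) and
    ``min_tree_prop`` (minimum share of flagged trees).  ``stiffness``
    is forwarded to the spline detrending.
    """

    method = "outbreak"

    def __init__(
        self,
        std: float = 0.5,
        lng: int = 2,
        abrupt: float = 0.8,
        min_tree_prop: float = 0.10,
        stiffness: float | None = None,
        min_event_gap: int = 2,
    ):
        self.std = std
        self.lng = lng
        self.abrupt = abrupt
        self.min_tree_prop = min_tree_prop
        self.stiffness = stiffness
        self.min_event_gap = min_event_gap

    def _detect(self, collection: SiteCollection) -> DetectionResult:
        if self.std <= 0 or self.lng < 1:
            raise ValueError("std must be > 0 and lng >= 1")
        if not 0 < self.abrupt <= 1 or not 0 < self.min_tree_prop <= 1:
            raise ValueError("abrupt and min_tree_prop must be in (0, 1]")
        indices = detrend_collection(
            collection, method="spline", kind="total", stiffness=self.stiffness
        )
        first, last = collection.span
        n_years = last - first + 1
        flag_mat = np.zeros((n_years, len(indices)), dtype=bool)
        covered = np.zeros((n_years, len(indices)), dtype=bool)
        for j, idx in enumerate(indices):
            i0 = idx.first_year - first
            flag_mat[i0 : i0 + len(idx.values), j] = outbreak_flag_tree(
                idx, self.std, self.lng, self.abrupt
            )
            covered[i0 : i0 + len(idx.values), j] = np.isfinite(idx.values)
        events: list[int] = []
        support: dict[int, dict] = {}
        n_cov = covered.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_cov > 0, flag_mat.sum(axis=1) / np.maximum(n_cov, 1), 0.0)
        for i in range(n_years):
            if n_cov[i] >= self.min_trees and frac[i] >= self.min_tree_prop:
                y = first + i
                events.append(y)
                support[y] = {
                    "frac_trees": round(float(frac[i]), 4),
                    "n_trees": int(n_cov[i]),
                }
        merged = merge_flagged_years(events, self.min_event_gap)
        flags = pd.DataFrame(
            flag_mat,
            index=np.arange(first, last + 1),
            columns=[t.tree_id for t in collection.trees],
        )
        return DetectionResult(
            site_id=collection.site_id,
            method=self.method,
            event_years=merged,
            support={y: support[y] for y in merged},
            per_tree_flags=flags,
            span=(first, last),
        )


def outbreak_detect(collection: SiteCollection, **params) -> DetectionResult:
    """Functional wrapper around :class:`OutbreakDetector`."""
    return OutbreakDetector(**params).fit(collection).result_
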