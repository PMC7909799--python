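"""Moving-window local-minimum detector on absolute ring widths.

A year is a local minimum for a tree when its raw ring width is strictly
smaller than every other width in the window [t − width, t + width]; the
stand records a probable defoliation when the share of trees with a local
minimum at t reaches ``perc``.  Edge years without a full window are never
flagged, and a within-window tie disqualifies both tied years (strictness
is configurable).

The detector sees the delayed total-width trough, so its events typically
trail the defoliation year by one to four years.  Because suppressed trees
can reach their minima in different calendar years, the per-year proportion
can split across adjacent years and stay below threshold — a documented
false-negative mode; the optional ``adjacent_sum`` flag sums the
proportions of two adjacent years before thresholding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..series import SiteCollection
from .base import BaseRingDetector, DetectionResult

__all__ = ["local_minimum_flags", "MovingWindowDetector", "mwm_detect"]


def local_minimum_flags(
    series, width: int = 3, allow_ties: bool = False
) -> np.ndarray:
    """Flag years that are the strict minimum of their full window.

    ``width`` is the half-window in years.  With ``allow_ties`` a year
    tied for the window minimum is still flagged.
    """
    w = np.asarray(series, dtype=float)
    if width < 1:
        raise ValueError("width must be >= 1")
    n = len(w)
    flags = np.zeros(n, dtype=bool)
    for t in range(width, n - width):
        window = w[t - width : t + width + 1]
        others = np.delete(window, width)
        if allow_ties:
            flags[t] = w[t] <= others.min()
        else:
            flags[t] = w[t] < others.min()
    return flags


class MovingWindowDetector(BaseRingDetector):
    """Synchronous local minima of absolute ring width.

    Parameters
    ----------
    width : int
        Half-window in years.
    perc : float
        Minimum share of trees (unit fraction) with a local minimum at t.
    allow_ties : bool
        Count a tied window minimum as a local minimum.
    adjacent_sum : bool
        Experimental: compare the sum of two adjacent years' proportions
        against ``perc`` (off by default).
    """

    method = "mwm"

    def __init__(
        self,
        width: int = 3,
        perc: float = 0.35,
        allow_ties: bool = False,
        adjacent_sum: bool = False,
    ):
        self.width = width
        self.perc = perc
        self.allow_ties = allow_ties
        self.adjacent_sum = adjacent_sum

    def _detect(self, collection: SiteCollection) -> DetectionResult:
        if self.width < 1 or not 0 < self.perc <= 1:
            raise ValueError("width must be >= 1 and perc in (0, 1]")
        first, last = collection.span
        n_years = last - first + 1
        trees = collection.trees
        flag_mat = np.zeros((n_years, len(trees)), dtype=bool)
        covered = np.zeros((n_years, len(trees)), dtype=bool)
        for j, t in enumerate(trees):
            i0 = t.first_year - first
            flags = local_minimum_flags(t.total, self.width, self.allow_ties)
            flag_mat[i0 : i0 + len(t), j] = flags
            # only years with a full window inside the tree's span count
            if len(t) >= 2 * self.width + 1:
                covered[i0 + self.width : i0 + len(t) - self.width, j] = True
        n_cov = covered.sum(axis=1)
        with np.errstate(invalid="ignore"):
            frac = np.where(n_cov > 0, flag_mat.sum(axis=1) / np.maximum(n_cov, 1), 0.0)
        if self.adjacent_sum:
            test = frac.copy()
            test[:-1] = frac[:-1] + frac[1:]
        else:
            test = frac
        events, support = [], {}
        used = np.zeros(n_years, dtype=bool)
        for i in range(n_years):
            if n_cov[i] < self.min_trees or used[i]:
                continue
            if test[i] >= self.perc:
                y = first + i
                events.append(y)
                support[y] = {
                    "frac_trees": round(float(frac[i]), 4),
                    "n_trees": int(n_cov[i]),
                }
                if self.adjacent_sum and i + 1 < n_years:
                    support[y]["frac_next"] = round(float(frac[i + 1]), 4)
                    used[i + 1] = True
        flags = pd.DataFrame(
            flag_mat,
            index=np.arange(first, last + 1),
            columns=[t.tree_id for t in trees],
        )
        return DetectionResult(
            site_id=collection.site_id,
            method=self.method,
            event_years=events,
            support=support,
            per_tree_flags=flags,
            span=(first, last),
        )


def mwm_detect(collection: SiteCollection, **params) -> DetectionResult:
    """Functional wrapper around :class:`MovingWindowDetector`."""
    return MovingWindowDetector(**params).fit(collection).result_
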