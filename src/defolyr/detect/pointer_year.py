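"""The seasonal pointer-year method (PYM).

A late-summer/autumn defoliator (here the pine looper, *Bupalus piniaria*)
eats needles after the current ring is complete, so its signature is
delayed and season-specific: latewood — built largely from the current
year's photosynthate — collapses in year t+1, and earlywood — drawing on
stored reserves — collapses in year t+2.  Year t is therefore declared a
defoliation year when both declines occur synchronously across the stand:

* (a) the latewood relative growth change in t+1 shows at least a
  ``change_l`` % drop in at least ``sync_l`` % of evaluable trees, and
* (b) the earlywood relative growth change in t+2 shows at least a
  ``change_e`` % drop in at least ``sync_e`` % of evaluable trees.

The relative growth change is RGC_t = 100 · R_t / R_{t−1} (per cent of the
previous ring); it is undefined at the series start, at missing rings and
where the previous ring is zero.

Threshold semantics: with the default ``"drop"`` semantics the test is
RGC ≤ 100 − change (a decline of at least ``change`` per cent); the
alternative ``"ratio"`` semantics tests RGC < change literally, i.e. a
collapse to below ``change`` % of the previous ring.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..series import SeasonalRingSeries, SiteCollection
from .base import BaseRingDetector, DetectionResult, merge_flagged_years

logger = logging.getLogger(__name__)


def rgc(series, missing_flags=None) -> np.ndarray:
    """Relative growth change, per cent: RGC_t = 100 · R_t / R_{t−1}.

    NaN marks years where the statistic is undefined: the first year,
    missing rings (either of the two years involved), and years whose
    previous width is zero.
    """
    if isinstance(series, SeasonalRingSeries):
        raise TypeError("pass a width vector and missing_flags explicitly")
    w = np.asarray(series, dtype=float)
    if len(w) < 2:
        raise ValueError("RGC requires at least 2 rings")
    out = np.full(len(w), np.nan)
    prev = w[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        out[1:] = 100.0 * w[1:] / prev
    out[1:][prev == 0] = np.nan
    if missing_flags is not None:
        m = np.asarray(missing_flags, dtype=bool)
        out[m] = np.nan
        out[1:][m[:-1]] = np.nan
    return out


class PointerYearDetector(BaseRingDetector):
    """Detect defoliation years from synchronized seasonal RGC drops.

    Parameters
    ----------
    change_l, sync_l : float
        Latewood drop threshold (%) and the minimum share of trees (%)
        that must show it in year t+1.
    change_e, sync_e : float
        The same pair for earlywood in year t+2.
    semantics : {"drop", "ratio"}
        ``drop``: test RGC ≤ 100 − change; ``ratio``: test RGC < change.
    min_event_gap : int
        Flagged years closer than this are merged, keeping the first.

    Fitted attributes: ``event_years_``, ``support_``, ``result_``.
    """

    method = "pym"

    def __init__(
        self,
        change_l: float = 10.0,
        sync_l: float = 55.0,
        change_e: float = 10.0,
        sync_e: float = 55.0,
        semantics: str = "drop",
        min_event_gap: int = 2,
    ):
        self.change_l = change_l
        self.sync_l = sync_l
        self.change_e = change_e
        self.sync_e = sync_e
        self.semantics = semantics
        self.min_event_gap = min_event_gap

    def _passes(self, rgc_values: np.ndarray, change: float) -> np.ndarray:
        if self.semantics == "drop":
            return rgc_values <= 100.0 - change
        if self.semantics == "ratio":
            return rgc_values < change
        raise ValueError(f"unknown threshold semantics {self.semantics!r}")

    def _detect(self, collection: SiteCollection) -> DetectionResult:
        for name in ("change_l", "sync_l", "change_e", "sync_e"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must be in (0, 100], got {v}")
        first, last = collection.span
        if last - first + 1 < 3:
            raise ValueError("analyzed span must cover at least 3 years")
        n_years = last - first + 1
        trees = collection.trees
        lw_rgc = np.full((n_years, len(trees)), np.nan)
        ew_rgc = np.full((n_years, len(trees)), np.nan)
        for j, t in enumerate(trees):
            i0 = t.first_year - first
            sl = slice(i0, i0 + len(t))
            lw_rgc[sl, j] = rgc(t.latewood, t.missing_flags)
            ew_rgc[sl, j] = rgc(t.earlywood, t.missing_flags)

        pass_l = self._passes(lw_rgc, self.change_l)
        pass_e = self._passes(ew_rgc, self.change_e)
        flagged: list[int] = []
        support: dict[int, dict] = {}
        tree_hits = np.zeros((n_years, len(trees)), dtype=bool)
        for t_year in range(first, last - 1):
            i_l = t_year + 1 - first  # latewood test year
            i_e = t_year + 2 - first  # earlywood test year
            eval_l = np.isfinite(lw_rgc[i_l])
            eval_e = np.isfinite(ew_rgc[i_e])
            n_l, n_e = int(eval_l.sum()), int(eval_e.sum())
            if n_l < self.min_trees or n_e < self.min_trees:
                logger.warning(
                    "year %d skipped: %d/%d evaluable trees for the "
                    "latewood/earlywood tests (need >= %d)",
                    t_year, n_l, n_e, self.min_trees,
                )
                continue
            frac_l = (pass_l[i_l] & eval_l).sum() / n_l
            frac_e = (pass_e[i_e] & eval_e).sum() / n_e
            if frac_l >= self.sync_l / 100.0 and frac_e >= self.sync_e / 100.0:
                flagged.append(t_year)
                support[t_year] = {
                    "frac_latewood": round(float(frac_l), 4),
                    "frac_earlywood": round(float(frac_e), 4),
                    "n_latewood": n_l,
                    "n_earlywood": n_e,
                }
                tree_hits[t_year - first] = (
                    pass_l[i_l] & eval_l & pass_e[i_e] & eval_e
                )
        events = merge_flagged_years(flagged, self.min_event_gap)
        flags = pd.DataFrame(
            tree_hits,
            index=np.arange(first, last + 1),
            columns=[t.tree_id for t in trees],
        )
        return DetectionResult(
            site_id=collection.site_id,
            method=self.method,
            event_years=events,
            support={y: support[y] for y in events},
            per_tree_flags=flags,
            span=(first, last),
        )


def pym_detect(collection: SiteCollection, **params) -> DetectionResult:
    """Functional wrapper around :class:`PointerYearDetector`."""
    return PointerYearDetector(**params).fit(collection).result_


def merge_site_events(
    per_site: list[DetectionResult], tolerance: int = 2
) -> list[dict]:
    """Single-linkage merge of per-site event years into regional events.

    Years whose chain-wise gaps are ≤ ``tolerance`` form one regional
    event, reported by its earliest year together with the member sites.
    """
    if not per_site:
        raise ValueError("no site results given")
    pairs = sorted(
        (y, r.site_id) for r in per_site for y in r.event_years
    )
    if not pairs:
        return []
    clusters: list[list[tuple[int, str]]] = [[pairs[0]]]
    for y, site in pairs[1:]:
        if y - clusters[-1][-1][0] <= tolerance:
            clusters[-1].append((y, site))
        else:
            clusters.append([(y, site)])
    return [
        {
            "year": c[0][0],
            "years": sorted({y for y, _ in c}),
            "sites": sorted({s for _, s in c}),
        }
        for c in clusters
    ]
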