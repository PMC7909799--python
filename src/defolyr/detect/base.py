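"""Shared detector machinery: result container and the estimator base."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ..series import SiteCollection

METHODS = ("pym", "outbreak", "mwm", "mica")


@dataclass
class DetectionResult:
    """Inferred defoliation years for one site and one method.

    ``support`` maps each event year to the statistics that triggered it
    (tree proportions, run lengths, ...); ``per_tree_flags`` optionally
    holds the year × tree boolean matrix behind the aggregation.
    """

    site_id: str
    method: str
    event_years: list[int]
    support: dict[int, dict] = field(default_factory=dict)
    per_tree_flags: pd.DataFrame | None = None
    span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        self.event_years = sorted(int(y) for y in self.event_years)
        if self.span is not None:
            lo, hi = self.span
            for y in self.event_years:
                if not lo <= y <= hi:
                    raise ValueError(f"event year {y} outside analyzed span {self.span}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for y in self.event_years:
            sup = self.support.get(y, {})
            rows.append({"site": self.site_id, "method": self.method, "year": y, **sup})
        return pd.DataFrame(rows, columns=None if rows else ["site", "method", "year"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path=None):
        payload = {
            "site": self.site_id,
            "method": self.method,
            "span": list(self.span) if self.span else None,
            "events": [
                {"year": y, **_jsonable(self.support.get(y, {}))}
                for y in self.event_years
            ],
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        out[k] = v
    return out


def merge_flagged_years(years, min_gap: int = 2) -> list[int]:
    """Keep the first year of each cluster of flagged years.

    One defoliation episode produces overlapping growth signatures, so
    successive flagged years closer than ``min_gap`` to the previous
    flagged year are collapsed into one event reported by its first year.
    """
    years = sorted(int(y) for y in years)
    out: list[int] = []
    prev = None
    for y in years:
        if prev is None or y - prev >= min_gap:
            out.append(y)
        prev = y
    return out


class BaseRingDetector(BaseEstimator):
    """scikit-learn-style base for the stand-level detectors.

    Subclasses implement ``_detect(collection) -> DetectionResult``; ``fit``
    validates the collection, stores the result and exposes
    ``event_years_``, ``support_`` and ``result_``.
    """

    #: minimum number of trees required for a stand-level decision
    min_trees = 5

    method: str = ""

    def fit(self, X: SiteCollection, y=None) -> "BaseRingDetector":
        if not isinstance(X, SiteCollection):
            raise TypeError("X must be a SiteCollection")
        if len(X) < self.min_trees:
            raise ValueError(
                f"{type(self).__name__} requires >= {self.min_trees} trees, "
                f"got {len(X)}"
            )
        result = self._detect(X)
        self.result_ = result
        self.event_years_ = list(result.event_years)
        self.support_ = dict(result.support)
        self.n_trees_ = len(X)
        return self

    def predict(self, X: SiteCollection | None = None) -> list[int]:
        """Event years of the fitted (or freshly fitted) collection."""
        if X is not None:
            self.fit(X)
        if not hasattr(self, "event_years_"):
            raise AttributeError("detector is not fitted")
        return list(self.event_years_)

    def _detect(self, collection: SiteCollection) -> DetectionResult:
        raise NotImplementedError
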