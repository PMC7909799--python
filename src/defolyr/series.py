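"""Core containers for seasonal ring-width data.

A conifer's annual ring splits into a spring-formed earlywood fraction and
a summer-formed latewood fraction.  Late-summer defoliators remove foliage
after the current ring is essentially complete, so their signature appears
as a latewood decline one year later and an earlywood decline two years
later — which is why the containers here keep the two fractions separate
rather than only the total width.

All widths are in millimetres; years are calendar growth years, strictly
consecutive within a series.  A locally absent ("missing") ring is stored
as width 0 with its ``missing`` flag set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

#: tolerance (mm) for the earlywood + latewood = total identity
SEASONAL_SUM_TOL = 0.01


class IndexBasis(str, Enum):
    """Provenance of a dimensionless growth-index series."""

    BAILLIE_PILCHER = "baillie_pilcher"
    SPLINE = "spline"
    DOUBLE_DETREND = "double_detrend"
    ZSCORE = "zscore"
    RAW = "raw"


@dataclass
class IndexSeries:
    """A dated series of dimensionless growth indices.

    Parameters
    ----------
    first_year : int
        Calendar year of the first value.
    values : ndarray
        Growth indices; NaN marks years where the index is undefined
        (e.g. the detrending curve hit zero, or a missing ring).
    basis : IndexBasis
        Which standardisation produced the series.
    """

    first_year: int
    values: np.ndarray
    basis: IndexBasis = IndexBasis.RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("IndexSeries requires a 1-D vector of length >= 1")
        if np.isinf(self.values).any():
            raise ValueError("IndexSeries values must be finite or NaN")
        self.basis = IndexBasis(self.basis)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.values))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.values) - 1

    def window(self, first: int, last: int) -> "IndexSeries":
        """Closed-interval slice [first, last]; years outside the span error."""
        if first < self.first_year or last > self.last_year or first > last:
            raise ValueError(
                f"window [{first}, {last}] outside series span "
                f"[{self.first_year}, {self.last_year}]"
            )
        i0 = first - self.first_year
        return IndexSeries(first, self.values[i0 : i0 + last - first + 1], self.basis)

    def value_at(self, year: int) -> float:
        if year < self.first_year or year > self.last_year:
            return float("nan")
        return float(self.values[year - self.first_year])


@dataclass
class SeasonalRingSeries:
    """One tree's (or core's) dated earlywood/latewood/total width vectors.

    Invariants enforced at construction: equal-length vectors, non-negative
    widths, consecutive years, and |total − (earlywood + latewood)| ≤ 0.01 mm
    wherever the ring is not missing.
    """

    tree_id: str
    first_year: int
    earlywood: np.ndarray
    latewood: np.ndarray
    total: np.ndarray
    core_ids: list[str] = field(default_factory=list)
    missing_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.earlywood = np.asarray(self.earlywood, dtype=float)
        self.latewood = np.asarray(self.latewood, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        n = len(self.total)
        if n < 1:
            raise ValueError("series must contain at least one ring")
        if not (len(self.earlywood) == len(self.latewood) == n):
            raise ValueError("earlywood, latewood and total must have equal length")
        if self.missing_flags is None:
            self.missing_flags = np.zeros(n, dtype=bool)
        else:
            self.missing_flags = np.asarray(self.missing_flags, dtype=bool)
            if len(self.missing_flags) != n:
                raise ValueError("missing_flags length mismatch")
        for name in ("earlywood", "latewood", "total"):
            v = getattr(self, name)
            if np.isnan(v).any() or (v < 0).any():
                raise ValueError(f"{name} widths must be >= 0 and non-NaN")
        ok = self.missing_flags | (
            np.abs(self.total - (self.earlywood + self.latewood)) <= SEASONAL_SUM_TOL
        )
        if not ok.all():
            bad = int(np.argmin(ok)) + self.first_year
            raise ValueError(
                f"earlywood + latewood differs from total by more than "
                f"{SEASONAL_SUM_TOL} mm at year {bad}"
            )

    def __len__(self) -> int:
        return len(self.total)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self) - 1

    @property
    def span(self) -> tuple[int, int]:
        return self.first_year, self.last_year

    def fraction(self, kind: str) -> np.ndarray:
        """Width vector for ``kind`` in {'earlywood', 'latewood', 'total'}."""
        if kind not in ("earlywood", "latewood", "total"):
            raise ValueError(f"unknown wood fraction {kind!r}")
        return getattr(self, kind)

    def window(self, first: int, last: int) -> "SeasonalRingSeries":
        if first < self.first_year or last > self.last_year or first > last:
            raise ValueError(
                f"window [{first}, {last}] outside series span {self.span}"
            )
        i0, i1 = first - self.first_year, last - self.first_year + 1
        return SeasonalRingSeries(
            tree_id=self.tree_id,
            first_year=first,
            earlywood=self.earlywood[i0:i1],
            latewood=self.latewood[i0:i1],
            total=self.total[i0:i1],
            core_ids=list(self.core_ids),
            missing_flags=self.missing_flags[i0:i1],
        )


@dataclass
class SiteCollection:
    """Screened per-tree seasonal series for one site.

    ``reliable_span`` is the interval over which the chronology passes the
    EPS ≥ 0.85 reliability convention; ``chronology`` is the site mean
    index series when one has been built.
    """

    site_id: str
    trees: list[SeasonalRingSeries]
    reliable_span: tuple[int, int] | None = None
    chronology: IndexSeries | None = None

    def __post_init__(self) -> None:
        ids = [t.tree_id for t in self.trees]
        if len(set(ids)) != len(ids):
            raise ValueError("tree_ids must be unique within a site")
        if self.reliable_span is not None and self.trees:
            lo = min(t.first_year for t in self.trees)
            hi = max(t.last_year for t in self.trees)
            a, b = self.reliable_span
            if a < lo or b > hi or a > b:
                raise ValueError(
                    f"reliable_span {self.reliable_span} outside the union of "
                    f"tree spans [{lo}, {hi}]"
                )

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def span(self) -> tuple[int, int]:
        """Union of the tree spans."""
        if not self.trees:
            raise ValueError("empty collection has no span")
        return (
            min(t.first_year for t in self.trees),
            max(t.last_year for t in self.trees),
        )

    @property
    def common_span(self) -> tuple[int, int]:
        """Intersection of the tree spans (may be empty → ValueError)."""
        if not self.trees:
            raise ValueError("empty collection has no span")
        lo = max(t.first_year for t in self.trees)
        hi = min(t.last_year for t in self.trees)
        if lo > hi:
            raise ValueError("trees share no common span")
        return lo, hi

    def replace(self, **kwargs) -> "SiteCollection":
        return dataclasses.replace(self, **kwargs)
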