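"""Lag-tolerant concordance between the pointer-year method and the others.

The reference detectors see the delayed ring-width trough, so a PYM event
at year t counts as confirmed when the other method fires anywhere in
[t, t+4] (the default lag window).  Each span year contributes one cell of
a 2×2 contingency table:

====  =======================  =========================
cell  pointer-year method       other method
====  =======================  =========================
A     event                     matching event in window
B     event                     no match
C     no event                  unmatched event (own year)
D     no event                  no event
====  =======================  =========================

From the table: accuracy = (A+D)/N, sensitivity = A/(A+B), specificity =
D/(C+D); association is tested with Fisher's exact test and the p-values
of a family of tables are adjusted with the Benjamini–Yekutieli step-up
procedure (valid under arbitrary dependence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConfusionTable",
    "match_events",
    "confusion_metrics",
    "fisher_exact",
    "by_adjust",
]


@dataclass
class ConfusionTable:
    """2×2 year-level contingency counts and their derived rates."""

    A: int
    B: int
    C: int
    D: int

    def __post_init__(self) -> None:
        for name in "ABCD":
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be non-negative")

    @property
    def n(self) -> int:
        return self.A + self.B + self.C + self.D

    @property
    def acc(self) -> float:
        return (self.A + self.D) / self.n if self.n else math.nan

    @property
    def sens(self) -> float:
        return self.A / (self.A + self.B) if self.A + self.B else math.nan

    @property
    def spec(self) -> float:
        return self.D / (self.C + self.D) if self.C + self.D else math.nan

    def as_array(self) -> np.ndarray:
        return np.array([[self.A, self.B], [self.C, self.D]])


def match_events(
    pym_events,
    other_events,
    span: tuple[int, int],
    lag_window: tuple[int, int] = (0, 4),
) -> ConfusionTable:
    """Greedy earliest-first matching of PYM events to another method's.

    Each PYM event year t consumes the earliest unconsumed other-method
    event in [t + lag_window[0], t + lag_window[1]] (→ A) or counts as
    unconfirmed (→ B); leftover other-method events count at their own
    year (→ C); all remaining span years are D.
    """
    lo, hi = int(span[0]), int(span[1])
    if hi < lo:
        raise ValueError("empty span")
    pym = sorted(int(y) for y in pym_events)
    other = sorted(int(y) for y in other_events)
    for y in pym + other:
        if not lo <= y <= hi:
            raise ValueError(f"event year {y} outside span [{lo}, {hi}]")
    consumed = [False] * len(other)
    a = b = 0
    for t in pym:
        match = None
        for i, y in enumerate(other):
            if not consumed[i] and t + lag_window[0] <= y <= t + lag_window[1]:
                match = i
                break
        if match is None:
            b += 1
        else:
            consumed[match] = True
            a += 1
    c = consumed.count(False)
    n_years = hi - lo + 1
    d = n_years - a - b - c
    if d < 0:
        raise ValueError("span shorter than the number of event years")
    return ConfusionTable(a, b, c, d)


def confusion_metrics(table: ConfusionTable) -> dict[str, float]:
    """Accuracy, sensitivity and specificity (NaN where undefined)."""
    return {"acc": table.acc, "sens": table.sens, "spec": table.spec}


def fisher_exact(table: ConfusionTable | np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2×2 table (zero margin → p = 1)."""
    arr = table.as_array() if isinstance(table, ConfusionTable) else np.asarray(table)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        return 1.0
    return float(scipy.stats.fisher_exact(arr, alternative="two-sided")[1])


def by_adjust(p_values) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjusted p-values (capped at 1).

    Controls the false discovery rate under arbitrary dependence via the
    harmonic-sum factor c(m) = Σ 1/i.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]
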