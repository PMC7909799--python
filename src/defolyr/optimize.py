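"""Grid-search calibration of detector parameters against documented outbreaks.

Detector thresholds have no universal values — they depend on tree species,
insect species and damage intensity — so each stand's parameters are tuned
against independently documented outbreak windows (e.g. forest-service
records).  A detection "hits" a window when at least one event year falls
inside it or up to ``match_lead`` years before its first year (the ring
signal can precede the documented peak abundance); events hitting no
window are false positives.

Objectives:

* PYM / MWM / MICA — lexicographic: maximise windows hit, then minimise
  false positives, then prefer the most stringent thresholds (deterministic
  tie-break by grid order).
* OUTBREAK — maximise the mean flagged-tree proportion inside the windows,
  subject to all windows being hit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import (
    ICADetector,
    MovingWindowDetector,
    OutbreakDetector,
    PointerYearDetector,
)
from .detect.base import DetectionResult
from .series import SiteCollection

logger = logging.getLogger(__name__)

DETECTORS = {
    "pym": PointerYearDetector,
    "outbreak": OutbreakDetector,
    "mwm": MovingWindowDetector,
    "mica": ICADetector,
}

# sign of "more stringent" per parameter: +1 = larger is stricter
_STRINGENCY = {
    "change_l": +1, "sync_l": +1, "change_e": +1, "sync_e": +1,
    "width": +1, "perc": +1,
    "std": +1, "lng": +1, "abrupt": -1, "min_tree_prop": +1,
    "lim": -1, "q": -1, "rng": -1,
}


@dataclass
class ReferenceOutbreaks:
    """Documented outbreak windows used as calibration ground truth."""

    windows: list[tuple[int, int]]
    match_lead: int = 2

    def __post_init__(self) -> None:
        self.windows = sorted((int(a), int(b)) for a, b in self.windows)
        for (a, b) in self.windows:
            if a > b:
                raise ValueError(f"window [{a}, {b}] reversed")
        for (a1, b1), (a2, b2) in zip(self.windows, self.windows[1:]):
            if a2 <= b1:
                raise ValueError("reference windows overlap")


@dataclass
class GridScore:
    params: dict
    hits: int
    false_positives: int
    false_negatives: int
    events: list[int] = field(default_factory=list)
    objective: float | None = None


def score_params(
    detection: DetectionResult, reference: ReferenceOutbreaks
) -> tuple[int, int, int]:
    """(true positives, false negatives, false positives) for one detection.

    A window is hit when ≥ 1 event year lies in [first − match_lead, last];
    each event is credited to at most one window (earliest-first greedy).
    """
    events = sorted(detection.event_years)
    used = [False] * len(events)
    tp = 0
    for (a, b) in reference.windows:
        lo = a - reference.match_lead
        for i, y in enumerate(events):
            if not used[i] and lo <= y <= b:
                used[i] = True
                tp += 1
                break
    fn = len(reference.windows) - tp
    fp = sum(1 for u in used if not u)
    return tp, fn, fp


def _stringency_key(params: dict) -> tuple:
    return tuple(
        _STRINGENCY.get(k, 0) * float(v)
        for k, v in sorted(params.items())
        if isinstance(v, (int, float)) and k in _STRINGENCY
    )


def _outbreak_prop_in_windows(
    result: DetectionResult, reference: ReferenceOutbreaks
) -> float:
    """Mean flagged-tree proportion over the years inside reference windows."""
    if result.per_tree_flags is None:
        return 0.0
    flags = result.per_tree_flags
    vals = []
    for (a, b) in reference.windows:
        for y in range(a - reference.match_lead, b + 1):
            if y in flags.index:
                vals.append(flags.loc[y].mean())
    return float(np.mean(vals)) if vals else 0.0


def grid_search(
    method: str,
    collection: SiteCollection,
    reference: ReferenceOutbreaks,
    grid: dict[str, list],
    **fixed,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustively score every parameter combination in ``grid``.

    Returns the best parameter set and the full score table.  When no set
    hits every window, the best-effort set is returned with a warning.
    """
    if method not in DETECTORS:
        raise ValueError(f"unknown method {method!r}")
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must contain at least one value per parameter")
    keys = list(grid.keys())
    scores: list[GridScore] = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        det = DETECTORS[method](**params, **fixed)
        try:
            result = det.fit(collection).result_
        except (ValueError, RuntimeError) as exc:
            logger.warning("parameter set %s failed: %s", params, exc)
            continue
        tp, fn, fp = score_params(result, reference)
        gs = GridScore(params, tp, fp, fn, events=list(result.event_years))
        if method == "outbreak":
            gs.objective = _outbreak_prop_in_windows(result, reference)
        scores.append(gs)
    if not scores:
        raise RuntimeError("no parameter set could be evaluated")
    n_windows = len(reference.windows)
    if method == "outbreak":
        full = [s for s in scores if s.hits == n_windows]
        pool = full if full else scores
        if not full:
            logger.warning("no parameter set hits all windows; best effort returned")
        best = max(
            pool,
            key=lambda s: (s.hits, s.objective, _stringency_key(s.params)),
        )
    else:
        best = max(
            scores,
            key=lambda s: (s.hits, -s.false_positives, _stringency_key(s.params)),
        )
        if best.hits < n_windows:
            logger.warning("no parameter set hits all windows; best effort returned")
    table = pd.DataFrame(
        [
            {
                **s.params,
                "hits": s.hits,
                "false_positives": s.false_positives,
                "false_negatives": s.false_negatives,
                **({"mean_prop_in_windows": s.objective} if s.objective is not None else {}),
                "events": ",".join(map(str, s.events)),
            }
            for s in scores
        ]
    )
    return dict(best.params), table
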