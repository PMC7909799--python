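"""Synthetic multi-tree seasonal ring-width datasets with ground truth.

The generator emulates the statistical structure the detectors assume for
a mature even-aged Scots pine stand:

* a modified negative-exponential age trend (mm),
* a smooth stand-level growth factor shared by all trees (AR(1), high
  persistence) — the common signal that gives the chronology its EPS,
* a per-tree persistent factor (AR(1) with the target first-order
  autocorrelation ≈ 0.8) plus a small white measurement noise,
* a weak climate modulation built from the simulated monthly table,
* episodic defoliation: in each event year a Bernoulli subset of trees
  responds with a latewood decline the following year and an earlywood
  decline two years after (the seasonal signature of a late-summer
  defoliator), optionally with an extra total-width suppression in both
  years so that whole-ring detectors also see a lagged trough.

Each ring is split into earlywood/latewood at a 70/30 base ratio with a
small per-year jitter; the seasonal fractions always sum to the total.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ring_io
from .chronology import spline_detrend
from .series import SeasonalRingSeries, SiteCollection

logger = logging.getLogger(__name__)

#: south-Siberian forest-steppe climatology: annual mean 1.8 °C, July 19.6 °C
MEAN_ANNUAL_T = 1.8
JULY_T = 19.6


@dataclass
class SynthConfig:
    """Parameters of one simulated site.

    The defaults describe the baseline study conditions: 20 trees over
    100 years, per-tree first-order autocorrelation near 0.8, a common
    signal strong enough for EPS ≥ 0.85, and — when ``event_years`` is
    non-empty — defoliation events to which 70% of trees respond with a
    40% latewood and a 30% earlywood decline.
    """

    n_trees: int = 20
    n_years: int = 100
    first_year: int = 1914
    age_trend: tuple[float, float, float] = (1.5, 0.05, 0.55)  # a, b, k (mm)
    ar1: float = 0.8            # target lag-1 autocorr of detrended per-tree series
    tree_sd: float = 0.105      # stationary sd of the per-tree factor (log scale)
    stand_ar1: float = 0.99     # common stand factor, AR(1) phi (decadal-scale)
    stand_sd: float = 0.22      # stationary sd of the common factor (log scale)
    noise_sd: float = 0.01      # white multiplicative noise (log scale)
    climate_effects: tuple = ((5, "P", 0.004), (6, "P", 0.003), (7, "T", -0.004))
    ew_fraction: float = 0.7    # base earlywood share of the total width
    ew_jitter: float = 0.02     # per-year sd of the earlywood share
    event_years: tuple = ()
    responder_prob: float = 0.7
    latewood_drop: float = 0.4      # in year t+1
    earlywood_drop: float = 0.3     # in year t+2
    extra_width_suppression: float = 0.25  # whole-ring, years t+1..t+2
    missing_ring_prob: float = 0.0
    seed: int = 0
    site_id: str = "synthetic"

    def __post_init__(self) -> None:
        for name in ("responder_prob", "missing_ring_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("latewood_drop", "earlywood_drop", "extra_width_suppression"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.n_trees < 5:
            raise ValueError("n_trees must be >= 5")

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


def simulate_climate(
    n_years: int, seed: int = 0, start_year: int = 1914
) -> pd.DataFrame:
    """Monthly climate table with a continental seasonal cycle.

    Temperature follows a sine with annual mean 1.8 °C and July mean
    19.6 °C plus white noise; precipitation is lognormal per month.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    amp = JULY_T - MEAN_ANNUAL_T
    for y in range(start_year, start_year + n_years):
        for m in range(1, 13):
            t = MEAN_ANNUAL_T + amp * np.cos(2 * np.pi * (m - 7) / 12)
            t += rng.normal(0, 1.5)
            p = rng.lognormal(mean=np.log(35.0), sigma=0.5)
            rows.append(
                {"year": y, "month": m, "temperature": t, "precipitation": p}
            )
    return pd.DataFrame(rows)


def _ar1_series(rng, n, phi, sd) -> np.ndarray:
    """Stationary AR(1) with the given marginal sd."""
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    innov_sd = sd * np.sqrt(1 - phi**2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.normal(0, innov_sd)
    return x


def simulate_site(
    config: SynthConfig,
    climate: pd.DataFrame | None = None,
    verify_ar1: bool = False,
) -> tuple[SiteCollection, pd.DataFrame, dict]:
    """Generate one site, its climate table, and the ground truth.

    Returns ``(collection, climate, truth)`` where ``truth`` holds the
    event years, the responder tree ids per event, and the config echo.
    With ``verify_ar1`` the realized mean lag-1 autocorrelation of the
    detrended per-tree series is checked post hoc against ``config.ar1``
    (warning when off by more than 0.1).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    first, last = cfg.first_year, cfg.first_year + cfg.n_years - 1
    for e in cfg.event_years:
        if not first + 3 <= e <= last - 3:
            raise ValueError(
                f"event year {e} closer than 3 years to the span edges"
            )
    if climate is None:
        climate = simulate_climate(
            cfg.n_years, seed=rng.integers(2**31), start_year=first
        )
    years = np.arange(first, last + 1)

    # climate multiplier from z-scored monthly values of the growth year
    clim_mult = np.ones(cfg.n_years)
    piv = {
        "T": climate.pivot(index="year", columns="month", values="temperature"),
        "P": climate.pivot(index="year", columns="month", values="precipitation"),
    }
    for month, var, coef in cfg.climate_effects:
        col = piv[var].loc[years, month].to_numpy()
        z = (col - col.mean()) / col.std(ddof=1)
        clim_mult += coef * z
    clim_mult = np.clip(clim_mult, 0.1, None)

    t_idx = np.arange(cfg.n_years, dtype=float)
    a, b, k = cfg.age_trend
    age = a * np.exp(-b * t_idx) + k
    stand = _ar1_series(rng, cfg.n_years, cfg.stand_ar1, cfg.stand_sd)

    # per-event responder sets, redrawn independently per event
    responders: dict[int, list[str]] = {}
    tree_ids = [f"T{j + 1:02d}" for j in range(cfg.n_trees)]
    for e in sorted(cfg.event_years):
        mask = rng.random(cfg.n_trees) < cfg.responder_prob
        responders[int(e)] = [tid for tid, m in zip(tree_ids, mask) if m]

    # detrending whitens the series slightly, so the innovation phi sits
    # above the target lag-1 autocorrelation of the detrended index
    tree_phi = min(0.98, cfg.ar1 + 0.07)
    trees = []
    for j, tid in enumerate(tree_ids):
        tree_fac = _ar1_series(rng, cfg.n_years, tree_phi, cfg.tree_sd)
        noise = rng.normal(0, cfg.noise_sd, cfg.n_years)
        width = age * clim_mult * np.exp(stand + tree_fac + noise)
        frac = np.clip(
            cfg.ew_fraction + rng.normal(0, cfg.ew_jitter, cfg.n_years), 0.5, 0.9
        )
        ew = width * frac
        lw = width * (1 - frac)
        for e in sorted(cfg.event_years):
            if tid not in responders[e]:
                continue
            i1, i2 = e + 1 - first, e + 2 - first
            sup = 1 - cfg.extra_width_suppression
            ew[i1] *= sup
            lw[i1] *= sup
            ew[i2] *= sup
            lw[i2] *= sup
            lw[i1] *= 1 - cfg.latewood_drop
            ew[i2] *= 1 - cfg.earlywood_drop
        missing = rng.random(cfg.n_years) < cfg.missing_ring_prob
        ew[missing] = 0.0
        lw[missing] = 0.0
        trees.append(
            SeasonalRingSeries(
                tree_id=tid,
                core_ids=[tid + "a"],
                first_year=first,
                earlywood=ew,
                latewood=lw,
                total=ew + lw,
                missing_flags=missing,
            )
        )
    collection = SiteCollection(site_id=cfg.site_id, trees=trees)
    if verify_ar1:
        ac = realized_ar1(collection)
        if abs(ac - cfg.ar1) > 0.1:
            logger.warning(
                "realized detrended AR(1) %.3f deviates from the %.2f target",
                ac, cfg.ar1,
            )
    truth = {
        "site_id": cfg.site_id,
        "event_years": sorted(int(e) for e in cfg.event_years),
        "responders": responders,
        "config": _config_dict(cfg),
    }
    return collection, climate, truth


def _config_dict(cfg: SynthConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["age_trend"] = list(cfg.age_trend)
    d["climate_effects"] = [list(e) for e in cfg.climate_effects]
    d["event_years"] = [int(e) for e in cfg.event_years]
    return d


def realized_ar1(collection: SiteCollection, stiffness: float | None = None) -> float:
    """Mean lag-1 autocorrelation of the spline-detrended per-tree series."""
    acs = []
    for t in collection.trees:
        w = t.total.astype(float).copy()
        w[t.missing_flags] = np.nan
        idx = spline_detrend(w, stiffness=stiffness, first_year=t.first_year).values
        ok = np.isfinite(idx)
        v = idx[ok]
        if len(v) < 10:
            continue
        acs.append(np.corrcoef(v[:-1], v[1:])[0, 1])
    return float(np.mean(acs))


def write_fixture_suite(directory, seed: int = 0) -> dict:
    """Write the standard test fixtures to ``directory``.

    Emits a null site (no events), a single-event site, and a three-site
    scenario with 25/18/15 trees, each as Tucson files (one per wood
    fraction), a seasonal CSV, a climate CSV and a truth JSON.  Returns a
    manifest of the files written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    scenarios = {
        "null_site": SynthConfig(
            site_id="null_site", event_years=(), seed=int(rng.integers(2**31))
        ),
        "single_event": SynthConfig(
            site_id="single_event",
            event_years=(1964,),
            seed=int(rng.integers(2**31)),
        ),
    }
    for name, n_trees, events in (
        ("site_a", 25, (1959, 1996)),
        ("site_b", 18, (1949, 1996)),
        ("site_c", 15, (1959, 1995)),
    ):
        scenarios[name] = SynthConfig(
            site_id=name,
            n_trees=n_trees,
            event_years=events,
            seed=int(rng.integers(2**31)),
        )
    manifest: dict[str, list[str]] = {}
    for name, cfg in scenarios.items():
        collection, climate, truth = simulate_site(cfg)
        files = []
        for kind in ("total", "earlywood", "latewood"):
            path = directory / f"{name}_{kind}.rwl"
            raw = [
                ring_io.RawSeries(t.tree_id, t.first_year, t.fraction(kind))
                for t in collection.trees
            ]
            ring_io.write_rwl(path, raw)
            files.append(path.name)
        csv_path = directory / f"{name}_seasonal.csv"
        ring_io.write_seasonal_csv(csv_path, collection.trees)
        files.append(csv_path.name)
        clim_path = directory / f"{name}_climate.csv"
        ring_io.write_climate_csv(clim_path, climate)
        files.append(clim_path.name)
        truth_path = directory / f"{name}_truth.json"
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2)
        files.append(truth_path.name)
        manifest[name] = files
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
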