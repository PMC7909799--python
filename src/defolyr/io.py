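"""Readers and writers for ring-width and climate files.

Supported formats:

* Tucson ("RWL") decadal text format, the community interchange format for
  ring-width measurements — one file per wood fraction.  Both circulating
  dialects are accepted: stop marker ``999`` with widths in 0.01 mm, and
  stop marker ``-9999`` with widths in 0.001 mm; the unit is inferred from
  the marker.
* A long-format seasonal CSV with columns ``tree, core, year, earlywood,
  latewood`` (mm); total width is their sum.
* A monthly climate CSV with columns ``year, month, temperature,
  precipitation`` (°C monthly mean, mm monthly sum).

Missing (locally absent) rings are recorded as width 0 and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import SeasonalRingSeries

logger = logging.getLogger(__name__)

RWL_KINDS = ("total", "earlywood", "latewood")


class RwlParseError(ValueError):
    """Raised on a malformed Tucson decadal line; carries the line number."""


@dataclass
class RawSeries:
    """A single dated measurement series (one core, one wood fraction)."""

    series_id: str
    first_year: int
    widths: np.ndarray
    missing_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.missing_flags is None:
            self.missing_flags = self.widths == 0.0
        else:
            self.missing_flags = np.asarray(self.missing_flags, dtype=bool)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.widths))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1


def read_rwl(path, kind: str = "total") -> list[RawSeries]:
    """Read a Tucson decadal ring-width file into dated series in mm.

    ``kind`` is a label recorded by callers assembling seasonal series; the
    file layout is identical for every wood fraction.
    """
    if kind not in RWL_KINDS:
        raise ValueError(f"kind must be one of {RWL_KINDS}, got {kind!r}")
    first_years: dict[str, int] = {}
    values_by_id: dict[str, list[int]] = {}
    scale_by_id: dict[str, float] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) < 3:
                raise RwlParseError(
                    f"{path}: line {lineno}: expected 'id year values...', "
                    f"got {line.strip()!r}"
                )
            sid = tokens[0]
            try:
                year = int(tokens[1])
                values = [int(t) for t in tokens[2:]]
            except ValueError as exc:
                raise RwlParseError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from None
            if sid in scale_by_id:
                raise RwlParseError(
                    f"{path}: line {lineno}: duplicate series id {sid!r} "
                    "after its end-of-series marker"
                )
            if sid not in first_years:
                first_years[sid] = year
                values_by_id[sid] = []
                order.append(sid)
            vals = values_by_id[sid]
            expected = first_years[sid] + len(vals)
            if year != expected:
                raise RwlParseError(
                    f"{path}: line {lineno}: decade starts at {year}, "
                    f"expected {expected} for series {sid!r}"
                )
            for v in values:
                if v in (999, -9999):
                    scale_by_id[sid] = 100.0 if v == 999 else 1000.0
                    break
                vals.append(v)

    out: list[RawSeries] = []
    for sid in order:
        first, vals = first_years[sid], values_by_id[sid]
        scale = scale_by_id.get(sid)
        if scale is None:
            # no stop marker seen; default to the 0.01 mm dialect
            scale = 100.0
            logger.warning("series %r has no end-of-series marker", sid)
        if not vals:
            logger.warning("series %r is empty, skipped", sid)
            continue
        widths = np.array(vals, dtype=float) / scale
        if (widths < 0).any():
            raise RwlParseError(f"{path}: negative width in series {sid!r}")
        out.append(RawSeries(series_id=sid, first_year=first, widths=widths))
    return out


def write_rwl(path, series: list[RawSeries], sentinel: int = 999) -> None:
    """Write dated series to a Tucson decadal file.

    ``sentinel=999`` writes 0.01 mm units, ``sentinel=-9999`` 0.001 mm.
    """
    if sentinel not in (999, -9999):
        raise ValueError("sentinel must be 999 or -9999")
    scale = 100 if sentinel == 999 else 1000
    with open(path, "w") as fh:
        for s in series:
            vals = [int(round(w * scale)) for w in s.widths] + [sentinel]
            year = s.first_year
            i = 0
            while i < len(vals):
                # each record runs to the end of the calendar decade
                n = 10 - (year % 10)
                chunk = vals[i : i + n]
                fields = " ".join(f"{v:>6d}" for v in chunk)
                fh.write(f"{s.series_id:<8s}{year:>6d} {fields}\n")
                i += n
                year += n


def read_seasonal_csv(path) -> list[SeasonalRingSeries]:
    """Read a long-format seasonal table into per-core seasonal series.

    Expected columns: ``tree, core, year, earlywood, latewood`` (mm).
    Total width is computed as earlywood + latewood.  Years within a core
    must be strictly consecutive and unique; widths must be non-negative.
    """
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("seasonal CSV %s is empty", path)
        return []
    required = {"tree", "core", "year", "earlywood", "latewood"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df[["earlywood", "latewood"]].to_numpy() < 0).any():
        raise ValueError(f"{path}: negative width")
    out = []
    for (tree, core), grp in df.groupby(["tree", "core"], sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=int)
        if len(np.unique(years)) != len(years):
            raise ValueError(f"{path}: duplicate (core, year) row for core {core!r}")
        if len(years) > 1 and not (np.diff(years) == 1).all():
            raise ValueError(
                f"{path}: non-consecutive years within core {core!r}"
            )
        ew = grp["earlywood"].to_numpy(dtype=float)
        lw = grp["latewood"].to_numpy(dtype=float)
        missing_flags = None
        if "missing" in grp.columns:
            missing_flags = grp["missing"].to_numpy(dtype=bool)
        out.append(
            SeasonalRingSeries(
                tree_id=str(tree),
                core_ids=[str(core)],
                first_year=int(years[0]),
                earlywood=ew,
                latewood=lw,
                total=ew + lw,
                missing_flags=missing_flags,
            )
        )
    return out


def write_seasonal_csv(path, series: list[SeasonalRingSeries]) -> None:
    rows = []
    for s in series:
        core = s.core_ids[0] if s.core_ids else s.tree_id
        for i, year in enumerate(s.years):
            rows.append(
                {
                    "tree": s.tree_id,
                    "core": core,
                    "year": int(year),
                    "earlywood": s.earlywood[i],
                    "latewood": s.latewood[i],
                    "missing": bool(s.missing_flags[i]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def assemble_seasonal(
    earlywood: list[RawSeries], latewood: list[RawSeries]
) -> list[SeasonalRingSeries]:
    """Pair per-core earlywood and latewood series (by id) into seasonal ones."""
    lw_by_id = {s.series_id: s for s in latewood}
    out = []
    for ew in earlywood:
        if ew.series_id not in lw_by_id:
            raise ValueError(f"no latewood series for id {ew.series_id!r}")
        lw = lw_by_id[ew.series_id]
        if ew.first_year != lw.first_year or len(ew.widths) != len(lw.widths):
            raise ValueError(
                f"earlywood/latewood span mismatch for id {ew.series_id!r}"
            )
        out.append(
            SeasonalRingSeries(
                tree_id=ew.series_id,
                core_ids=[ew.series_id],
                first_year=ew.first_year,
                earlywood=ew.widths,
                latewood=lw.widths,
                total=ew.widths + lw.widths,
                missing_flags=ew.missing_flags & lw.missing_flags,
            )
        )
    return out


def average_cores_per_tree(cores: list[SeasonalRingSeries]) -> SeasonalRingSeries:
    """Average several cores from one tree into a single seasonal series.

    Earlywood and latewood are averaged per year over the cores covering
    that year (plain arithmetic mean); total is recomputed as their sum.
    A year is flagged missing only if every covering core is missing there.
    """
    if not cores:
        raise ValueError("no cores given")
    tree_ids = {c.tree_id for c in cores}
    if len(tree_ids) != 1:
        raise ValueError(f"cores belong to different trees: {sorted(tree_ids)}")
    if len(cores) == 1:
        c = cores[0]
        return SeasonalRingSeries(
            tree_id=c.tree_id,
            core_ids=list(c.core_ids),
            first_year=c.first_year,
            earlywood=c.earlywood.copy(),
            latewood=c.latewood.copy(),
            total=c.earlywood + c.latewood,
            missing_flags=c.missing_flags.copy(),
        )
    # cores must chain-overlap; averaging disjoint cores would concatenate
    # unrelated spans into one series
    spans = sorted((c.first_year, c.last_year) for c in cores)
    reach = spans[0][1]
    for a, b in spans[1:]:
        if a > reach:
            raise ValueError(
                "cores do not overlap; refusing to concatenate disjoint spans"
            )
        reach = max(reach, b)
    first = min(c.first_year for c in cores)
    last = max(c.last_year for c in cores)
    n = last - first + 1
    ew_sum = np.zeros(n)
    lw_sum = np.zeros(n)
    count = np.zeros(n)
    all_missing = np.ones(n, dtype=bool)
    for c in cores:
        i0 = c.first_year - first
        sl = slice(i0, i0 + len(c))
        ew_sum[sl] += c.earlywood
        lw_sum[sl] += c.latewood
        count[sl] += 1
        all_missing[sl] &= c.missing_flags
    ew = ew_sum / count
    lw = lw_sum / count
    core_ids = sorted({cid for c in cores for cid in c.core_ids})
    return SeasonalRingSeries(
        tree_id=cores[0].tree_id,
        core_ids=core_ids,
        first_year=first,
        earlywood=ew,
        latewood=lw,
        total=ew + lw,
        missing_flags=all_missing,
    )


def read_climate_csv(path) -> pd.DataFrame:
    """Read and validate a monthly climate table.

    Returns a DataFrame with columns ``year, month, temperature,
    precipitation`` — one row per (year, month), with no gaps inside the
    covered span.
    """
    df = pd.read_csv(path)
    return validate_climate(df)


def validate_climate(df: pd.DataFrame) -> pd.DataFrame:
    required = {"year", "month", "temperature", "precipitation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"climate table missing columns {sorted(missing)}")
    if df.duplicated(["year", "month"]).any():
        raise ValueError("climate table has duplicate (year, month) rows")
    if not df["month"].between(1, 12).all():
        raise ValueError("month outside 1..12")
    df = df.sort_values(["year", "month"]).reset_index(drop=True)
    y0, y1 = int(df["year"].min()), int(df["year"].max())
    # the first and last calendar year may be partial; interior years may not
    interior = df[(df["year"] > y0) & (df["year"] < y1)]
    n_interior_years = max(0, y1 - y0 - 1)
    if len(interior) != n_interior_years * 12:
        raise ValueError("climate table has gaps inside the covered span")
    return df


def write_climate_csv(path, df: pd.DataFrame) -> None:
    validate_climate(df).to_csv(path, index=False)
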