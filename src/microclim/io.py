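"""Reading and writing logger series and site metadata.

Canonical CSV dialect: header ``timestamp,temp_c,rh_pct``, ISO-8601
timestamps, UTF-8, comma separator. Other headers are adapted through a
``schema`` column mapping. Raw binary iButton mission logs are out of scope.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateTimestampError, ScheduleError, ValidationError
from .types import (
    DEFAULT_WINDOW,
    SCHEDULE_HOURS,
    LoggerSeries,
    SiteMeta,
    expected_slots,
    validate_site_links,
)

CANONICAL_COLUMNS = ("timestamp", "temp_c", "rh_pct")

#: tolerance for snapping off-schedule rows in lenient mode
SNAP_TOLERANCE = dt.timedelta(minutes=30)


def read_series(
    path: str | Path,
    schema: Optional[Mapping[str, str]] = None,
    *,
    strict: bool = True,
    window: tuple[dt.date, dt.date] = DEFAULT_WINDOW,
    site_id: Optional[str] = None,
) -> LoggerSeries:
    """Read one site's CSV into a validated :class:`LoggerSeries`.

    Parameters
    ----------
    schema : mapping of canonical name -> file column name, e.g.
        ``{"timestamp": "Date/Time", "temp_c": "Value", "rh_pct": "RH"}``.
        ``None`` assumes the canonical header.
    strict : reject off-schedule rows (default). In lenient mode rows within
        ±30 min of a schedule slot are snapped to it; others are dropped.
    """
    path = Path(path)
    colmap = dict(schema) if schema else {c: c for c in CANONICAL_COLUMNS}
    missing = set(CANONICAL_COLUMNS) - set(colmap)
    if missing:
        raise ValidationError(f"schema missing mappings for {sorted(missing)}")
    raw = pd.read_csv(path, usecols=list(colmap.values()))
    raw = raw.rename(columns={v: k for k, v in colmap.items()})

    ts = pd.to_datetime(raw["timestamp"], errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ValidationError(
            f"{path.name}: malformed timestamp at data row {row}: "
            f"{raw['timestamp'].iloc[row]!r}"
        )
    df = pd.DataFrame(
        {
            "temp_c": pd.to_numeric(raw["temp_c"], errors="raise"),
            "rh_pct": pd.to_numeric(raw["rh_pct"], errors="raise"),
        }
    )
    df.index = pd.DatetimeIndex(ts.values)

    rh = df["rh_pct"].to_numpy(float)
    if np.any(rh < 0) or np.any(rh > 100):
        row = int(np.flatnonzero((rh < 0) | (rh > 100))[0])
        raise ValidationError(
            f"{path.name}: relative humidity outside [0, 100] at data row {row}"
        )

    off = ~_on_schedule(df.index)
    if off.any():
        if strict:
            bad = df.index[off][0]
            raise ScheduleError(
                f"{path.name}: off-schedule record at {bad} (strict mode)"
            )
        df = _snap_lenient(df)

    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise DuplicateTimestampError(f"{path.name}: duplicate timestamp {dup}")
    df = df.sort_index()

    # restrict to window; rows outside are simply not part of the series
    dates = df.index.normalize()
    keep = (dates >= pd.Timestamp(window[0])) & (dates <= pd.Timestamp(window[1]))
    df = df.loc[keep]

    return LoggerSeries(site_id=site_id or path.stem, data=df, window=window)


def _on_schedule(idx: pd.DatetimeIndex) -> np.ndarray:
    return (
        np.isin(idx.hour, SCHEDULE_HOURS) & (idx.minute == 0) & (idx.second == 0)
    )


def _snap_lenient(df: pd.DataFrame) -> pd.DataFrame:
    """Snap timestamps within ±30 min of a schedule slot; drop the rest."""
    idx = df.index
    snapped = []
    keep = np.zeros(len(idx), bool)
    for i, ts in enumerate(idx):
        best = None
        for day_off in (-1, 0, 1):
            d = ts.date() + dt.timedelta(days=day_off)
            for h in SCHEDULE_HOURS:
                slot = dt.datetime.combine(d, dt.time(h))
                if abs(ts.to_pydatetime() - slot) <= SNAP_TOLERANCE:
                    best = slot
        if best is not None:
            snapped.append(best)
            keep[i] = True
    out = df.loc[keep].copy()
    out.index = pd.DatetimeIndex(snapped)
    return out[~out.index.duplicated(keep="first")]


def write_series(series: LoggerSeries, path: str | Path) -> None:
    """Write a series in the canonical dialect (round-trips bit-identically)."""
    df = series.data.copy()
    df.insert(0, "timestamp", df.index.strftime("%Y-%m-%dT%H:%M:%S"))
    df.to_csv(path, index=False)


def read_sites(path: str | Path) -> list[SiteMeta]:
    """Read ``sites.csv`` (columns site_id,sector,aspect,elevation_m,vegetation,
    setting,pair_id) and validate gap→stand links."""
    df = pd.read_csv(path, dtype={"site_id": str, "pair_id": str})
    required = {"site_id", "sector", "aspect", "elevation_m", "vegetation", "setting"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sites file missing columns: {sorted(missing)}")
    sites = []
    for row in df.itertuples(index=False):
        pair = getattr(row, "pair_id", None)
        if pair is not None and (pd.isna(pair) or pair == ""):
            pair = None
        sites.append(
            SiteMeta(
                site_id=row.site_id,
                sector=int(row.sector),
                aspect=row.aspect,
                elevation=float(row.elevation_m),
                vegetation=row.vegetation,
                setting=row.setting,
                pair_id=pair,
            )
        )
    validate_site_links(sites)
    return sites


def write_sites(sites: Sequence[SiteMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "sector": [s.sector for s in sites],
            "aspect": [s.aspect.value for s in sites],
            "elevation_m": [s.elevation for s in sites],
            "vegetation": [s.vegetation.value for s in sites],
            "setting": [s.setting.value for s in sites],
            "pair_id": [s.pair_id or "" for s in sites],
        }
    ).to_csv(path, index=False)


def clip_to_window(
    series: LoggerSeries, start: dt.date, end: dt.date
) -> LoggerSeries:
    """Retain records whose local date lies in [start, end]; update the window.

    Idempotent; an empty result is a valid (length-0) series.
    """
    if start > end:
        raise ValidationError("clip_to_window: start after end")
    dates = series.data.index.normalize()
    keep = (dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end))
    return LoggerSeries(
        site_id=series.site_id, data=series.data.loc[keep].copy(), window=(start, end)
    )


@dataclass(frozen=True)
class CompletenessReport:
    site_id: str
    fraction: float
    n_expected: int
    n_present: int
    missing: tuple = field(repr=False, default=())

    @property
    def complete(self) -> bool:
        return self.fraction == 1.0


def completeness(series: LoggerSeries) -> CompletenessReport:
    """Fraction of the window's 6-per-day slots actually present."""
    slots = expected_slots(series.window)
    present = series.data.index
    n_exp = len(slots)
    n_present = int(slots.isin(present).sum())
    missing = tuple(slots[~slots.isin(present)])
    frac = n_present / n_exp if n_exp else 0.0
    return CompletenessReport(
        site_id=series.site_id,
        fraction=frac,
        n_expected=n_exp,
        n_present=n_present,
        missing=missing,
    )


def filter_complete(
    network: Sequence[LoggerSeries], threshold: float = 1.0
) -> tuple[list[LoggerSeries], list[CompletenessReport]]:
    """Split a network into retained series (fraction ≥ threshold) and an
    exclusion log naming every dropped series with its completeness."""
    windows = {s.window for s in network}
    if len(windows) > 1:
        raise ValidationError("filter_complete: series have differing windows")
    retained, excluded = [], []
    for s in network:
        rep = completeness(s)
        if rep.fraction >= threshold:
            retained.append(s)
        else:
            excluded.append(rep)
    return retained, excluded
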