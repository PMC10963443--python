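"""Daily, monthly, quarterly and annual summaries and bioclimatic indices.

Derived from six-per-day recordings: mean annual temperature (MAT), mean
diurnal range (DRT, the BIO2 idea), and thermal continentality (BIO7,
warmest-month MMT minus coldest-month MMT). Daily extremes use only the six
recorded values — a known negative bias of DRT relative to continuous
sensing, shared with the source data.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, IncompleteYearError, ValidationError
from .types import LoggerSeries, SiteMeta

#: Southern-Hemisphere quarters: warmest = Dec–Feb, coldest = Jun–Aug.
WQ_MONTHS = (12, 1, 2)
CQ_MONTHS = (6, 7, 8)

DAILY_COLUMNS = ["t_mean", "t_min", "t_max", "drt", "rh_mean", "rh_min", "n_obs"]


def daily_summaries(series: LoggerSeries, min_obs: int = 6) -> pd.DataFrame:
    """Per-calendar-date summary of temperature and RH.

    Days with fewer than ``min_obs`` recordings are omitted. Min/max are taken
    over the available recordings only; nothing is interpolated.

    Returns a DataFrame indexed by date with columns
    ``t_mean, t_min, t_max, drt, rh_mean, rh_min, n_obs``.
    """
    df = series.data
    if df.empty:
        return pd.DataFrame(columns=DAILY_COLUMNS, index=pd.Index([], name="date"))
    g = df.groupby(df.index.date)
    out = pd.DataFrame(
        {
            "t_mean": g["temp_c"].mean(),
            "t_min": g["temp_c"].min(),
            "t_max": g["temp_c"].max(),
            "rh_mean": g["rh_pct"].mean(),
            "rh_min": g["rh_pct"].min(),
            "n_obs": g["temp_c"].size(),
        }
    )
    out["drt"] = out["t_max"] - out["t_min"]
    out = out[out["n_obs"] >= min_obs]
    out.index.name = "date"
    return out[DAILY_COLUMNS]


def monthly_means(daily: pd.DataFrame) -> pd.DataFrame:
    """Mean monthly temperature (MMT): unweighted mean of daily means per
    (year, month). Returns columns ``year, month, mmt, n_days``."""
    if daily.empty:
        raise ValidationError("monthly_means: no daily summaries")
    idx = pd.DatetimeIndex(daily.index)
    g = daily["t_mean"].groupby(
        [pd.Index(idx.year, name="year"), pd.Index(idx.month, name="month")]
    )
    out = g.mean().rename("mmt").reset_index()
    out["n_days"] = g.size().to_numpy()
    # chronological order
    out = out.sort_values(["year", "month"]).reset_index(drop=True)
    return out


def bio7_continentality(
    monthly: pd.DataFrame, strict: bool = False
) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """BIO7 thermal continentality: warmest-month MMT − coldest-month MMT.

    Ties are broken by the earliest month in the window. In strict mode a
    full 12-month record is required.

    Returns ``(bio7, (year, month) warmest, (year, month) coldest)``.
    """
    if len(monthly) < 2:
        raise ValidationError("bio7 needs at least two monthly means")
    if strict and len(monthly) < 12:
        raise IncompleteYearError(
            f"strict BIO7 requires 12 months, got {len(monthly)}"
        )
    mmt = monthly["mmt"].to_numpy(float)
    i_warm = int(np.argmax(mmt))  # argmax returns first (earliest) on ties
    i_cold = int(np.argmin(mmt))
    warm = (int(monthly["year"].iloc[i_warm]), int(monthly["month"].iloc[i_warm]))
    cold = (int(monthly["year"].iloc[i_cold]), int(monthly["month"].iloc[i_cold]))
    return float(mmt[i_warm] - mmt[i_cold]), warm, cold


def quarter_mask(dates: pd.DatetimeIndex, months: Sequence[int]) -> np.ndarray:
    return np.isin(dates.month, list(months))


@dataclass(frozen=True)
class BioclimSummary:
    """Per-site annual bioclimatic indices."""

    site_id: str
    mat: float        # °C, mean of daily means over the window
    bio7: float       # K
    warmest_month: tuple[int, int]
    coldest_month: tuple[int, int]
    mdt_annual: float
    mdt_wq: float
    mdt_cq: float
    drt_annual: float
    drt_wq: float
    drt_cq: float
    n_days: int


def bioclim_summary(series: LoggerSeries, min_obs: int = 6) -> BioclimSummary:
    """Annual indices for one series: MAT, BIO7, quarter MDT and DRT means.

    The warmest quarter pools December of the window's first year with
    January/February of its second (a single Dec–Feb quarter inside a
    one-year record); the coldest quarter is June–August.
    """
    daily = daily_summaries(series, min_obs=min_obs)
    if daily.empty:
        raise ValidationError(f"{series.site_id}: no complete days")
    monthly = monthly_means(daily)
    bio7, warm, cold = bio7_continentality(monthly)
    idx = pd.DatetimeIndex(daily.index)
    wq = quarter_mask(idx, WQ_MONTHS)
    cq = quarter_mask(idx, CQ_MONTHS)
    if not wq.any() or not cq.any():
        raise ValidationError(f"{series.site_id}: a quarter has zero days")
    return BioclimSummary(
        site_id=series.site_id,
        mat=float(daily["t_mean"].mean()),
        bio7=bio7,
        warmest_month=warm,
        coldest_month=cold,
        mdt_annual=float(daily["t_mean"].mean()),
        mdt_wq=float(daily["t_mean"][wq].mean()),
        mdt_cq=float(daily["t_mean"][cq].mean()),
        drt_annual=float(daily["drt"].mean()),
        drt_wq=float(daily["drt"][wq].mean()),
        drt_cq=float(daily["drt"][cq].mean()),
        n_days=int(len(daily)),
    )


def network_bioclim(
    network: Sequence[LoggerSeries], min_obs: int = 6
) -> pd.DataFrame:
    """One row of bioclim indices per site."""
    rows = []
    for s in network:
        b = bioclim_summary(s, min_obs=min_obs)
        rows.append(
            {
                "site_id": b.site_id,
                "mat": b.mat,
                "bio7": b.bio7,
                "warmest_month": f"{b.warmest_month[0]}-{b.warmest_month[1]:02d}",
                "coldest_month": f"{b.coldest_month[0]}-{b.coldest_month[1]:02d}",
                "mdt_annual": b.mdt_annual,
                "mdt_wq": b.mdt_wq,
                "mdt_cq": b.mdt_cq,
                "drt_annual": b.drt_annual,
                "drt_wq": b.drt_wq,
                "drt_cq": b.drt_cq,
                "n_days": b.n_days,
            }
        )
    return pd.DataFrame(rows).set_index("site_id")


def drt_day_matrix(
    network: Sequence[LoggerSeries],
    sites: Sequence[SiteMeta],
    min_obs: int = 6,
) -> pd.DataFrame:
    """Per-site, per-date DRT table, rows sorted by sector, aspect, elevation
    (the heat-strip ordering of the temporal-pattern figure)."""
    windows = {s.window for s in network}
    if len(windows) > 1:
        raise ValidationError("drt_day_matrix: series have differing windows")
    meta = {m.site_id: m for m in sites}
    order = sorted(
        [s for s in network if s.site_id in meta],
        key=lambda s: (
            meta[s.site_id].sector,
            meta[s.site_id].aspect.value,
            meta[s.site_id].elevation,
        ),
    )
    rows = {}
    for s in order:
        rows[s.site_id] = daily_summaries(s, min_obs=min_obs)["drt"]
    out = pd.DataFrame(rows).T
    out.index.name = "site_id"
    return out
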