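"""Saturation vapour pressure, VPD, and fire-risk day counting.

Saturation vapour pressure follows the Murray (1967) exponential form

    e_sat(T) = e0 * exp(a * T / (T + b))       [hPa, T in °C]

with the over-water constants a = 17.2693882, b = 237.3 °C, e0 = 6.1078 hPa,
used as a single continuous branch at all temperatures (an over-ice branch is
available behind a flag). VPD = e_sat * (1 - RH/100). The internal unit is
hPa throughout; kPa is accepted at interfaces with explicit conversion.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import TEMP_RANGE, LoggerSeries
from .aggregate import daily_summaries

HPA_PER_KPA = 10.0


@dataclass(frozen=True)
class VpdParams:
    a_water: float = 17.2693882
    b_water: float = 237.3   # °C
    e0: float = 6.1078       # hPa
    ice_branch: bool = False
    a_ice: float = 21.8745584
    b_ice: float = 265.5

    def __post_init__(self) -> None:
        if self.e0 <= 0 or self.b_water <= 0:
            raise ValidationError("VpdParams: e0 and b_water must be positive")


DEFAULT_VPD_PARAMS = VpdParams()


def vp_sat(t, params: VpdParams = DEFAULT_VPD_PARAMS):
    """Saturation vapour pressure (hPa) at air temperature t (°C).

    Strictly increasing in t; t must lie in the sensor-plausible range
    [-40, 60] °C. Accepts scalars or arrays.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < TEMP_RANGE[0]) or np.any(t_arr > TEMP_RANGE[1]):
        raise ValidationError(f"vp_sat: temperature outside {TEMP_RANGE} °C")
    if params.ice_branch:
        a = np.where(t_arr < 0.0, params.a_ice, params.a_water)
        b = np.where(t_arr < 0.0, params.b_ice, params.b_water)
    else:
        a, b = params.a_water, params.b_water
    out = params.e0 * np.exp(a * t_arr / (t_arr + b))
    return out if np.ndim(t) else float(out)


def vpd(t, rh, params: VpdParams = DEFAULT_VPD_PARAMS):
    """Vapour pressure deficit (hPa) = vp_sat(t) * (1 - rh/100).

    Zero exactly at RH = 100%; equals vp_sat at RH = 0%.
    """
    rh_arr = np.asarray(rh, dtype=float)
    if np.any(rh_arr < 0.0) or np.any(rh_arr > 100.0):
        raise ValidationError("vpd: relative humidity outside [0, 100] %")
    out = np.asarray(vp_sat(t, params)) * (1.0 - rh_arr / 100.0)
    return out if (np.ndim(t) or np.ndim(rh)) else float(out)


def daily_mean_vpd(
    series: LoggerSeries, params: VpdParams = DEFAULT_VPD_PARAMS, min_obs: int = 6
) -> pd.Series:
    """Per-day mean VPD (hPa), computed per recording *before* averaging.

    The order matters: vp_sat is convex in T, so VPD of daily means is not
    the daily mean of VPD.
    """
    df = series.data
    if df.empty:
        return pd.Series(dtype=float, name="vpd")
    v = vpd(df["temp_c"].to_numpy(), df["rh_pct"].to_numpy(), params)
    s = pd.Series(v, index=df.index)
    g = s.groupby(s.index.date)
    out = g.mean()[g.size() >= min_obs]
    out.name = "vpd"
    out.index.name = "date"
    return out


def annual_max_daily_vpd(daily_vpd: pd.Series) -> tuple[float, dt.date]:
    """Maximum of the daily-mean VPD over the window and its (earliest) date."""
    if len(daily_vpd) == 0:
        raise ValidationError("annual_max_daily_vpd: empty series")
    i = int(np.argmax(daily_vpd.to_numpy()))  # first index on ties
    return float(daily_vpd.iloc[i]), daily_vpd.index[i]


@dataclass(frozen=True)
class FireThreshold:
    """Empirical fire-ignition indicator: a day counts iff daily maximum
    temperature exceeds ``t_max_gt`` AND minimum RH falls below ``rh_min_lt``
    (both inequalities strict)."""

    t_max_gt: float = 25.0   # °C
    rh_min_lt: float = 25.0  # %

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t_max_gt) and np.isfinite(self.rh_min_lt)):
            raise ValidationError("FireThreshold values must be finite")


DEFAULT_FIRE_THRESHOLD = FireThreshold()


def fire_days(
    daily: pd.DataFrame, thr: FireThreshold = DEFAULT_FIRE_THRESHOLD
) -> tuple[int, list]:
    """Count days with t_max > threshold and rh_min < threshold (strict).

    ``daily`` is a daily_summaries frame (needs t_max and rh_min columns).
    Returns (count, flagged dates).
    """
    mask = (daily["t_max"].to_numpy() > thr.t_max_gt) & (
        daily["rh_min"].to_numpy() < thr.rh_min_lt
    )
    flagged = [d for d, m in zip(daily.index, mask) if m]
    return int(mask.sum()), flagged


def vpd50_exceedance(daily_vpd: pd.Series, threshold_kpa: float = 1.3) -> int:
    """Days whose daily-mean VPD exceeds a kPa threshold (e.g. the VPD_50 of
    1.3 kPa for temperate broadleaf/mixed forests, 2.3 kPa Mediterranean).

    The threshold is given in kPa and converted to the internal hPa unit.
    """
    if threshold_kpa <= 0:
        raise ValidationError("vpd50_exceedance: threshold must be positive")
    thr_hpa = threshold_kpa * HPA_PER_KPA
    return int((daily_vpd.to_numpy() > thr_hpa).sum())


def moisture_summary(
    series: LoggerSeries,
    params: VpdParams = DEFAULT_VPD_PARAMS,
    thr: FireThreshold = DEFAULT_FIRE_THRESHOLD,
    min_obs: int = 6,
) -> dict:
    """Per-site moisture indices: annual max of daily-mean VPD, fire days,
    and VPD_50 exceedance counts at 1.3 and 2.3 kPa."""
    dv = daily_mean_vpd(series, params, min_obs=min_obs)
    vmax, vdate = annual_max_daily_vpd(dv)
    daily = daily_summaries(series, min_obs=min_obs)
    n_fire, _ = fire_days(daily, thr)
    return {
        "site_id": series.site_id,
        "vpd_annual_max_of_daily_mean": vmax,
        "vpd_max_date": vdate,
        "fire_days": n_fire,
        "vpd50_days_13hpa": vpd50_exceedance(dv, 1.3),
        "vpd50_days_23hpa": vpd50_exceedance(dv, 2.3),
    }


def network_moisture(
    network: Sequence[LoggerSeries],
    params: VpdParams = DEFAULT_VPD_PARAMS,
    thr: FireThreshold = DEFAULT_FIRE_THRESHOLD,
    min_obs: int = 6,
) -> pd.DataFrame:
    rows = [moisture_summary(s, params, thr, min_obs) for s in network]
    return pd.DataFrame(rows).set_index("site_id")
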