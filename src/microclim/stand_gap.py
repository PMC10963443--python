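"""Stand-gap microclimate contrasts.

Pairs each canopy-gap logger with its forest-stand counterpart and
quantifies the diurnal temperature contrast by recording hour within the
warmest/coldest month, plus daily DRT differences. Differences follow the
interior-climate convention: diurnal profiles report gap - stand, the DRT
contrast reports stand - gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .aggregate import daily_summaries, monthly_means
from .errors import ValidationError
from .group_stats import paired_t_test
from .io import completeness
from .types import SCHEDULE_HOURS, LoggerSeries, Setting, SiteMeta

MIN_DAYS = 20  # a month must contribute at least this many shared days


@dataclass(frozen=True)
class StandGapPair:
    stand: LoggerSeries
    gap: LoggerSeries
    vegetation: str

    def __post_init__(self) -> None:
        if self.stand.window != self.gap.window:
            raise ValidationError(
                f"pair {self.stand.site_id}/{self.gap.site_id}: windows differ"
            )


def make_pairs(
    sites: Sequence[SiteMeta],
    series_by_id: dict,
    completeness_threshold: float = 1.0,
) -> tuple[list[StandGapPair], list[str]]:
    """Resolve gap→stand links into pairs; log every exclusion.

    Only pairs where both members pass the completeness threshold are kept.
    A gap whose stand is missing or excluded is logged, not fatal; a
    vegetation mismatch is a validation error.
    """
    meta = {m.site_id: m for m in sites}
    pairs, log = [], []
    for m in sites:
        if m.setting is not Setting.gap:
            continue
        if m.pair_id is None:
            log.append(f"gap {m.site_id}: no pair_id")
            continue
        partner = meta.get(m.pair_id)
        if partner is None:
            log.append(f"gap {m.site_id}: pair_id {m.pair_id} not in site table")
            continue
        if partner.vegetation is not m.vegetation:
            raise ValidationError(
                f"gap {m.site_id}: vegetation mismatch with stand {m.pair_id}"
            )
        gap_s = series_by_id.get(m.site_id)
        stand_s = series_by_id.get(m.pair_id)
        if gap_s is None or stand_s is None:
            log.append(f"gap {m.site_id}: series missing for gap or stand")
            continue
        ok = True
        for s in (gap_s, stand_s):
            frac = completeness(s).fraction
            if frac < completeness_threshold:
                log.append(
                    f"pair {m.pair_id}/{m.site_id}: {s.site_id} completeness "
                    f"{frac:.4f} below threshold"
                )
                ok = False
        if ok:
            pairs.append(
                StandGapPair(stand=stand_s, gap=gap_s, vegetation=m.vegetation.value)
            )
    return pairs, log


def warmest_coldest_months(
    series: LoggerSeries, min_obs: int = 6
) -> tuple[tuple[int, int], tuple[int, int]]:
    """(year, month) of the highest and lowest MMT; ties go to the earliest."""
    monthly = monthly_means(daily_summaries(series, min_obs=min_obs))
    mmt = monthly["mmt"].to_numpy()
    iw, ic = int(np.argmax(mmt)), int(np.argmin(mmt))
    return (
        (int(monthly["year"].iloc[iw]), int(monthly["month"].iloc[iw])),
        (int(monthly["year"].iloc[ic]), int(monthly["month"].iloc[ic])),
    )


MonthSelector = Union[str, tuple]


def _resolve_month(pair: StandGapPair, month: MonthSelector) -> tuple[int, int]:
    if month == "warmest":
        return warmest_coldest_months(pair.stand)[0]
    if month == "coldest":
        return warmest_coldest_months(pair.stand)[1]
    y, m = month
    return int(y), int(m)


def _month_frame(series: LoggerSeries, ym: tuple[int, int]) -> pd.DataFrame:
    idx = series.data.index
    mask = (idx.year == ym[0]) & (idx.month == ym[1])
    return series.data.loc[mask]


def diurnal_profile(pair: StandGapPair, month: MonthSelector = "warmest") -> pd.DataFrame:
    """Per-recording-hour stand/gap means and day-matched paired t-tests.

    ``month`` is 'warmest', 'coldest' (site-specific, judged on the stand
    series) or an explicit (year, month). Returns one row per schedule hour:
    ``stand_mean, gap_mean, diff`` (gap - stand, K), ``t, p, p_holm, n_days``.
    Raw p mirrors the unadjusted reporting convention; the Holm column is
    provided alongside.
    """
    ym = _resolve_month(pair, month)
    stand = _month_frame(pair.stand, ym)
    gap = _month_frame(pair.gap, ym)
    rows = []
    pvals = []
    for h in SCHEDULE_HOURS:
        s = stand.loc[stand.index.hour == h, "temp_c"]
        g = gap.loc[gap.index.hour == h, "temp_c"]
        merged = pd.concat(
            [s.rename("stand"), g.rename("gap")], axis=1, join="inner"
        ).dropna()
        if len(merged) < MIN_DAYS:
            raise ValidationError(
                f"diurnal_profile: only {len(merged)} shared days at "
                f"{h:02d}:00 in {ym[0]}-{ym[1]:02d} (need >= {MIN_DAYS})"
            )
        try:
            res = paired_t_test(merged["stand"], merged["gap"])
            t, p = res.t, res.p
        except Exception:
            t, p = 0.0, 1.0
        rows.append(
            {
                "hour": h,
                "stand_mean": float(merged["stand"].mean()),
                "gap_mean": float(merged["gap"].mean()),
                "diff": float((merged["gap"] - merged["stand"]).mean()),
                "t": t,
                "p": p,
                "n_days": len(merged),
            }
        )
        pvals.append(p)
    out = pd.DataFrame(rows).set_index("hour")
    out["p_holm"] = multipletests(pvals, method="holm")[1]
    out.attrs["month"] = ym
    return out


def stand_gap_drt(
    pair: StandGapPair, month: Optional[MonthSelector] = None, min_obs: int = 6
) -> tuple[pd.Series, Optional[dict]]:
    """Daily DRT difference (stand - gap) and a paired-test summary.

    With ``month=None`` the whole shared window is used and no test summary
    is computed for a specific month; with 'warmest'/'coldest'/(year, month)
    the series is restricted to that month and summarised.
    """
    d_stand = daily_summaries(pair.stand, min_obs=min_obs)["drt"]
    d_gap = daily_summaries(pair.gap, min_obs=min_obs)["drt"]
    merged = pd.concat(
        [d_stand.rename("stand"), d_gap.rename("gap")], axis=1, join="inner"
    ).dropna()
    if month is not None:
        ym = _resolve_month(pair, month)
        idx = pd.DatetimeIndex(merged.index)
        merged = merged[(idx.year == ym[0]) & (idx.month == ym[1])]
        if len(merged) < MIN_DAYS:
            raise ValidationError(
                f"stand_gap_drt: only {len(merged)} shared days in "
                f"{ym[0]}-{ym[1]:02d}"
            )
    diff = (merged["stand"] - merged["gap"]).rename("drt_diff")
    summary = None
    if month is not None and len(diff) >= 3:
        try:
            res = paired_t_test(merged["gap"], merged["stand"])
            summary = {
                "month": ym,
                "mean_diff": float(diff.mean()),
                "t": res.t,
                "p": res.p,
                "n_days": res.n,
            }
        except Exception:
            summary = {
                "month": ym,
                "mean_diff": float(diff.mean()),
                "t": 0.0,
                "p": 1.0,
                "n_days": len(diff),
            }
    return diff, summary
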