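"""Core domain types: site metadata, sensor specs, and logger time series.

Timestamps are naive local civil time (ART, UTC-3; no DST applies in the
study region), because the recording schedule is defined by six fixed local
clock hours. No timezone arithmetic is ever performed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateTimestampError, ScheduleError, ValidationError

#: The six fixed recording hours (local civil time).
SCHEDULE_HOURS: tuple[int, ...] = (2, 6, 10, 14, 18, 22)

#: Default one-year analysis window.
DEFAULT_WINDOW: tuple[dt.date, dt.date] = (dt.date(2022, 3, 1), dt.date(2023, 2, 28))

TEMP_RANGE = (-40.0, 60.0)
RH_RANGE = (0.0, 100.0)


class Aspect(str, Enum):
    """Slope aspect: N (north-facing, sun-exposed in the Southern Hemisphere),
    S (south-facing), V (valley bottom)."""

    N = "N"
    S = "S"
    V = "V"


class Vegetation(str, Enum):
    """The four vegetation types of the study design."""

    AusChil = "AusChil"  # Austrocedrus chilensis dry forest
    NotDomb = "NotDomb"  # Nothofagus dombeyi mesic forest
    NotAnta = "NotAnta"  # Nothofagus antarctica post-fire shrubland
    NotPumi = "NotPumi"  # Nothofagus pumilio subalpine deciduous forest


class Setting(str, Enum):
    stand = "stand"
    gap = "gap"


@dataclass(frozen=True)
class SensorSpec:
    """Resolution/accuracy of the hygrochron logger (iButton DS1923 class)."""

    t_resolution: float = 0.0625  # K, 16-bit temperature channel
    rh_resolution: float = 0.6    # %RH, 8-bit humidity channel
    t_accuracy: float = 0.5       # K
    rh_accuracy: float = 5.0      # %RH

    def __post_init__(self) -> None:
        for name in ("t_resolution", "rh_resolution", "t_accuracy", "rh_accuracy"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"SensorSpec.{name} must be strictly positive")


@dataclass(frozen=True)
class SiteMeta:
    """Descriptors of one measurement location."""

    site_id: str
    sector: int              # 1 (west) .. 4 (east)
    aspect: Aspect
    elevation: float         # m a.s.l.
    vegetation: Vegetation
    setting: Setting = Setting.stand
    pair_id: Optional[str] = None  # for a gap: site_id of its stand partner

    def __post_init__(self) -> None:
        if self.sector not in (1, 2, 3, 4):
            raise ValidationError(f"sector must be 1..4, got {self.sector}")
        if not 0.0 <= self.elevation <= 4000.0:
            raise ValidationError(
                f"elevation {self.elevation} m outside [0, 4000] for {self.site_id}"
            )
        # coerce plain strings for convenience
        object.__setattr__(self, "aspect", Aspect(self.aspect))
        object.__setattr__(self, "vegetation", Vegetation(self.vegetation))
        object.__setattr__(self, "setting", Setting(self.setting))


def validate_site_links(sites: Sequence[SiteMeta]) -> None:
    """Check that every gap's pair_id resolves to a stand of the same vegetation."""
    by_id = {s.site_id: s for s in sites}
    for s in sites:
        if s.setting is Setting.gap and s.pair_id is not None:
            partner = by_id.get(s.pair_id)
            if partner is None:
                raise ValidationError(
                    f"gap {s.site_id}: pair_id {s.pair_id!r} does not resolve"
                )
            if partner.setting is not Setting.stand:
                raise ValidationError(
                    f"gap {s.site_id}: partner {s.pair_id} is not a stand"
                )
            if partner.vegetation is not s.vegetation:
                raise ValidationError(
                    f"gap {s.site_id}: vegetation {s.vegetation.value} does not "
                    f"match stand {partner.site_id} ({partner.vegetation.value})"
                )


@dataclass
class LoggerSeries:
    """One site's time-ordered (timestamp, temperature, RH) recordings.

    ``data`` is a DataFrame with a naive DatetimeIndex and columns
    ``temp_c`` (°C) and ``rh_pct`` (%), restricted to the six schedule hours.
    """

    site_id: str
    data: pd.DataFrame
    window: tuple[dt.date, dt.date] = field(default=DEFAULT_WINDOW)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        df = self.data
        if list(df.columns[:2]) != ["temp_c", "rh_pct"]:
            df = df[["temp_c", "rh_pct"]]
            self.data = df
        idx = df.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValidationError(f"{self.site_id}: index must be a DatetimeIndex")
        if idx.tz is not None:
            raise ValidationError(f"{self.site_id}: timestamps must be naive local time")
        if len(idx) > 0:
            if idx.has_duplicates:
                dup = idx[idx.duplicated()][0]
                raise DuplicateTimestampError(f"{self.site_id}: duplicate timestamp {dup}")
            if not idx.is_monotonic_increasing:
                raise ValidationError(f"{self.site_id}: timestamps not strictly increasing")
            bad_hours = set(np.unique(idx.hour)) - set(SCHEDULE_HOURS)
            if bad_hours or (idx.minute != 0).any() or (idx.second != 0).any():
                raise ScheduleError(
                    f"{self.site_id}: records off the fixed schedule "
                    f"(hours {sorted(SCHEDULE_HOURS)}, minute=second=0)"
                )
            t = df["temp_c"].to_numpy(float)
            rh = df["rh_pct"].to_numpy(float)
            if np.any(t < TEMP_RANGE[0]) or np.any(t > TEMP_RANGE[1]):
                raise ValidationError(f"{self.site_id}: temperature outside {TEMP_RANGE}")
            if np.any(rh < RH_RANGE[0]) or np.any(rh > RH_RANGE[1]):
                raise ValidationError(f"{self.site_id}: RH outside {RH_RANGE}")
        start, end = self.window
        if start > end:
            raise ValidationError(f"{self.site_id}: window start after end")
        if len(idx) > 0:
            dates = idx.date
            if dates.min() < start or dates.max() > end:
                raise ValidationError(
                    f"{self.site_id}: records outside window {start}..{end}"
                )

    # -- convenience --------------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def n_days(self) -> int:
        """Number of calendar days in the window (inclusive)."""
        return (self.window[1] - self.window[0]).days + 1

    @classmethod
    def from_records(
        cls,
        site_id: str,
        records: Iterable[tuple[dt.datetime, float, float]],
        window: tuple[dt.date, dt.date] = DEFAULT_WINDOW,
    ) -> "LoggerSeries":
        rows = list(records)
        idx = pd.DatetimeIndex([r[0] for r in rows])
        df = pd.DataFrame(
            {"temp_c": [r[1] for r in rows], "rh_pct": [r[2] for r in rows]}, index=idx
        )
        return cls(site_id=site_id, data=df, window=window)


def expected_slots(window: tuple[dt.date, dt.date]) -> pd.DatetimeIndex:
    """All schedule timestamps between window start and end, inclusive."""
    days = pd.date_range(window[0], window[1], freq="D")
    stamps = days.values[:, None] + np.array(
        [np.timedelta64(h, "h") for h in SCHEDULE_HOURS]
    )
    return pd.DatetimeIndex(stamps.ravel())
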