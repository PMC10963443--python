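"""Synthetic logger-network generator with full ground truth.

Emulates the statistical structure of a mountain-forest logger campaign:
a west-east continentality gradient over four sectors, a linear elevational
lapse, warmer north-facing slopes (Southern Hemisphere), vegetation- and
canopy-dependent diurnal amplitude (gaps exceed stands), a Southern-
Hemisphere seasonal cycle, day-to-day synoptic weather (AR(1) anomalies),
relative humidity anticorrelated with temperature, and hygrochron sensor
quantization (0.0625 K / 0.6 %RH).

Deterministic temperature model for site s at day-of-year d and hour h:

    T = base(sector) + lapse*(z - z_ref)/100 + aspect(z)
        + A_season(sector) * cos(2*pi*(d - phase)/365)
        + A_diurnal(veg, setting) * f_sector * cos(2*pi*(h - 14)/24)

plus an AR(1) day anomaly and iid recording noise. RH is generated
conditionally on the temperature deviation from the site's deterministic
seasonal mean, so VPD inherits a realistic T-RH anticorrelation.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .types import (
    DEFAULT_WINDOW,
    SCHEDULE_HOURS,
    Aspect,
    LoggerSeries,
    SensorSpec,
    Setting,
    SiteMeta,
    Vegetation,
    expected_slots,
)

#: cosine values of the diurnal term at the six schedule hours (peak 14:00);
#: they sum to zero, so the diurnal term never biases daily means.
_DIURNAL_COS = {h: np.cos(2 * np.pi * (h - 14) / 24.0) for h in SCHEDULE_HOURS}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative parameterisation. The defaults are the study
    conditions: a 365-day window, lapse -0.47 K/100 m, four sectors of
    increasing continentality west→east, and vegetation niches matching the
    campaign's elevation bands."""

    seed: int = 0
    window: tuple[dt.date, dt.date] = DEFAULT_WINDOW
    sites: tuple[SiteMeta, ...] = ()
    lapse: float = -0.47                      # K per 100 m
    reference_elevation: float = 1000.0       # m
    sector_baseline: tuple[float, ...] = (7.0, 7.2, 7.4, 7.6)   # °C MAT at ref
    sector_seasonal_amplitude: tuple[float, ...] = (6.0, 7.4, 7.5, 7.6)  # K
    seasonal_amplitude_lapse: float = -0.0013  # K of amplitude per m elevation
    aspect_offset: float = 0.54               # K, N minus S at ref elevation
    aspect_offset_decay: float = -0.0004      # K per m of elevation
    diurnal_amplitude: dict = field(
        default_factory=lambda: {
            "AusChil": 5.6,
            "NotDomb": 4.85,
            "NotAnta": 6.4,
            "NotPumi": 4.45,
        }
    )
    gap_extra_amplitude: float = 2.5          # K added to a gap's amplitude
    sector_diurnal_factor: tuple[float, ...] = (0.90, 0.97, 1.03, 1.10)
    seasonal_phase: int = 15                  # day of year of maximum (mid-Jan)
    rh_base: tuple[float, ...] = (61.0, 58.0, 55.0, 52.0)  # % per sector
    rh_veg_offset: dict = field(
        default_factory=lambda: {"NotDomb": -7.0, "NotAnta": -8.0, "NotPumi": -9.0}
    )
    rh_temp_slope: float = -3.0               # % per K
    noise_sd_t: float = 0.3                   # K per recording
    noise_sd_rh: float = 3.0                  # % per recording
    synoptic_sd: float = 3.0                  # K, day-level AR(1) anomaly
    synoptic_rho: float = 0.6
    quantize: Optional[SensorSpec] = field(default_factory=SensorSpec)
    missingness: float = 0.0                  # fraction of slots dropped

    def __post_init__(self) -> None:
        if len(self.sector_baseline) != 4 or len(self.sector_seasonal_amplitude) != 4:
            raise ConfigError("sector parameter tuples must have length 4")
        if any(a < 0 for a in self.sector_seasonal_amplitude):
            raise ConfigError("seasonal amplitudes must be >= 0")
        if any(a < 0 for a in self.diurnal_amplitude.values()):
            raise ConfigError("diurnal amplitudes must be >= 0")
        if not 0.0 <= self.missingness < 1.0:
            raise ConfigError("missingness must be in [0, 1)")
        if not -1.0 < self.synoptic_rho < 1.0:
            raise ConfigError("synoptic_rho must be in (-1, 1)")


# ---------------------------------------------------------------------------
# default study layout
# ---------------------------------------------------------------------------

#: (vegetation, sector, aspect, elevations): 37 stands mirroring the
#: campaign counts and bands (AusChil 6 @ 600-890, NotDomb 7 @ 500-1000,
#: NotAnta 9 @ 900-1300, NotPumi 15 @ 1100-1600) over 8 transects.
#: Aspect/elevation placements are balanced so the pooled deterministic
#: MAT-elevation regression of the layout recovers the configured lapse.
_STAND_LAYOUT = [
    ("NotDomb", 1, "N", (500, 600, 800)),
    ("NotPumi", 1, "N", (1100, 1400, 1600)),
    ("NotDomb", 1, "S", (600, 900)),
    ("NotPumi", 1, "S", (1100, 1300, 1500)),
    ("NotDomb", 2, "S", (700, 1000)),
    ("NotAnta", 2, "S", (1000,)),
    ("NotPumi", 2, "S", (1200, 1400)),
    ("NotAnta", 2, "N", (900, 1100)),
    ("NotPumi", 2, "N", (1300, 1500)),
    ("AusChil", 3, "N", (600, 800)),
    ("NotAnta", 3, "N", (1000, 1200)),
    ("NotPumi", 3, "N", (1400,)),
    ("AusChil", 3, "S", (700,)),
    ("NotAnta", 3, "S", (1000, 1300)),
    ("NotPumi", 3, "S", (1500,)),
    ("AusChil", 4, "N", (650, 890)),
    ("NotAnta", 4, "N", (1000, 1300)),
    ("NotPumi", 4, "N", (1400, 1600)),
    ("AusChil", 4, "S", (600,)),
    ("NotPumi", 4, "S", (1300,)),
]

#: gap loggers paired to stands (vegetation inherited from the stand)
_GAP_LAYOUT = [
    ("AusChil", 3, "N", 600),
    ("NotDomb", 1, "N", 800),
    ("NotPumi", 1, "N", 1400),
]


def default_sites() -> tuple[SiteMeta, ...]:
    sites = []
    for veg, sector, aspect, elevs in _STAND_LAYOUT:
        for z in elevs:
            sites.append(
                SiteMeta(
                    site_id=f"{veg}_s{sector}{aspect}_{z}",
                    sector=sector,
                    aspect=aspect,
                    elevation=float(z),
                    vegetation=veg,
                    setting="stand",
                )
            )
    for veg, sector, aspect, z in _GAP_LAYOUT:
        stand_id = f"{veg}_s{sector}{aspect}_{z}"
        sites.append(
            SiteMeta(
                site_id=f"{stand_id}_gap",
                sector=sector,
                aspect=aspect,
                elevation=float(z),
                vegetation=veg,
                setting="gap",
                pair_id=stand_id,
            )
        )
    return tuple(sites)


def default_study_config(seed: int = 0) -> SyntheticConfig:
    """The study-layout configuration: 40 sites (37 stands + 3 gaps) over
    4 sectors x 2 aspects, elevations 500-1600 m."""
    return SyntheticConfig(seed=seed, sites=default_sites())


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTruth:
    """Exact expectations implied by a config (noise-free components)."""

    expected_mat: dict
    expected_bio7: dict
    expected_drt: dict
    deterministic_temperature: Callable = field(repr=False, default=None)


def _site_terms(cfg: SyntheticConfig, m: SiteMeta) -> dict:
    s = m.sector - 1
    base = cfg.sector_baseline[s]
    lapse_term = cfg.lapse * (m.elevation - cfg.reference_elevation) / 100.0
    off = max(
        0.0,
        cfg.aspect_offset
        + cfg.aspect_offset_decay * (m.elevation - cfg.reference_elevation),
    )
    aspect_term = {Aspect.N: off / 2.0, Aspect.S: -off / 2.0, Aspect.V: 0.0}[m.aspect]
    amp_d = cfg.diurnal_amplitude[m.vegetation.value] * cfg.sector_diurnal_factor[s]
    if m.setting is Setting.gap:
        amp_d += cfg.gap_extra_amplitude
    amp_season = max(
        0.0,
        cfg.sector_seasonal_amplitude[s]
        + cfg.seasonal_amplitude_lapse * (m.elevation - cfg.reference_elevation),
    )
    return {
        "const": base + lapse_term + aspect_term,
        "amp_season": amp_season,
        "amp_diurnal": amp_d,
        "rh_base": cfg.rh_base[s] + cfg.rh_veg_offset.get(m.vegetation.value, 0.0),
    }


def _deterministic_temp(
    cfg: SyntheticConfig, m: SiteMeta, timestamps: pd.DatetimeIndex
) -> np.ndarray:
    terms = _site_terms(cfg, m)
    doy = timestamps.dayofyear.to_numpy()
    hour = timestamps.hour.to_numpy()
    seasonal = terms["amp_season"] * np.cos(
        2 * np.pi * (doy - cfg.seasonal_phase) / 365.0
    )
    diurnal = terms["amp_diurnal"] * np.cos(2 * np.pi * (hour - 14) / 24.0)
    return terms["const"] + seasonal + diurnal


def generate(
    cfg: SyntheticConfig,
) -> tuple[list[LoggerSeries], list[SiteMeta], SyntheticTruth]:
    """Generate the network. Fully determined by ``cfg.seed``."""
    if not cfg.sites:
        raise ConfigError("generate: config has no sites")
    rng = np.random.default_rng(cfg.seed)
    slots = expected_slots(cfg.window)
    n_days = (cfg.window[1] - cfg.window[0]).days + 1
    day_index = np.repeat(np.arange(n_days), len(SCHEDULE_HOURS))

    # Shared regional weather: one AR(1) day-anomaly series for the whole
    # network (all sites experience the same synoptic situation), with
    # stationary marginal sd = synoptic_sd.
    eps = rng.standard_normal(n_days)
    anom = np.empty(n_days)
    anom[0] = eps[0]
    c = np.sqrt(1.0 - cfg.synoptic_rho**2)
    for d in range(1, n_days):
        anom[d] = cfg.synoptic_rho * anom[d - 1] + c * eps[d]
    if n_days > 1:
        anom -= anom.mean()  # weather varies within the year, not the climate
    anom *= cfg.synoptic_sd

    series_list: list[LoggerSeries] = []
    for m in cfg.sites:
        terms = _site_terms(cfg, m)
        det = _deterministic_temp(cfg, m, slots)
        t = det + anom[day_index]
        if cfg.noise_sd_t > 0:
            t = t + cfg.noise_sd_t * rng.standard_normal(len(slots))
        else:
            rng.standard_normal(len(slots))

        seasonal_mean = det - terms["amp_diurnal"] * np.cos(
            2 * np.pi * (slots.hour.to_numpy() - 14) / 24.0
        )
        rh = terms["rh_base"] + cfg.rh_temp_slope * (t - seasonal_mean)
        if cfg.noise_sd_rh > 0:
            rh = rh + cfg.noise_sd_rh * rng.standard_normal(len(slots))
        else:
            rng.standard_normal(len(slots))
        rh = np.clip(rh, 2.0, 100.0)

        if cfg.quantize is not None:
            t = np.round(t / cfg.quantize.t_resolution) * cfg.quantize.t_resolution
            rh = np.round(rh / cfg.quantize.rh_resolution) * cfg.quantize.rh_resolution
            rh = np.clip(rh, 0.0, 100.0)

        df = pd.DataFrame({"temp_c": t, "rh_pct": rh}, index=slots)
        keep_mask = np.ones(len(slots), bool)
        if cfg.missingness > 0:
            keep_mask = rng.random(len(slots)) >= cfg.missingness
        else:
            rng.random(len(slots))
        series = LoggerSeries(
            site_id=m.site_id, data=df.loc[keep_mask], window=cfg.window
        )
        series_list.append(series)

    truth = _truth(cfg, slots)
    return series_list, list(cfg.sites), truth


def _truth(cfg: SyntheticConfig, slots: pd.DatetimeIndex) -> SyntheticTruth:
    mat, bio7, drt = {}, {}, {}
    for m in cfg.sites:
        terms = _site_terms(cfg, m)
        det = _deterministic_temp(cfg, m, slots)
        # daily means of the deterministic series (diurnal term cancels)
        daily = det.reshape(-1, len(SCHEDULE_HOURS)).mean(axis=1)
        mat[m.site_id] = float(daily.mean())
        months = pd.Series(daily, index=pd.DatetimeIndex(slots[:: len(SCHEDULE_HOURS)]))
        mmt = months.groupby([months.index.year, months.index.month]).mean()
        bio7[m.site_id] = float(mmt.max() - mmt.min())
        # sampled diurnal range: cos at the six hours spans [-1, 1]
        cosvals = np.array([_DIURNAL_COS[h] for h in SCHEDULE_HOURS])
        drt[m.site_id] = float(terms["amp_diurnal"] * np.ptp(cosvals))

    def det_fn(site_id: str, timestamps: pd.DatetimeIndex) -> np.ndarray:
        m = next(s for s in cfg.sites if s.site_id == site_id)
        return _deterministic_temp(cfg, m, timestamps)

    return SyntheticTruth(
        expected_mat=mat,
        expected_bio7=bio7,
        expected_drt=drt,
        deterministic_temperature=det_fn,
    )


def inject_missingness(
    series: LoggerSeries,
    fraction: float,
    seed: int,
    mode: str = "uniform",
) -> LoggerSeries:
    """Drop slots from a series, reproducibly.

    ``mode='uniform'``: each slot is dropped independently with probability
    ``fraction``. ``mode='burst'``: the trailing ``fraction`` of slots is
    dropped (the battery-death failure mode of field loggers).
    """
    if not 0.0 <= fraction < 1.0:
        raise ConfigError("inject_missingness: fraction must be in [0, 1)")
    if fraction == 0.0:
        return series
    n = series.n_records
    if mode == "uniform":
        rng = np.random.default_rng(seed)
        keep = rng.random(n) >= fraction
    elif mode == "burst":
        keep = np.arange(n) < int(round(n * (1.0 - fraction)))
    else:
        raise ConfigError(f"inject_missingness: unknown mode {mode!r}")
    return LoggerSeries(
        site_id=series.site_id,
        data=series.data.loc[keep],
        window=series.window,
    )
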