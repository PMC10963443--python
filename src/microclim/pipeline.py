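"""End-to-end analysis pipeline.

Orchestrates ingest → QC → aggregation → moisture → gradients → stand-gap →
group statistics from a single YAML config, writing plain-CSV tables, a
structured run log, and a JSON manifest. Deterministic for a fixed config
and seed.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import daily_summaries, drt_day_matrix, network_bioclim
from .errors import ConfigError, StageError
from .gradients import (
    fit_lapse,
    fit_vpd_smooth,
    flag_above_band,
    standardize_continentality,
)
from .group_stats import table1_analogue
from .io import filter_complete, read_series, read_sites, write_series, write_sites
from .moisture import FireThreshold, VpdParams, network_moisture
from .stand_gap import diurnal_profile, make_pairs, stand_gap_drt
from .synthetic import SyntheticConfig, default_study_config, generate
from .types import Aspect, LoggerSeries, Setting, SiteMeta, Vegetation

_KNOWN_KEYS = {
    "input_dir",
    "simulate",
    "seed",
    "window",
    "completeness_threshold",
    "schedule_strict",
    "min_obs",
    "reference_elevation",
    "gam_k",
    "alpha",
    "fire_threshold",
    "vpd_params",
    "out_dir",
    "force",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    out_dir: Path
    input_dir: Optional[Path] = None
    simulate: bool = True
    seed: int = 0
    window: tuple[dt.date, dt.date] = (dt.date(2022, 3, 1), dt.date(2023, 2, 28))
    completeness_threshold: float = 1.0
    schedule_strict: bool = True
    min_obs: int = 6
    reference_elevation: float = 1000.0
    gam_k: int = 5
    alpha: float = 0.001
    fire_threshold: FireThreshold = field(default_factory=FireThreshold)
    vpd_params: VpdParams = field(default_factory=VpdParams)
    force: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        if "out_dir" not in raw:
            raise ConfigError("config requires out_dir")
        kwargs["out_dir"] = Path(raw["out_dir"])
        if "input_dir" in raw and raw["input_dir"]:
            kwargs["input_dir"] = Path(raw["input_dir"])
            kwargs["simulate"] = bool(raw.get("simulate", False))
        else:
            kwargs["simulate"] = bool(raw.get("simulate", True))
        for key in (
            "seed",
            "completeness_threshold",
            "schedule_strict",
            "min_obs",
            "reference_elevation",
            "gam_k",
            "alpha",
            "force",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "window" in raw:
            w = raw["window"]
            kwargs["window"] = (
                _as_date(w["start"]),
                _as_date(w["end"]),
            )
        if "fire_threshold" in raw:
            ft = raw["fire_threshold"]
            kwargs["fire_threshold"] = FireThreshold(
                t_max_gt=float(ft.get("t_max_gt", 25.0)),
                rh_min_lt=float(ft.get("rh_min_lt", 25.0)),
            )
        if "vpd_params" in raw:
            vp = raw["vpd_params"]
            kwargs["vpd_params"] = VpdParams(
                a_water=float(vp.get("a_water", 17.2693882)),
                b_water=float(vp.get("b_water", 237.3)),
                e0=float(vp.get("e0", 6.1078)),
            )
        return cls(**kwargs)


def _as_date(x) -> dt.date:
    if isinstance(x, dt.date):
        return x
    return dt.date.fromisoformat(str(x))


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def log(self, stage: str, level: str, code: str, message: str) -> None:
        line = f"{stage}\t{level}\t{code}\t{message}"
        self.lines.append(line)
        print(line, file=sys.stderr)

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    Stage order: ingest, qc, aggregate, moisture, gradients, stand_gap,
    group_stats, report tables. Any stage failure raises StageError with the
    stage name.
    """
    out = config.out_dir
    if out.exists() and any(out.iterdir()) and not config.force:
        existing = {p.name for p in out.iterdir()}
        if "manifest.json" in existing:
            raise ConfigError(
                f"output dir {out} already holds a run (use force to overwrite)"
            )
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run.log")
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": {},
        "exclusions": [],
    }

    # -- ingest -------------------------------------------------------------
    try:
        if config.simulate or config.input_dir is None:
            cfg = default_study_config(seed=config.seed)
            if config.window != cfg.window:
                from dataclasses import replace

                cfg = replace(cfg, window=config.window)
            series, sites, _ = generate(cfg)
            manifest["input"] = {"simulated": True, "seed": config.seed}
        else:
            sites = read_sites(config.input_dir / "sites.csv")
            series = []
            checksums = {}
            for m in sites:
                p = config.input_dir / f"{m.site_id}.csv"
                if not p.exists():
                    log.log("ingest", "WARN", "missing_series", m.site_id)
                    continue
                series.append(
                    read_series(
                        p,
                        strict=config.schedule_strict,
                        window=config.window,
                        site_id=m.site_id,
                    )
                )
                checksums[m.site_id] = _sha256(p)
            manifest["input"] = {"simulated": False, "checksums": checksums}
        meta = {m.site_id: m for m in sites}
        manifest["stages"]["ingest"] = {"n_series": len(series), "n_sites": len(sites)}
        log.log("ingest", "INFO", "ok", f"{len(series)} series, {len(sites)} sites")
    except StageError:
        raise
    except Exception as e:  # pragma: no cover - defensive
        raise StageError("ingest", str(e)) from e

    # -- qc -----------------------------------------------------------------
    try:
        retained, excluded = filter_complete(series, config.completeness_threshold)
        for rep in excluded:
            log.log(
                "qc",
                "INFO",
                "excluded_incomplete",
                f"{rep.site_id} completeness={rep.fraction:.4f}",
            )
            manifest["exclusions"].append(
                {"site_id": rep.site_id, "reason": "incomplete", "fraction": rep.fraction}
            )
        manifest["stages"]["qc"] = {
            "n_retained": len(retained),
            "n_excluded": len(excluded),
        }
        by_id = {s.site_id: s for s in retained}
        stand_ids = [
            m.site_id
            for m in sites
            if m.setting is Setting.stand and m.site_id in by_id
        ]
    except Exception as e:
        raise StageError("qc", str(e)) from e

    # -- aggregate ------------------------------------------------------------
    try:
        daily_by_site = {
            sid: daily_summaries(by_id[sid], min_obs=config.min_obs)
            for sid in by_id
        }
        bio = network_bioclim(retained, min_obs=config.min_obs)
        bio.to_csv(out / "bioclim.csv")
        drt_mat = drt_day_matrix(retained, sites, min_obs=config.min_obs)
        drt_mat.to_csv(out / "drt_matrix.csv")
        daily_rows = []
        for sid, d in daily_by_site.items():
            dd = d.reset_index()
            dd.insert(0, "site_id", sid)
            daily_rows.append(dd)
        pd.concat(daily_rows, ignore_index=True).to_csv(out / "daily.csv", index=False)
        manifest["stages"]["aggregate"] = {"n_sites": len(bio)}
        log.log("aggregate", "INFO", "ok", f"{len(bio)} bioclim rows")
    except Exception as e:
        raise StageError("aggregate", str(e)) from e

    # -- moisture -------------------------------------------------------------
    try:
        moist = network_moisture(
            retained, config.vpd_params, config.fire_threshold, config.min_obs
        )
        moist.to_csv(out / "moisture.csv")
        manifest["stages"]["moisture"] = {"n_sites": len(moist)}
    except Exception as e:
        raise StageError("moisture", str(e)) from e

    # -- gradients ------------------------------------------------------------
    try:
        z = np.array([meta[s].elevation for s in stand_ids])
        mat = bio.loc[stand_ids, "mat"].to_numpy()
        models = [fit_lapse(z, mat, "overall")]
        for sec in (1, 2, 3, 4):
            ids = [s for s in stand_ids if meta[s].sector == sec]
            if len(ids) >= 3:
                models.append(
                    fit_lapse(
                        [meta[s].elevation for s in ids],
                        bio.loc[ids, "mat"].to_numpy(),
                        f"sector-{sec}",
                    )
                )
        aspect_models = {}
        for asp in (Aspect.N, Aspect.S):
            ids = [s for s in stand_ids if meta[s].aspect is asp]
            if len(ids) >= 3:
                m = fit_lapse(
                    [meta[s].elevation for s in ids],
                    bio.loc[ids, "mat"].to_numpy(),
                    f"aspect-{asp.value}",
                )
                aspect_models[asp] = m
                models.append(m)
        pd.DataFrame(
            [
                {
                    "stratum": m.stratum,
                    "slope_per_m": m.slope,
                    "slope_per_100m": m.slope_per_100m,
                    "intercept": m.intercept,
                    "adj_r2": m.adj_r2,
                    "p_value": m.p_value,
                    "n": m.n,
                }
                for m in models
            ]
        ).to_csv(out / "lapse_models.csv", index=False)

        cont, cont_model = standardize_continentality(
            z,
            bio.loc[stand_ids, "bio7"].to_numpy(),
            stand_ids,
            reference=config.reference_elevation,
        )
        cont["sector"] = [meta[s].sector for s in stand_ids]
        cont.to_csv(out / "continentality.csv")

        if Aspect.N in aspect_models and Aspect.S in aspect_models:
            from .gradients import aspect_elevation_equivalence

            eq = aspect_elevation_equivalence(
                aspect_models[Aspect.N],
                aspect_models[Aspect.S],
                models[0],
                [500.0, 1000.0, 1500.0],
            )
            eq.rename_axis("elevation_m").to_csv(out / "aspect_equivalence.csv")

        # VPD-elevation smooth on reference stands (shrubland stages excluded)
        ref_ids = [
            s for s in stand_ids if meta[s].vegetation is not Vegetation.NotAnta
        ]
        anta_ids = [
            s for s in stand_ids if meta[s].vegetation is Vegetation.NotAnta
        ]
        fit = fit_vpd_smooth(
            [meta[s].elevation for s in ref_ids],
            moist.loc[ref_ids, "vpd_annual_max_of_daily_mean"].to_numpy(),
            k=config.gam_k,
        )
        lo, hi = fit.x_range_
        grid = np.linspace(lo, hi, 111)
        f = fit.predict(grid)
        se = fit.se(grid)
        pd.DataFrame(
            {
                "elevation_m": grid,
                "fitted": f,
                "se": se,
                "lo95": f - 1.96 * se,
                "hi95": f + 1.96 * se,
            }
        ).to_csv(out / "vpd_fit.csv", index=False)
        flag_ids = [
            s for s in anta_ids if lo <= meta[s].elevation <= hi
        ]
        flags = flag_above_band(
            fit,
            [meta[s].elevation for s in flag_ids],
            moist.loc[flag_ids, "vpd_annual_max_of_daily_mean"].to_numpy(),
        )
        pd.DataFrame(
            {
                "site_id": flag_ids,
                "elevation_m": [meta[s].elevation for s in flag_ids],
                "vpd": moist.loc[flag_ids, "vpd_annual_max_of_daily_mean"].to_numpy(),
                "flag": flags,
            }
        ).to_csv(out / "vpd_flags.csv", index=False)
        manifest["stages"]["gradients"] = {
            "lapse_per_100m": models[0].slope_per_100m,
            "cont_slope_per_m": cont_model.slope,
            "vpd_fit_adj_r2": fit.adj_r2_,
            "vpd_fit_n": fit.n_,
        }
        log.log(
            "gradients",
            "INFO",
            "ok",
            f"lapse {models[0].slope_per_100m:.3f} K/100m",
        )
    except Exception as e:
        raise StageError("gradients", str(e)) from e

    # -- stand_gap ------------------------------------------------------------
    try:
        pairs, pair_log = make_pairs(sites, by_id, config.completeness_threshold)
        for line in pair_log:
            log.log("stand_gap", "INFO", "pair_excluded", line)
        if pairs:
            prof_rows, drt_rows = [], []
            for pair in pairs:
                for month in ("warmest", "coldest"):
                    prof = diurnal_profile(pair, month)
                    ym = prof.attrs["month"]
                    p = prof.reset_index()
                    p.insert(0, "pair", f"{pair.stand.site_id}/{pair.gap.site_id}")
                    p.insert(1, "month", f"{ym[0]}-{ym[1]:02d}")
                    prof_rows.append(p)
                    _, summary = stand_gap_drt(pair, month, config.min_obs)
                    if summary:
                        drt_rows.append(
                            {
                                "pair": f"{pair.stand.site_id}/{pair.gap.site_id}",
                                "month": f"{summary['month'][0]}-{summary['month'][1]:02d}",
                                "mean_drt_diff": summary["mean_diff"],
                                "t": summary["t"],
                                "p": summary["p"],
                                "n_days": summary["n_days"],
                            }
                        )
            pd.concat(prof_rows, ignore_index=True).to_csv(
                out / "standgap_profiles.csv", index=False
            )
            pd.DataFrame(drt_rows).to_csv(out / "standgap_drt.csv", index=False)
            manifest["stages"]["stand_gap"] = {"n_pairs": len(pairs)}
        else:
            log.log("stand_gap", "INFO", "skipped", "no resolvable gap pairs")
            manifest["stages"]["stand_gap"] = {"n_pairs": 0, "skipped": True}
    except Exception as e:
        raise StageError("stand_gap", str(e)) from e

    # -- group_stats ----------------------------------------------------------
    try:
        veg_by_site = {
            s: meta[s].vegetation.value for s in stand_ids
        }
        table1 = table1_analogue(
            {s: daily_by_site[s] for s in stand_ids},
            veg_by_site,
            alpha=config.alpha,
        )
        table1.to_csv(out / "table1_analogue.csv")
        manifest["stages"]["group_stats"] = {"n_vegetation": len(table1)}
    except Exception as e:
        raise StageError("group_stats", str(e)) from e

    # -- manifest -------------------------------------------------------------
    tables = sorted(p.name for p in out.glob("*.csv"))
    manifest["tables"] = {name: _sha256(out / name) for name in tables}
    log.flush()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def report(out_dir: str | Path) -> str:
    """Human-readable summary assembled from a completed run's tables.

    No recomputation: reads the CSVs, verifies them against the manifest
    checksums, and formats the headline results.
    """
    out = Path(out_dir)
    man_path = out / "manifest.json"
    if not man_path.exists():
        raise StageError("report", "manifest.json missing — run the pipeline first")
    manifest = json.loads(man_path.read_text())
    for name, digest in manifest.get("tables", {}).items():
        p = out / name
        if not p.exists():
            raise StageError("report", f"table {name} missing")
        if _sha256(p) != digest:
            raise StageError("report", f"table {name} checksum mismatch")

    lines = [f"microclim run (package {manifest['package_version']}, seed {manifest['seed']})"]
    qc = manifest["stages"].get("qc", {})
    lines.append(
        f"QC: {qc.get('n_retained', '?')} complete series retained, "
        f"{qc.get('n_excluded', '?')} excluded"
    )
    grad = manifest["stages"].get("gradients", {})
    if grad:
        lines.append(
            f"MAT lapse: {grad['lapse_per_100m']:.3f} K/100 m; "
            f"continentality trend {grad['cont_slope_per_m']:.5f} K/m; "
            f"VPD smooth adj R2 {grad['vpd_fit_adj_r2']:.2f} (n={grad['vpd_fit_n']})"
        )
    t1 = out / "table1_analogue.csv"
    if t1.exists():
        df = pd.read_csv(t1, index_col=0)
        lines.append("Vegetation summary (MDT 365 d, mean ± SD, letters):")
        for veg, row in df.iterrows():
            lines.append(
                f"  {veg}: {row['mdt_365d_mean']:.1f} ± {row['mdt_365d_sd']:.1f} "
                f"[{row['mdt_365d_letters']}]"
            )
    flags = out / "vpd_flags.csv"
    if flags.exists():
        fdf = pd.read_csv(flags)
        n_above = int((fdf["flag"] == "above").sum())
        lines.append(
            f"Shrubland-stage VPD: {n_above}/{len(fdf)} sites above the 95% band"
        )
    return "\n".join(lines)
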