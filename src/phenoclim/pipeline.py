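"""End-to-end analysis pipeline.

Chains the stages over plot-level input tables: soil-climate summaries
(matric potential + MAT/MWT/MST/MAMP/DFWP/DBWP per annual window), NDVI
phenometrics per plot-season, flowering metrics and temperature
sensitivities, treatment-collapse decisions, and the 15-model AICc
variable-importance attribution of every phenology response to soil
temperature vs moisture predictors. The run is deterministic given the
inputs and configuration; every output carries provenance (config hash
and input digests).
"""

from __future__ import annotations

from datetime import date, timedelta
import json
from hashlib import sha256

import numpy as np
import pandas as pd

from . import flowering as fl
from . import models
from . import ndvi_phenology as ndvi_ph
from .config import AnalysisConfig, annual_window
from .soil_water import (SoilTexture, fit_retention_curve,
                         matric_potential_series, summarize_climate)


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and the offending unit."""


def _df_digest(df: pd.DataFrame) -> str:
    if df is None or len(df) == 0:
        return "empty"
    h = pd.util.hash_pandas_object(df.astype(str), index=False).to_numpy()
    return sha256(h.tobytes()).hexdigest()[:12]


def _covered_annual_windows(env: pd.DataFrame, min_coverage: float = 0.9) -> list[int]:
    """Start years of Jul-15 -> Jul-15 windows covered by the env series."""
    days = pd.to_datetime(env["date"]).dt.date
    lo, hi = days.min(), days.max()
    years = []
    for y in range(lo.year - 1, hi.year + 1):
        w = annual_window(y)
        if w.start >= lo and w.end <= hi + timedelta(days=1):
            n = days[(days >= w.start) & (days < w.end)].nunique()
            if n >= min_coverage * w.n_days:
                years.append(y)
    return years


def _date_to_days(values, origin: date) -> pd.Series:
    """Event dates to numeric days since a window origin (NaN-safe)."""
    def conv(d):
        if d is None or pd.isna(d):
            return np.nan
        return float((pd.Timestamp(d).date() - origin).days)
    return values.map(conv)


def run_pipeline(config: AnalysisConfig, design: pd.DataFrame,
                 env: pd.DataFrame, ndvi: pd.DataFrame,
                 flowering: pd.DataFrame,
                 textures: dict[str, SoilTexture]) -> dict:
    """Run every analysis stage; returns a bundle of output tables.

    `textures` maps site -> SoilTexture (one retention curve per site).
    The flowering stage is skipped (empty outputs) when the flowering
    table is empty; the NDVI and climate stages are independent of it.
    """
    provenance = {
        "config": config.digest(),
        "inputs": {name: _df_digest(df) for name, df in
                   [("design", design), ("env", env), ("ndvi", ndvi),
                    ("flowering", flowering)]},
    }
    site_of = design.set_index("plot_id")["site"]

    # ---- soil water / climate summaries -----------------------------------
    try:
        psi_frames = []
        for site, grp in env.merge(design[["plot_id", "site"]], on="plot_id") \
                           .groupby("site"):
            curve = fit_retention_curve(textures[site])
            psi_frames.append(matric_potential_series(grp, curve,
                                                      config.wilting_point_kPa))
        psi = pd.concat(psi_frames, ignore_index=True)
        window_years = _covered_annual_windows(env)
        summaries = []
        for y in window_years:
            s = summarize_climate(env, psi, annual_window(y),
                                  config.wilting_point_kPa)
            s.insert(1, "season", str(y + 1))
            summaries.append(s)
        climate = pd.concat(summaries, ignore_index=True) if summaries \
            else pd.DataFrame()
    except Exception as exc:
        raise StageError(f"soil_water stage failed: {exc}") from exc

    # ---- NDVI phenometrics ------------------------------------------------
    ndvi_rows = []
    for y in window_years:
        w = annual_window(y)
        season = str(y + 1)
        season_win = (pd.Timestamp(w.start), pd.Timestamp(w.end))
        summer_win = (pd.Timestamp(w.start),
                      pd.Timestamp(w.start + timedelta(days=92)))
        for plot_id, grp in ndvi.groupby("plot_id", sort=True):
            grp = grp.sort_values("date").reset_index(drop=True)
            try:
                m = ndvi_ph.season_phenometrics(
                    grp, season_window=season_win, summer_window=summer_win,
                    senescence_fraction=config.senescence_fraction,
                    greenup_fraction=config.greenup_fraction,
                    window_points=config.senescence_window_points,
                    greenup_min_floor=config.greenup_min_floor,
                    greenup_offset=config.greenup_offset)
            except ndvi_ph.InsufficientDataError:
                continue
            except Exception as exc:
                raise StageError(
                    f"ndvi_phenology stage failed for plot {plot_id}, "
                    f"season {season}: {exc}") from exc
            m.update(plot_id=plot_id, season=season)
            ndvi_rows.append(m)
    ndvi_metrics = pd.DataFrame(ndvi_rows)

    # ---- flowering --------------------------------------------------------
    if len(flowering):
        try:
            fmetrics = fl.flowering_metrics(flowering)
            abundance = fl.abundance_table(flowering, design)
            sens = fl.sensitivity_table(fmetrics, design,
                                        delta_T=config.warming_delta_C)
        except Exception as exc:
            raise StageError(f"flowering stage failed: {exc}") from exc
    else:
        fmetrics = pd.DataFrame(columns=["species", "plot_id", "ffd", "pfd",
                                         "max_open_flowers", "abundance"])
        abundance = pd.DataFrame()
        sens = pd.DataFrame()

    # ---- responses for attribution ---------------------------------------
    responses: dict[str, tuple[pd.Series, str]] = {}  # name -> (values, season)
    for season, grp in (ndvi_metrics.groupby("season")
                        if len(ndvi_metrics) else []):
        origin = date(int(season) - 1, 7, 15)
        grp = grp.set_index("plot_id")
        responses[f"peak_date_{season}"] = (
            _date_to_days(grp["peak_date"], origin), season)
        responses[f"senescence_date_{season}"] = (
            _date_to_days(grp["senescence_date"], origin), season)
        responses[f"senescence_rate_{season}"] = (
            grp["senescence_rate"].astype(float), season)
        gsl = grp["gsl_days"].astype(float)
        if gsl.notna().sum() >= 10:
            responses[f"gsl_{season}"] = (gsl, season)
    if len(fmetrics):
        fseason = str(pd.to_datetime(flowering["date"]).dt.year.mode()[0])
        origin = date(int(fseason) - 1, 7, 15)
        multi_site = (fmetrics.dropna(subset=["ffd"])
                      .merge(design[["plot_id", "site"]], on="plot_id")
                      .groupby("species")["site"].nunique())
        for sp in sorted(fmetrics["species"].unique()):
            if multi_site.get(sp, 0) < 2:
                continue  # species surviving at a single site are excluded
            sub = fmetrics[fmetrics["species"] == sp].set_index("plot_id")
            for event in ("ffd", "pfd"):
                vals = _date_to_days(sub[event], origin)
                if vals.notna().sum() >= 10:
                    responses[f"{event}_{sp}_{fseason}"] = (vals, fseason)

    # ---- collapse decisions, candidate sets, importance -------------------
    collapse_rows, model_frames, importance_frames = [], [], []
    for name, (values, season) in responses.items():
        values = values.dropna()
        dec = models.collapse_treatments(values, design, config.collapse_alpha)
        collapse_rows.append({
            "response": name, "p_control_vs_drought": dec.p_control_vs_drought,
            "p_warming_vs_warmingppt": dec.p_warming_vs_warmingppt,
            "collapsed": dec.collapsed, "deferred": dec.deferred,
        })
        clim = climate[climate["season"] == season]
        if not len(clim):
            continue
        try:
            mset = models.build_candidate_set(values, clim, response_name=name)
        except ValueError:
            continue
        table = mset.table.copy()
        table.insert(0, "response", name)
        table["terms"] = table["terms"].map(lambda t: "+".join(t))
        reported = models.rank_and_filter(mset, config.delta_aicc_equiv)
        reported_terms = {"+".join(t) for t in reported.get("terms", [])}
        table["reported"] = table["terms"].isin(reported_terms)
        model_frames.append(table)
        importance_frames.append(models.relative_importance(mset))

    bundle = {
        "climate_summary": climate,
        "matric_potential": psi,
        "ndvi_metrics": ndvi_metrics,
        "flowering_metrics": fmetrics,
        "abundance": abundance,
        "sensitivity": sens,
        "collapse": pd.DataFrame(collapse_rows),
        "model_tables": (pd.concat(model_frames, ignore_index=True)
                         if model_frames else pd.DataFrame()),
        "importance": (pd.concat(importance_frames, ignore_index=True)
                       if importance_frames else pd.DataFrame()),
        "provenance": provenance,
    }
    return bundle


def provenance_json(bundle: dict) -> str:
    return json.dumps(bundle["provenance"], sort_keys=True, indent=2)
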