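"""Population-level flowering phenology from repeated count surveys.

Each survey records, per plot x species x date, the number of open flowers
(for the grass, reproductive stalks count as flowers) and the number of
flowering individuals. Derived per species x plot:

FFD  first flowering date: earliest survey date with open flowers.
PFD  peak flowering date: survey date with the most open flowers
     (earliest on ties).
abundance  the plot-season count of reproductive plants, taken as the
     maximum flowering-individual count over the season's surveys (a
     plant detected flowering in any week is counted once).

Temperature sensitivity of an event (FFD or PFD) is computed per warmed
plot as (event date in the warmed plot - mean event date over ambient
plots) / delta_T with delta_T the canopy warming offset (2.5 C); negative
values mean warming advances the event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("plot_id", "species", "date", "open_flowers", "flowering_individuals")


def _check_sorted(dates: np.ndarray) -> None:
    if len(dates) > 1 and not np.all(dates[1:] > dates[:-1]):
        raise ValueError("survey dates must be strictly increasing within a plot x species")


def first_flowering_date(survey: pd.DataFrame):
    """Earliest survey date with open_flowers > 0; None if never flowered."""
    d = survey["date"].to_numpy()
    _check_sorted(d)
    hits = np.flatnonzero(survey["open_flowers"].to_numpy() > 0)
    return d[hits[0]] if len(hits) else None


def peak_flowering_date(survey: pd.DataFrame):
    """Date of maximum open_flowers (earliest on ties); None if all zero."""
    d = survey["date"].to_numpy()
    _check_sorted(d)
    flowers = survey["open_flowers"].to_numpy()
    if flowers.max(initial=0) == 0:
        return None
    return d[int(np.argmax(flowers))]


@dataclass(frozen=True)
class SensitivityResult:
    per_plot: pd.Series          # sensitivity (days/C) indexed by warmed plot_id
    mean: float
    se: float
    untestable: bool             # no variance in either group (no t test possible)


def temperature_sensitivity(event_dates_warm: pd.Series,
                            event_dates_ambient: pd.Series,
                            delta_T: float = 2.5) -> SensitivityResult:
    """Days/C shift per warmed plot relative to the ambient-plot mean date.

    Inputs are event dates (as day-of-year or dates) indexed by plot_id;
    plots lacking the event must already be dropped. The contrast is
    flagged untestable when both groups are internally constant (no
    within-group variance for a t test), mirroring populations that flower
    in lockstep.
    """
    warm = event_dates_warm.dropna()
    amb = event_dates_ambient.dropna()
    if len(amb) == 0 or len(warm) == 0:
        raise ValueError("need >= 1 warmed and >= 1 ambient event date")
    warm_days = warm.map(_to_days).astype(float)
    amb_days = amb.map(_to_days).astype(float)
    sens = (warm_days - amb_days.mean()) / delta_T
    se = float(sens.std(ddof=1) / np.sqrt(len(sens))) if len(sens) > 1 else np.nan
    untestable = (warm_days.nunique() == 1) and (amb_days.nunique() == 1)
    return SensitivityResult(per_plot=sens, mean=float(sens.mean()), se=se,
                             untestable=untestable)


def _to_days(d) -> float:
    if isinstance(d, (pd.Timestamp, np.datetime64)):
        return float(pd.Timestamp(d).toordinal())
    if hasattr(d, "toordinal"):
        return float(d.toordinal())
    return float(d)


def flowering_metrics(surveys: pd.DataFrame) -> pd.DataFrame:
    """FFD, PFD, max open flowers and season abundance per species x plot."""
    missing = set(REQUIRED_COLUMNS) - set(surveys.columns)
    if missing:
        raise ValueError(f"flowering survey missing columns: {sorted(missing)}")
    if (surveys["open_flowers"] < 0).any() or (surveys["flowering_individuals"] < 0).any():
        raise ValueError("counts must be nonnegative")
    rows = []
    for (species, plot_id), grp in surveys.groupby(["species", "plot_id"], sort=True):
        grp = grp.sort_values("date")
        rows.append({
            "species": species,
            "plot_id": plot_id,
            "ffd": first_flowering_date(grp),
            "pfd": peak_flowering_date(grp),
            "max_open_flowers": int(grp["open_flowers"].max()),
            "abundance": int(grp["flowering_individuals"].max()),
        })
    return pd.DataFrame(rows)


def abundance_table(surveys: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Median reproductive-plant abundance per species x site x treatment.

    Plot abundance is the season maximum of flowering_individuals; the
    median is taken over the replicates (zeros included).
    """
    metrics = flowering_metrics(surveys)
    merged = metrics.merge(design[["plot_id", "site", "treatment"]], on="plot_id",
                           validate="many_to_one")
    table = (merged.groupby(["species", "site", "treatment"], sort=True)["abundance"]
             .median().rename("median_abundance").reset_index())
    return table


def sensitivity_table(metrics: pd.DataFrame, design: pd.DataFrame,
                      delta_T: float = 2.5,
                      exclusions: set[tuple[str, str, str]] | None = None) -> pd.DataFrame:
    """Per-plot temperature sensitivities for FFD and PFD, by species x site.

    `exclusions` holds (species, site, event) combinations flagged
    uncountable in the field (excluded before computing). Combinations
    without at least one warmed and one ambient event date are dropped.
    """
    exclusions = exclusions or set()
    merged = metrics.merge(
        design[["plot_id", "site", "temperature_category"]], on="plot_id",
        validate="many_to_one",
    )
    rows = []
    for event in ("ffd", "pfd"):
        for (species, site), grp in merged.groupby(["species", "site"], sort=True):
            if (species, site, event) in exclusions:
                continue
            dated = grp.dropna(subset=[event])
            warm = dated[dated["temperature_category"] == "warming"]
            amb = dated[dated["temperature_category"] == "ambient"]
            if len(warm) == 0 or len(amb) == 0:
                continue
            res = temperature_sensitivity(
                warm.set_index("plot_id")[event],
                amb.set_index("plot_id")[event],
                delta_T=delta_T,
            )
            for plot_id, s in res.per_plot.items():
                rows.append({
                    "species": species, "site": site, "event": event,
                    "plot_id": plot_id, "sensitivity_days_per_C": float(s),
                    "site_mean": res.mean, "site_se": res.se,
                    "untestable": res.untestable,
                })
    return pd.DataFrame(rows, columns=[
        "species", "site", "event", "plot_id", "sensitivity_days_per_C",
        "site_mean", "site_se", "untestable",
    ])
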