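"""Community-level phenometrics from per-plot NDVI series.

NDVI (normalized difference vegetation index, in [-1, 1]) is a proxy for
live canopy biomass. In a Mediterranean annual cycle the canopy greens up
with the fall rains, peaks in spring and senesces into the summer drought.
Five phenometrics are extracted per plot and season, all defined on the
sampled dates themselves (no interpolation or smoothing — the date
resolution equals the sampling interval):

peak biomass
    maximum NDVI in the season window; ties break to the earliest date.
date of senescence
    first sampled date after the peak with NDVI <= 80% of the peak value.
rate of senescence
    least-squares slope (delta NDVI per day) over the run of three
    consecutive sampling points with the greatest total decline
    (two points allowed where senescence is too rapid for three).
green-up date
    first sampled date after the summer minimum with NDVI >= 125% of the
    minimum; for minima near zero the multiplicative rule degenerates, so
    below a small floor an additive offset rule is used instead (flagged).
growing season length
    days from fall green-up to the next season's date of senescence.

Detectors that never cross their threshold return a censored flag rather
than a fabricated date.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
import numpy as np
import pandas as pd


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class PeakResult:
    peak_date: object   # date or numeric day
    peak_ndvi: float


def _dates_values(series: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    d = series["date"].to_numpy()
    v = series["ndvi"].to_numpy(dtype=float)
    if len(d) > 1 and not np.all(d[1:] > d[:-1]):
        raise ValueError("NDVI series dates must be strictly increasing")
    if np.any(v < -1) or np.any(v > 1):
        raise ValueError("NDVI values must lie in [-1, 1]")
    return d, v


def _day_number(d) -> float:
    """Dates to a day count; numeric inputs pass through."""
    if isinstance(d, (date, np.datetime64, pd.Timestamp)):
        return pd.Timestamp(d).toordinal()
    return float(d)


def peak_biomass(series: pd.DataFrame) -> PeakResult:
    """Date and value of maximum NDVI (earliest date on ties)."""
    d, v = _dates_values(series)
    if len(d) == 0:
        raise InsufficientDataError("empty NDVI window")
    i = int(np.argmax(v))  # argmax returns the first maximum
    return PeakResult(peak_date=d[i], peak_ndvi=float(v[i]))


def senescence_date(series: pd.DataFrame, peak: PeakResult,
                    fraction: float = 0.80):
    """First sampled date strictly after the peak with NDVI <= fraction * peak.

    Returns None (censored) when the threshold is never crossed before the
    series ends.
    """
    d, v = _dates_values(series)
    threshold = fraction * peak.peak_ndvi
    after = d > peak.peak_date
    hits = np.flatnonzero(after & (v <= threshold))
    return d[hits[0]] if len(hits) else None


def senescence_rate(series: pd.DataFrame, window_points: int = 3) -> tuple[float, bool]:
    """Slope (delta NDVI / day) over the steepest-declining run of samples.

    Among all runs of `window_points` consecutive observations, the run
    maximizing (first NDVI - last NDVI) is selected (earliest run on ties)
    and the least-squares slope of NDVI on date is returned. With two
    points this is the difference quotient. The second return value flags
    a nonsenescent series (best run actually increases, slope > 0).
    """
    d, v = _dates_values(series)
    if len(d) < window_points:
        raise InsufficientDataError(
            f"need >= {window_points} observations, got {len(d)}"
        )
    declines = v[: len(v) - window_points + 1] - v[window_points - 1:]
    best = int(np.argmax(declines))
    run = slice(best, best + window_points)
    x = np.array([_day_number(di) for di in d[run]])
    slope = float(np.polyfit(x - x.mean(), v[run], 1)[0])
    return slope, slope > 0


def summer_minimum(series: pd.DataFrame) -> PeakResult:
    """Minimum NDVI in a (summer) window; earliest date on ties."""
    d, v = _dates_values(series)
    if len(d) == 0:
        raise InsufficientDataError("empty summer window")
    i = int(np.argmin(v))
    return PeakResult(peak_date=d[i], peak_ndvi=float(v[i]))


def greenup_date(series: pd.DataFrame, summer_min: PeakResult,
                 fraction: float = 1.25, min_floor: float = 0.05,
                 offset: float = 0.05):
    """First sampled date after the summer minimum with NDVI >= threshold.

    The threshold is fraction * minimum (inclusive). When the minimum is at
    or below `min_floor` the multiplicative rule is replaced by
    minimum + offset and the substitution is flagged in the second return
    value. Returns (None, flag) when never crossed (censored).
    """
    d, v = _dates_values(series)
    substituted = summer_min.peak_ndvi <= min_floor
    threshold = (summer_min.peak_ndvi + offset) if substituted \
        else fraction * summer_min.peak_ndvi
    after = d > summer_min.peak_date
    hits = np.flatnonzero(after & (v >= threshold))
    return (d[hits[0]] if len(hits) else None), substituted


def growing_season_length(greenup, senescence) -> int:
    """Integer days from fall green-up to the following date of senescence."""
    if greenup is None or senescence is None:
        raise ValueError("growing season length undefined for censored dates")
    days = int(round(_day_number(senescence) - _day_number(greenup)))
    if days < 0:
        raise ValueError(f"senescence {senescence} precedes green-up {greenup}")
    return days


def _window_mask(dates: np.ndarray, window) -> np.ndarray:
    if window is None:
        return np.ones(len(dates), dtype=bool)
    start, end = window
    return np.array([start <= pd.Timestamp(d) < end if isinstance(d, (date, np.datetime64, pd.Timestamp))
                     else start <= d < end for d in dates])


def season_phenometrics(series: pd.DataFrame, season_window=None,
                        summer_window=None, senescence_fraction: float = 0.80,
                        greenup_fraction: float = 1.25,
                        window_points: int = 3,
                        greenup_min_floor: float = 0.05,
                        greenup_offset: float = 0.05) -> dict:
    """All phenometrics for one plot-season, with censoring/quality flags.

    `series` is a (date, ndvi) frame for one plot; `season_window` and
    `summer_window` are (start, end) half-open pairs restricting, resp.,
    the growth season and the summer-minimum search. Green-up and growing
    season length are reported only when a summer window is given.
    """
    d, v = _dates_values(series)
    in_season = _window_mask(d, season_window)
    season = series.loc[in_season]
    if len(season) < 3:
        raise InsufficientDataError("need >= 3 observations in the season window")

    peak = peak_biomass(season)
    sen = senescence_date(season, peak, senescence_fraction)
    rate, nonsenescent = senescence_rate(season, window_points)

    out = {
        "peak_date": peak.peak_date,
        "peak_ndvi": peak.peak_ndvi,
        "senescence_date": sen,
        "senescence_censored": sen is None,
        "senescence_rate": rate,
        "nonsenescent": nonsenescent,
        "greenup_date": None,
        "greenup_censored": None,
        "greenup_substituted": None,
        "gsl_days": None,
    }
    if summer_window is not None:
        summer = series.loc[_window_mask(d, summer_window)]
        smin = summer_minimum(summer)
        gup, substituted = greenup_date(
            series, smin, greenup_fraction, greenup_min_floor, greenup_offset
        )
        out.update(greenup_date=gup, greenup_censored=gup is None,
                   greenup_substituted=substituted)
        if gup is not None and sen is not None:
            out["gsl_days"] = growing_season_length(gup, sen)
    return out
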