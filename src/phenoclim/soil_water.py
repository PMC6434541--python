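"""Soil-water retention and annual climate summaries.

Volumetric water content (VWC) is not comparable across sites with
different soil textures, so plot-level VWC is converted to soil matric
potential (psi, kPa, <= 0) through texture-based pedotransfer regressions
(Saxton-Rawls moisture-retention equations): the texture of a site
determines the retention-curve anchors theta_1500 (VWC at -1500 kPa, the
permanent wilting point), theta_33 (VWC at -33 kPa, field capacity) and
theta_s (saturation), and tension between -1500 and -33 kPa follows the
power law psi = -A * theta**(-B).

From the daily matric-potential series the module computes the annual
climate summary variables used as predictors downstream:

MAT / MWT / MST
    mean annual / winter (Dec 1-Feb 28) / spring (Mar 1-May 31) soil
    temperature, degrees C.
MAMP
    mean annual matric potential after clamping at the wilting point
    (any psi < -1500 kPa becomes -1500).
DFWP
    date of first wilting point: first day of the annual window whose
    daily-mean psi drops strictly below -1500 kPa (missing if never).
DBWP
    number of days in the annual window below the wilting point.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
import math

import numpy as np
import pandas as pd

from .config import SeasonWindow, winter_window, spring_window

WILTING_POINT_KPA = -1500.0


class DegenerateTextureError(ValueError):
    """Texture for which the pedotransfer regressions give no valid curve."""


@dataclass(frozen=True)
class SoilTexture:
    """Mass fractions of sand, clay and organic matter (all in 0-1)."""

    sand_fraction: float
    clay_fraction: float
    organic_matter_fraction: float = 0.025

    def __post_init__(self) -> None:
        for name in ("sand_fraction", "clay_fraction", "organic_matter_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.sand_fraction + self.clay_fraction > 1.0:
            raise ValueError("sand + clay fractions exceed 1")


@dataclass(frozen=True)
class RetentionCurve:
    """Anchors and coefficients of a soil moisture-retention curve.

    theta_1500 < theta_33 < theta_s are the VWCs at -1500 kPa, -33 kPa and
    saturation; A and B parameterise the -1500..-33 kPa power-law segment
    (tension = A * theta**-B, kPa); psi_air_entry_kPa is the (negative)
    air-entry tension at saturation.
    """

    theta_s: float
    theta_33: float
    theta_1500: float
    A: float
    B: float
    psi_air_entry_kPa: float

    def __post_init__(self) -> None:
        if not 0 < self.theta_1500 < self.theta_33 < self.theta_s <= 1:
            raise ValueError(
                "need 0 < theta_1500 < theta_33 < theta_s <= 1, got "
                f"{self.theta_1500}, {self.theta_33}, {self.theta_s}"
            )
        if self.B <= 0:
            raise ValueError("power-law exponent B must be positive")


def power_law_coefficients(theta_33: float, theta_1500: float) -> tuple[float, float]:
    """A, B of the tension power law through (-33, theta_33), (-1500, theta_1500)."""
    B = math.log(1500.0 / 33.0) / math.log(theta_33 / theta_1500)
    A = math.exp(math.log(33.0) + B * math.log(theta_33))
    return A, B


def fit_retention_curve(texture: SoilTexture) -> RetentionCurve:
    """Moisture-retention curve from texture via the pedotransfer regressions.

    Deterministic in the texture. The regressions take sand and clay as
    decimal fractions and organic matter in percent weight; the conversion
    from the 0-1 organic-matter fraction happens here. Gravel, salinity and
    density adjustments are out of scope (only matric potential from VWC is
    needed downstream).
    """
    S = texture.sand_fraction
    C = texture.clay_fraction
    OM = texture.organic_matter_fraction * 100.0  # regressions use %w

    t1500t = (-0.024 * S + 0.487 * C + 0.006 * OM
              + 0.005 * S * OM - 0.013 * C * OM + 0.068 * S * C + 0.031)
    theta_1500 = t1500t + (0.14 * t1500t - 0.02)

    t33t = (-0.251 * S + 0.195 * C + 0.011 * OM
            + 0.006 * S * OM - 0.027 * C * OM + 0.452 * S * C + 0.299)
    theta_33 = t33t + (1.283 * t33t**2 - 0.374 * t33t - 0.015)

    ts33t = (0.278 * S + 0.034 * C + 0.022 * OM
             - 0.018 * S * OM - 0.027 * C * OM - 0.584 * S * C + 0.078)
    theta_s33 = ts33t + (0.636 * ts33t - 0.107)  # theta between -33 kPa and saturation

    psi_et = (-21.67 * S - 27.93 * C - 81.97 * theta_s33
              + 71.12 * S * theta_s33 + 8.29 * C * theta_s33
              + 14.05 * S * C + 27.16)
    psi_e = psi_et + (0.02 * psi_et**2 - 0.113 * psi_et - 0.70)  # kPa, tension
    psi_e = min(max(psi_e, 0.5), 32.0)  # keep air entry within (0, 33)

    theta_s = theta_33 + theta_s33 - 0.097 * S + 0.043

    if not theta_1500 > 0 or not theta_33 > theta_1500:
        raise DegenerateTextureError(
            f"texture {texture} yields theta_33={theta_33:.4f} <= theta_1500={theta_1500:.4f}"
        )
    theta_s = min(theta_s, 1.0)
    if theta_s <= theta_33:
        raise DegenerateTextureError(f"texture {texture} yields theta_s <= theta_33")

    A, B = power_law_coefficients(theta_33, theta_1500)
    return RetentionCurve(
        theta_s=theta_s, theta_33=theta_33, theta_1500=theta_1500,
        A=A, B=B, psi_air_entry_kPa=-psi_e,
    )


def vwc_to_matric_potential(theta, curve: RetentionCurve):
    """Matric potential (kPa, <= 0) from volumetric water content.

    Piecewise: 0 at/above saturation; linear in theta from 0 at theta_s
    down to -33 kPa at theta_33 (the air-entry tension is retained as
    curve metadata but the wet segment is taken to zero so psi(theta) is
    continuous); the power law -A * theta**-B between theta_33 and
    theta_1500, extrapolated below theta_1500 (downstream clamping at
    -1500 kPa makes the extrapolation inconsequential for MAMP, but
    DFWP/DBWP need psi < -1500 representable).

    Accepts a scalar or array; non-decreasing and continuous in theta.
    """
    theta_arr = np.asarray(theta, dtype=float)
    if np.any(theta_arr <= 0):
        raise ValueError("VWC must be > 0")

    tension_dry = curve.A * theta_arr ** (-curve.B)
    # linear from 33 kPa at theta_33 to 0 at theta_s
    frac = (theta_arr - curve.theta_33) / (curve.theta_s - curve.theta_33)
    tension_wet = 33.0 * (1.0 - frac)

    tension = np.where(theta_arr <= curve.theta_33, tension_dry, tension_wet)
    tension = np.where(theta_arr >= curve.theta_s, 0.0, tension)
    psi = -tension
    return float(psi) if np.isscalar(theta) or theta_arr.ndim == 0 else psi


def clamp_at_wilting_point(psi, wilting_point_kPa: float = WILTING_POINT_KPA):
    """Elementwise max(psi, -1500): values below the wilting point saturate."""
    return np.maximum(np.asarray(psi, dtype=float), wilting_point_kPa)


def matric_potential_series(env: pd.DataFrame, curve: RetentionCurve,
                            wilting_point_kPa: float = WILTING_POINT_KPA) -> pd.DataFrame:
    """Per-plot daily matric potential from an environmental series.

    `env` needs columns plot_id, date, vwc. Returns plot_id, date, psi_kPa
    and psi_clamped_kPa (clamped at the wilting point).
    """
    out = env[["plot_id", "date"]].copy()
    out["psi_kPa"] = vwc_to_matric_potential(env["vwc"].to_numpy(), curve)
    out["psi_clamped_kPa"] = clamp_at_wilting_point(out["psi_kPa"], wilting_point_kPa)
    return out


class CoverageError(ValueError):
    """The series does not cover enough of the requested window."""


def summarize_climate(env: pd.DataFrame, psi: pd.DataFrame, window: SeasonWindow,
                      wilting_point_kPa: float = WILTING_POINT_KPA,
                      min_coverage: float = 0.9) -> pd.DataFrame:
    """Annual climate summary per plot over the given Jul-15 -> Jul-15 window.

    Daily means are formed first (a day is below wilting point if its daily
    mean psi is strictly below -1500 kPa; boundary days at exactly -1500 do
    not count). DFWP is reported both as a date and as days since the window
    start (dfwp_days, for use as a numeric predictor); it is missing when
    the wilting point is never reached inside the window.
    """
    env = env.copy()
    env["day"] = pd.to_datetime(env["date"]).dt.date
    psi = psi.copy()
    psi["day"] = pd.to_datetime(psi["date"]).dt.date

    win_start, win_end = window.start, window.end
    wyear = win_start.year
    winter = winter_window(wyear)
    spring = spring_window(wyear + 1)

    rows = []
    for plot_id, grp in env.groupby("plot_id", sort=True):
        daily_t = grp.groupby("day")["soil_temp_C"].mean()
        daily_t = daily_t[(daily_t.index >= win_start) & (daily_t.index < win_end)]
        coverage = len(daily_t) / window.n_days
        if coverage < min_coverage:
            raise CoverageError(
                f"plot {plot_id}: only {len(daily_t)}/{window.n_days} days in "
                f"window {win_start}..{win_end}"
            )
        pgrp = psi[psi["plot_id"] == plot_id]
        daily_psi = pgrp.groupby("day")["psi_kPa"].mean()
        daily_psi = daily_psi[(daily_psi.index >= win_start) & (daily_psi.index < win_end)]

        below = daily_psi[daily_psi < wilting_point_kPa]
        dfwp = below.index.min() if len(below) else None
        clamped = np.maximum(daily_psi.to_numpy(), wilting_point_kPa)

        rows.append({
            "plot_id": plot_id,
            "window": f"{win_start.isoformat()}/{win_end.isoformat()}",
            "MAT_C": float(daily_t.mean()),
            "MWT_C": float(daily_t[[winter.contains(d) for d in daily_t.index]].mean()),
            "MST_C": float(daily_t[[spring.contains(d) for d in daily_t.index]].mean()),
            "MAMP_kPa": float(clamped.mean()),
            "DFWP": dfwp,
            "dfwp_days": (dfwp - win_start).days if dfwp is not None else np.nan,
            "DBWP": int(len(below)),
        })
    return pd.DataFrame(rows)
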