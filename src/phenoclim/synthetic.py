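"""Synthetic warming x moisture experiment with stored ground truth.

Generates a complete experiment — daily plot-level environmental series,
NDVI surveys and flowering surveys — with the statistical structure the
analysis pipeline assumes, so every downstream stage is testable without
any field data. The emulated design is 3 sites on a latitudinal gradient
x 4 treatments (control, drought, warming, warming + ppt) x 5 replicates.

Climate model (per site, daily):
  * canopy temperature = annual sinusoid + AR(1) noise; the warming and
    warming + ppt treatments add a +2.5 C canopy offset and a damped
    (0.8x) offset on soil temperature;
  * rainfall is a shared site-level wet-season process (Bernoulli
    occurrence x gamma amounts), giving the Mediterranean regime of wet
    cool winters and rain-free summers; drought plots receive 0.60 x
    infiltration (a 40% exclusion);
  * soil water follows a single-layer bucket: infiltration minus
    temperature-driven evapotranspiration, bounded between a residual
    and the texture's saturation water content; warming + ppt plots get a
    nightly irrigation pulse whenever their water content falls below
    95% of the same-site control-plot mean (the feedback irrigation
    rule).
The site parameter defaults order the gradient: the southern site is
warmest with the earliest summer drought, the northern coolest and most
mesic.

Greenness model: each plot-season has a latent curve (rising logistic x
falling logistic, the asymmetric green-up/senescence shape standard in
land-surface phenology) whose green-up is tied to the first post-summer
day the plot's matric potential rises above the wilting point and whose
senescence phase is advanced by `warming_advance_days` in warming-category
plots. Observed NDVI = latent + Gaussian noise, clipped to [-1, 1].

Flowering model: per species x plot, the number of flowering individuals
is zero-inflated negative binomial with mean increasing and zero-inflation
decreasing from south to north; open-flower counts follow a Gaussian pulse
in time centred on the plot's true peak-flowering day (advanced in warming
plots by the flowering temperature sensitivity x the warming offset).

Ground truth for every phenometric is computed by applying the
definitional detectors to the noise-free daily latent curves, so on
zero-noise daily sampling the pipeline must recover the truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .design import full_design, TEMPERATURE_CATEGORY
from .soil_water import SoilTexture, fit_retention_curve, vwc_to_matric_potential

SOIL_DEPTH_MM = 300.0  # VWC sensor integration depth


@dataclass(frozen=True)
class SiteClimateSpec:
    """Climate and soil parameters of one site.

    Soil textures are plausible placeholders for prairie loams (no
    site-specific measurements exist to copy); their role is only to give
    each site a distinct retention curve.
    """

    name: str
    latitude_rank: int                  # 0 = southernmost
    mean_annual_temp_C: float
    seasonal_temp_amplitude_C: float
    temp_peak_doy: int = 200            # canopy temperature maximum (mid July)
    # deviations of the site's soil temperature from the plain sinusoid in
    # the winter (Dec-Feb) and spring (Mar-May) windows; maritime influence
    # and cold-air pooling differ seasonally along the gradient, so winter,
    # spring and annual means are not affine images of one another
    winter_anomaly_C: float = 0.0
    spring_anomaly_C: float = 0.0
    wet_season_start_doy: int = 280
    wet_season_end_doy: int = 150
    rain_probability: float = 0.60
    rain_gamma_shape: float = 1.3
    rain_gamma_scale_mm: float = 6.0
    et_reference_mm_per_day: float = 3.6
    texture: SoilTexture = field(default_factory=lambda: SoilTexture(0.40, 0.22, 0.035))
    ndvi_amplitude: float = 0.31
    ndvi_base: float = 0.12
    senescence_midpoint_doy: int = 150  # ambient senescence phase centre
    ndvi_sampling_interval_days: int = 7


def default_site_specs() -> dict[str, SiteClimateSpec]:
    """The 3-site latitudinal gradient: southern warmest/driest, northern
    coolest/most mesic (asserted on generated output, not just here)."""
    return {
        "southern": SiteClimateSpec(
            name="southern", latitude_rank=0, mean_annual_temp_C=12.5,
            seasonal_temp_amplitude_C=8.5, wet_season_start_doy=285,
            wet_season_end_doy=128, rain_probability=0.55,
            winter_anomaly_C=0.9, spring_anomaly_C=-0.5,
            rain_gamma_scale_mm=6.0, et_reference_mm_per_day=4.2,
            texture=SoilTexture(0.35, 0.28, 0.030), ndvi_amplitude=0.28,
            senescence_midpoint_doy=135, ndvi_sampling_interval_days=14,
        ),
        "central": SiteClimateSpec(
            name="central", latitude_rank=1, mean_annual_temp_C=11.4,
            seasonal_temp_amplitude_C=8.0, wet_season_start_doy=278,
            wet_season_end_doy=150, rain_probability=0.60,
            winter_anomaly_C=-0.7, spring_anomaly_C=0.8,
            rain_gamma_scale_mm=6.5, et_reference_mm_per_day=3.6,
            texture=SoilTexture(0.40, 0.22, 0.035), ndvi_amplitude=0.31,
            senescence_midpoint_doy=158, ndvi_sampling_interval_days=7,
        ),
        "northern": SiteClimateSpec(
            name="northern", latitude_rank=2, mean_annual_temp_C=10.3,
            seasonal_temp_amplitude_C=7.5, wet_season_start_doy=271,
            wet_season_end_doy=170, rain_probability=0.65,
            winter_anomaly_C=0.4, spring_anomaly_C=-0.9,
            rain_gamma_scale_mm=7.0, et_reference_mm_per_day=3.1,
            texture=SoilTexture(0.45, 0.18, 0.040), ndvi_amplitude=0.34,
            senescence_midpoint_doy=172, ndvi_sampling_interval_days=7,
        ),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the simulated experiment."""

    start: date = date(2015, 11, 1)
    n_days: int = 1035                    # through late August 2018
    flowering_year: int | None = None     # default: end year of the first
                                          # fully covered Jul-Jul season
    warming_delta_C: float = 2.5
    soil_offset_factor: float = 0.8       # soil damping of the canopy offset
    drought_infiltration_factor: float = 0.60  # 40% precipitation exclusion
    irrigation_threshold: float = 0.95    # x same-site control mean VWC
    irrigation_pulse_mm: float = 5.0
    warming_advance_days: float = 20.0    # advance of NDVI peak/senescence
    flowering_sensitivity_days_per_C: float = 2.8
    temp_noise_sd: float = 0.8            # site-shared AR(1) innovations, C
    temp_noise_rho: float = 0.7
    plot_temp_noise_sd: float = 0.25
    plot_microsite_sd: float = 0.3        # persistent per-plot soil-temp offsets
                                          # (annual/winter/spring components)
    ndvi_noise_sd: float = 0.02
    ndvi_plot_amp_sd: float = 0.02
    flower_peak_jitter_sd: float = 2.0
    flowers_per_plant: float = 5.0
    nb_dispersion: float = 2.0            # NB size parameter for abundances
    greenup_lag_days: int = 10            # rain trigger -> green-up midpoint lag
    greenup_rate_days: float = 16.0
    senescence_rate_days: float = 6.0
    spring_growth_per_day: float = 0.004  # spring-growth tilt pinning a
                                          # pronounced peak to the senescence
                                          # phase (shifts propagate ~1:1)

    def zero_noise(self) -> "SyntheticConfig":
        return replace(self, temp_noise_sd=0.0, plot_temp_noise_sd=0.0,
                       plot_microsite_sd=0.0, ndvi_noise_sd=0.0,
                       ndvi_plot_amp_sd=0.0, flower_peak_jitter_sd=0.0)


#: species code -> (base peak-flowering doy, mean abundance multiplier)
DEFAULT_SPECIES = {
    "ACHMOL": (125, 1.0), "COLGRA": (110, 1.5), "FESROE": (140, 0.8),
    "MICLAC": (135, 0.6), "PLANOT": (105, 1.2), "PLECON": (120, 1.4),
    "RANAUS": (115, 0.5), "SIDMAL": (145, 0.9),
}
#: site -> (abundance multiplier, zero-inflation probability, peak doy offset)
SITE_FLOWERING = {"southern": (0.4, 0.50, -12.0), "central": (1.0, 0.30, -4.0),
                  "northern": (2.5, 0.10, 8.0)}


def _dates(cfg: SyntheticConfig) -> np.ndarray:
    return np.array([cfg.start + timedelta(days=int(i)) for i in range(cfg.n_days)])


def _doy(dates) -> np.ndarray:
    return np.array([d.timetuple().tm_yday for d in dates], dtype=float)


def generate_environment(specs: dict[str, SiteClimateSpec],
                         design: pd.DataFrame, cfg: SyntheticConfig,
                         seed: int) -> tuple[pd.DataFrame, dict]:
    """Daily environmental series per plot, plus accounting diagnostics.

    Returns (env, diagnostics): env has plot_id, date, canopy_temp_C,
    soil_temp_C, vwc; diagnostics holds per-site rain series and per-plot
    cumulative infiltration and irrigation (for water-balance checks).
    """
    unknown = set(design["site"]) - set(specs)
    if unknown:
        raise ValueError(f"no climate spec for sites: {sorted(unknown)}")
    if cfg.n_days < 365:
        raise ValueError("need at least one full year of daily steps")
    rng = np.random.default_rng(seed)
    dates = _dates(cfg)
    doy = _doy(dates)

    frames = []
    diagnostics = {"rain_mm": {}, "cum_infiltration_mm": {}, "cum_irrigation_mm": {}}
    for site_name, site_plots in design.groupby("site", sort=True):
        spec = specs[site_name]
        curve = fit_retention_curve(spec.texture)
        w_sat = curve.theta_s * SOIL_DEPTH_MM
        w_res = 0.5 * curve.theta_1500 * SOIL_DEPTH_MM

        # shared site weather
        phase = 2 * np.pi * (doy - spec.temp_peak_doy) / 365.25
        t_base = spec.mean_annual_temp_C + spec.seasonal_temp_amplitude_C * np.cos(phase)
        ar = np.zeros(cfg.n_days)
        innov = rng.normal(0, cfg.temp_noise_sd, cfg.n_days)
        for i in range(1, cfg.n_days):
            ar[i] = cfg.temp_noise_rho * ar[i - 1] + innov[i]
        start_doy, end_doy = spec.wet_season_start_doy, spec.wet_season_end_doy
        in_wet = (doy >= start_doy) | (doy <= end_doy)
        rain = np.where(
            in_wet & (rng.random(cfg.n_days) < spec.rain_probability),
            rng.gamma(spec.rain_gamma_shape, spec.rain_gamma_scale_mm, cfg.n_days),
            0.0,
        )
        diagnostics["rain_mm"][site_name] = rain

        plots = site_plots.reset_index(drop=True)
        n_plots = len(plots)
        warmed = plots["treatment"].map(TEMPERATURE_CATEGORY).eq("warming").to_numpy()
        droughted = plots["treatment"].eq("drought").to_numpy()
        irrigated = plots["treatment"].eq("warming_ppt").to_numpy()
        controls = plots["treatment"].eq("control").to_numpy()

        infil_factor = np.where(droughted, cfg.drought_infiltration_factor, 1.0)
        canopy_offset = np.where(warmed, cfg.warming_delta_C, 0.0)
        soil_offset = cfg.soil_offset_factor * canopy_offset

        plot_noise = rng.normal(0, cfg.plot_temp_noise_sd, (cfg.n_days, n_plots)) \
            if cfg.plot_temp_noise_sd > 0 else np.zeros((cfg.n_days, n_plots))

        canopy = t_base[:, None] + ar[:, None] + canopy_offset[None, :] + plot_noise
        soil_phase = 2 * np.pi * (doy - spec.temp_peak_doy - 12) / 365.25
        months = np.array([d.month for d in dates])
        winter_mask = np.isin(months, (12, 1, 2)).astype(float)
        spring_mask = np.isin(months, (3, 4, 5)).astype(float)
        soil_base = (spec.mean_annual_temp_C
                     + 0.75 * spec.seasonal_temp_amplitude_C * np.cos(soil_phase)
                     + spec.winter_anomaly_C * winter_mask
                     + spec.spring_anomaly_C * spring_mask)
        # persistent microsite offsets with independent seasonal components
        micro = rng.normal(0, cfg.plot_microsite_sd, (3, n_plots)) \
            if cfg.plot_microsite_sd > 0 else np.zeros((3, n_plots))
        micro_field = (micro[0][None, :]
                       + winter_mask[:, None] * micro[1][None, :]
                       + spring_mask[:, None] * micro[2][None, :])
        soil = (soil_base[:, None] + 0.5 * ar[:, None] + soil_offset[None, :]
                + 0.5 * plot_noise + micro_field)

        # bucket model; warming raises ET through the canopy offset
        w = np.full(n_plots, w_res + 0.05 * (w_sat - w_res))  # mid-summer start: dry
        vwc = np.empty((cfg.n_days, n_plots))
        cum_infil = np.zeros(n_plots)
        cum_irrig = np.zeros(n_plots)
        for i in range(cfg.n_days):
            infil = rain[i] * infil_factor
            cum_infil += infil
            et = (spec.et_reference_mm_per_day
                  * np.clip(canopy[i], 0.0, None) / 15.0
                  * (w - w_res) / (w_sat - w_res))
            w = np.clip(w + infil - et, w_res, w_sat)
            theta = w / SOIL_DEPTH_MM
            if irrigated.any() and controls.any():
                control_mean = theta[controls].mean()
                needs = irrigated & (theta < cfg.irrigation_threshold * control_mean)
                if needs.any():
                    w = np.where(needs, np.minimum(w + cfg.irrigation_pulse_mm, w_sat), w)
                    cum_irrig += np.where(needs, cfg.irrigation_pulse_mm, 0.0)
                    theta = w / SOIL_DEPTH_MM
            vwc[i] = theta

        for j, plot_id in enumerate(plots["plot_id"]):
            frames.append(pd.DataFrame({
                "plot_id": plot_id, "date": dates,
                "canopy_temp_C": canopy[:, j], "soil_temp_C": soil[:, j],
                "vwc": vwc[:, j],
            }))
            diagnostics["cum_infiltration_mm"][plot_id] = float(cum_infil[j])
            diagnostics["cum_irrigation_mm"][plot_id] = float(cum_irrig[j])

    env = pd.concat(frames, ignore_index=True)
    return env, diagnostics


# ---------------------------------------------------------------------------
# NDVI


def _latent_ndvi(t: np.ndarray, base: float, amp: float, t_up_mid: float,
                 r_up: float, t_down_mid: float, r_down: float,
                 growth: float = 0.002) -> np.ndarray:
    """Rising x falling logistic with a slow spring-growth tilt.

    The tilt keeps NDVI creeping upward between green-up and senescence so
    the seasonal maximum sits a fixed distance before the senescence
    midpoint (rather than drifting toward green-up); an advance of the
    senescence phase then advances the peak by nearly the same number of
    days, as canopy warming does in the field.
    """
    rise = 1.0 / (1.0 + np.exp(-(t - t_up_mid) / r_up))
    fall = 1.0 / (1.0 + np.exp((t - t_down_mid) / r_down))
    tilt = np.clip(1.0 + growth * (t - t_up_mid), 0.2, None)
    return base + amp * rise * fall * tilt


def _season_windows(cfg: SyntheticConfig) -> list[tuple[str, date, date]]:
    """Jul-15 -> Jul-15 seasons fully covered by the simulated span."""
    out = []
    end = cfg.start + timedelta(days=cfg.n_days)
    year = cfg.start.year
    while True:
        s, e = date(year, 7, 15), date(year + 1, 7, 15)
        if s >= end:
            break
        if s >= cfg.start - timedelta(days=20) and e <= end:
            out.append((str(year + 1), s, e))
        year += 1
    return out


def generate_ndvi(env: pd.DataFrame, specs: dict[str, SiteClimateSpec],
                  design: pd.DataFrame, cfg: SyntheticConfig, seed: int,
                  sampling_interval_days: int | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NDVI survey series per plot plus the ground-truth phenometric table.

    Green-up midpoint of each season = first post-summer day the plot's
    matric potential exceeds the wilting point, plus a lag; senescence
    midpoint = the site's base day, advanced by `warming_advance_days` for
    warming-category plots. `sampling_interval_days` overrides the
    per-site default (weekly; biweekly at the southern site); pass 1 for
    daily sampling.
    """
    rng = np.random.default_rng(seed)
    dates = _dates(cfg)
    day_index = {d: i for i, d in enumerate(dates)}
    seasons = _season_windows(cfg)
    if not seasons:
        raise ValueError("simulated span too short for one Jul-Jul season")

    design_idx = design.set_index("plot_id")
    obs_frames, truth_rows = [], []
    for site_name, site_plots in design.groupby("site", sort=True):
        spec = specs[site_name]
        curve = fit_retention_curve(spec.texture)
        interval = sampling_interval_days or spec.ndvi_sampling_interval_days

        for plot_id in site_plots["plot_id"]:
            p_env = env[env["plot_id"] == plot_id]
            p_dates = np.array([pd.Timestamp(d).date() for d in p_env["date"]])
            psi = vwc_to_matric_potential(p_env["vwc"].to_numpy(), curve)
            warmedp = TEMPERATURE_CATEGORY[design_idx.loc[plot_id, "treatment"]] == "warming"
            amp = spec.ndvi_amplitude + (
                rng.normal(0, cfg.ndvi_plot_amp_sd) if cfg.ndvi_plot_amp_sd > 0 else 0.0)

            t = np.arange(len(dates), dtype=float)
            latent = np.full(len(dates), spec.ndvi_base)
            for season, s_start, s_end in seasons:
                # rain trigger: first post-summer day above wilting point
                summer_ref = date(s_start.year, 8, 1)
                mask = (p_dates >= summer_ref) & (p_dates < s_end)
                above = np.flatnonzero(mask & (psi > -1500.0))
                if len(above) == 0:
                    continue
                trigger = p_dates[above[0]]
                t_up = day_index[trigger] + cfg.greenup_lag_days
                sen_doy = spec.senescence_midpoint_doy - (
                    cfg.warming_advance_days if warmedp else 0.0)
                t_down = day_index[date(s_end.year, 1, 1)] - 1 + sen_doy
                seg = (t >= day_index.get(s_start, 0)) & \
                      (t < day_index.get(s_end - timedelta(days=1), len(dates) - 1) + 1)
                curve_vals = _latent_ndvi(t, spec.ndvi_base, amp, t_up,
                                          cfg.greenup_rate_days, t_down,
                                          cfg.senescence_rate_days,
                                          cfg.spring_growth_per_day)
                latent = np.where(seg, np.maximum(latent, curve_vals), latent)

                truth_rows.append(_truth_from_latent(
                    plot_id, season, s_start, s_end, dates, curve_vals, warmedp))

            sample_idx = np.arange(0, len(dates), interval)
            noise = rng.normal(0, cfg.ndvi_noise_sd, len(sample_idx)) \
                if cfg.ndvi_noise_sd > 0 else 0.0
            obs = np.clip(latent[sample_idx] + noise, -1.0, 1.0)
            obs_frames.append(pd.DataFrame({
                "plot_id": plot_id, "date": dates[sample_idx], "ndvi": obs,
            }))

    ndvi = pd.concat(obs_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return ndvi, truth


def _truth_from_latent(plot_id, season, s_start, s_end, dates, latent,
                       warmed: bool) -> dict:
    """Definitional phenometrics of the noise-free daily latent curve."""
    in_season = np.array([(s_start <= d < s_end) for d in dates])
    idx = np.flatnonzero(in_season)
    v = latent[idx]
    peak_i = int(np.argmax(v))
    peak_date = dates[idx[peak_i]]
    sen_after = np.flatnonzero((np.arange(len(v)) > peak_i) & (v <= 0.8 * v[peak_i]))
    sen_date = dates[idx[sen_after[0]]] if len(sen_after) else None
    # summer minimum searched in the first quarter of the season
    summer_cut = min(len(v), 92)
    min_i = int(np.argmin(v[:summer_cut]))
    gu_after = np.flatnonzero((np.arange(len(v)) > min_i) & (v >= 1.25 * v[min_i]))
    gu_date = dates[idx[gu_after[0]]] if len(gu_after) else None
    return {
        "plot_id": plot_id, "season": season, "warmed": warmed,
        "true_greenup_date": gu_date, "true_peak_date": peak_date,
        "true_senescence_date": sen_date,
    }


# ---------------------------------------------------------------------------
# flowering


def generate_flowering(design: pd.DataFrame, cfg: SyntheticConfig, seed: int,
                       species: dict[str, tuple[float, float]] | None = None,
                       year: int | None = None,
                       sampling_interval_days: dict[str, int] | None = None,
                       base_abundance: float = 8.0,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flowering surveys (open flowers + flowering individuals) with truth.

    Abundance per species x plot ~ zero-inflated negative binomial whose
    mean rises and zero-inflation falls from south to north; open-flower
    counts follow a Gaussian pulse centred on the plot's true peak day
    (advanced in warming plots by sensitivity x warming offset). Surveys
    run April through mid June, weekly (biweekly at the southern site).
    """
    species = species or DEFAULT_SPECIES
    if len(species) < 2:
        raise ValueError("configure at least 2 species")
    if year is None:
        year = cfg.flowering_year
    if year is None:
        year = cfg.start.year + (1 if cfg.start < date(cfg.start.year, 7, 15)
                                 else 2)
    rng = np.random.default_rng(seed)
    advance = cfg.flowering_sensitivity_days_per_C * cfg.warming_delta_C
    intervals = sampling_interval_days or {"southern": 14, "central": 7, "northern": 7}

    survey_start = date(year, 4, 1)
    n_survey_days = 80  # through mid June
    all_days = np.array([survey_start + timedelta(days=int(i))
                         for i in range(n_survey_days)])
    doys = _doy(all_days)
    pulse_sd = 7.0

    rows, truth_rows = [], []
    for _, plot in design.iterrows():
        site_mult, zi_prob, site_offset = SITE_FLOWERING[plot["site"]]
        warmed = TEMPERATURE_CATEGORY[plot["treatment"]] == "warming"
        interval = intervals.get(plot["site"], 7)
        sample_days = all_days[::interval]
        sample_doys = doys[::interval]
        for sp, (base_doy, sp_mult) in species.items():
            mu = base_abundance * sp_mult * site_mult
            structural_zero = rng.random() < zi_prob
            if structural_zero:
                n_ind = 0
            else:  # NB via gamma-Poisson mixture
                lam = rng.gamma(cfg.nb_dispersion, mu / cfg.nb_dispersion)
                n_ind = int(rng.poisson(lam))
            jitter = rng.normal(0, cfg.flower_peak_jitter_sd) \
                if cfg.flower_peak_jitter_sd > 0 else 0.0
            peak_doy = base_doy + site_offset + jitter - (advance if warmed else 0.0)

            latent_flowers = (n_ind * cfg.flowers_per_plant
                              * np.exp(-0.5 * ((doys - peak_doy) / pulse_sd) ** 2))
            latent_ind = n_ind * np.exp(-0.5 * ((doys - peak_doy) / (1.6 * pulse_sd)) ** 2)
            rounded = np.round(latent_flowers)
            onset_idx = np.flatnonzero(rounded >= 1)
            true_onset = all_days[onset_idx[0]] if len(onset_idx) else None
            # argmax of the rounded daily counts, earliest on ties: matches
            # the peak-date detector applied to noise-free daily surveys
            true_peak = (all_days[int(np.argmax(rounded))]
                         if n_ind and rounded.max() >= 1 else None)

            open_fl = np.round(latent_flowers[::interval]).astype(int)
            ind = np.round(latent_ind[::interval]).astype(int)
            for d, ofl, fin in zip(sample_days, open_fl, ind):
                rows.append({"plot_id": plot["plot_id"], "species": sp, "date": d,
                             "open_flowers": int(ofl),
                             "flowering_individuals": int(fin)})
            truth_rows.append({
                "species": sp, "plot_id": plot["plot_id"], "warmed": warmed,
                "true_individuals": n_ind,
                "true_onset_date": true_onset, "true_peak_flower_date": true_peak,
            })
    surveys = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return surveys, truth


# ---------------------------------------------------------------------------
# whole-experiment bundle


@dataclass
class SyntheticExperiment:
    design: pd.DataFrame
    env: pd.DataFrame
    ndvi: pd.DataFrame
    flowering: pd.DataFrame
    ndvi_truth: pd.DataFrame
    flowering_truth: pd.DataFrame
    diagnostics: dict
    specs: dict[str, SiteClimateSpec]
    config: SyntheticConfig


def generate_experiment(cfg: SyntheticConfig | None = None, seed: int = 0,
                        specs: dict[str, SiteClimateSpec] | None = None,
                        ndvi_sampling_interval_days: int | None = None
                        ) -> SyntheticExperiment:
    """One full synthetic experiment under the default study conditions."""
    cfg = cfg or SyntheticConfig()
    specs = specs or default_site_specs()
    design = full_design()
    env, diagnostics = generate_environment(specs, design, cfg, seed)
    ndvi, ndvi_truth = generate_ndvi(env, specs, design, cfg, seed + 1,
                                     sampling_interval_days=ndvi_sampling_interval_days)
    flowering, flowering_truth = generate_flowering(design, cfg, seed + 2)
    return SyntheticExperiment(design=design, env=env, ndvi=ndvi,
                               flowering=flowering, ndvi_truth=ndvi_truth,
                               flowering_truth=flowering_truth,
                               diagnostics=diagnostics, specs=specs, config=cfg)
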