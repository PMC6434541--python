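"""Generator properties: treatment construction, site ordering, bounds and
ground-truth consistency."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from phenoclim import ndvi_phenology as nph
from phenoclim.design import full_design
from phenoclim.soil_water import fit_retention_curve, vwc_to_matric_potential
from phenoclim.synthetic import (
    SyntheticConfig, default_site_specs, generate_environment,
    generate_flowering, generate_ndvi,
)


@pytest.fixture(scope="module")
def zero_noise_env():
    cfg = SyntheticConfig().zero_noise()
    specs = default_site_specs()
    design = full_design()
    env, diag = generate_environment(specs, design, cfg, seed=1)
    return cfg, specs, design, env, diag


class TestEnvironment:
    def test_same_site_same_treatment_identical_without_noise(self, zero_noise_env):
        _, _, design, env, _ = zero_noise_env
        plots = design[(design.site == "central") &
                       (design.treatment == "control")]["plot_id"]
        ref = env[env.plot_id == plots.iloc[0]].reset_index(drop=True)
        for p in plots.iloc[1:]:
            other = env[env.plot_id == p].reset_index(drop=True)
            assert np.allclose(ref["canopy_temp_C"], other["canopy_temp_C"])
            assert np.allclose(ref["vwc"], other["vwc"])

    def test_warming_canopy_offset_is_2p5(self, zero_noise_env):
        _, _, design, env, _ = zero_noise_env
        merged = env.merge(design[["plot_id", "treatment"]], on="plot_id")
        means = merged.groupby("treatment")["canopy_temp_C"].mean()
        assert means["warming"] - means["control"] == pytest.approx(2.5, abs=0.1)
        # soil offset is damped
        soil = merged.groupby("treatment")["soil_temp_C"].mean()
        assert 0 < soil["warming"] - soil["control"] < 2.5

    def test_drought_infiltration_ratio_exact(self, zero_noise_env):
        _, _, design, _, diag = zero_noise_env
        cum = diag["cum_infiltration_mm"]
        for site_code in ("S", "C", "N"):
            assert cum[f"{site_code}-D-1"] / cum[f"{site_code}-C-1"] == \
                pytest.approx(0.60, rel=1e-9)

    def test_irrigation_only_on_warming_ppt(self, zero_noise_env):
        _, _, design, _, diag = zero_noise_env
        for plot_id, mm in diag["cum_irrigation_mm"].items():
            if "-WP-" not in plot_id:
                assert mm == 0.0
        assert any(mm > 0 for p, mm in diag["cum_irrigation_mm"].items()
                   if "-WP-" in p)

    def test_vwc_bounds(self, zero_noise_env):
        *_, env, _ = zero_noise_env
        assert env["vwc"].between(0, 1).all()

    def test_site_wilting_order_south_first(self, zero_noise_env):
        """Southern control crosses the wilting point before central, and
        central before northern (summer 2016 onward)."""
        _, specs, design, env, _ = zero_noise_env
        first = {}
        for site in ("southern", "central", "northern"):
            curve = fit_retention_curve(specs[site].texture)
            plot = design[(design.site == site) &
                          (design.treatment == "control")]["plot_id"].iloc[0]
            sub = env[env.plot_id == plot]
            psi = vwc_to_matric_potential(sub["vwc"].to_numpy(), curve)
            days = np.array([pd.Timestamp(d).date() for d in sub["date"]])
            mask = (days >= date(2016, 5, 1)) & (psi < -1500)
            first[site] = days[mask][0]
        assert first["southern"] < first["central"] < first["northern"]

    def test_unknown_site_rejected(self, zero_noise_env):
        cfg, specs, design, *_ = zero_noise_env
        bad = design.copy()
        bad.loc[0, "site"] = "alpine"
        with pytest.raises(ValueError, match="alpine"):
            generate_environment(specs, bad, cfg, seed=1)


class TestNdvi:
    def test_bounds_and_truth_ordering(self, default_experiment):
        exp = default_experiment
        assert exp.ndvi["ndvi"].between(-1, 1).all()
        t = exp.ndvi_truth.dropna()
        assert (t["true_greenup_date"] < t["true_peak_date"]).all()
        assert (t["true_peak_date"] < t["true_senescence_date"]).all()

    def test_zero_noise_daily_full_recovery(self, zero_noise_experiment):
        """Definitional detectors recover the stored truth exactly."""
        exp = zero_noise_experiment
        checked = 0
        for (plot, season), trow in exp.ndvi_truth.set_index(
                ["plot_id", "season"]).iterrows():
            y = int(season)
            s_start = pd.Timestamp(date(y - 1, 7, 15))
            s_end = pd.Timestamp(date(y, 7, 15))
            grp = exp.ndvi[exp.ndvi.plot_id == plot].sort_values(
                "date").reset_index(drop=True)
            grp["date"] = pd.to_datetime(grp["date"])
            m = nph.season_phenometrics(
                grp, season_window=(s_start, s_end),
                summer_window=(s_start, s_start + timedelta(days=92)))

            def same(a, b):
                if a is None or b is None:
                    return a is None and b is None
                return pd.Timestamp(a).date() == b

            assert same(m["peak_date"], trow["true_peak_date"])
            assert same(m["senescence_date"], trow["true_senescence_date"])
            assert same(m["greenup_date"], trow["true_greenup_date"])
            checked += 1
        assert checked == 120

    def test_injected_peak_advance_by_construction(self, zero_noise_experiment):
        """The stored truth shows the ~20-day warming advance of the peak."""
        t = zero_noise_experiment.ndvi_truth.dropna(subset=["true_peak_date"]).copy()
        t["ord"] = t["true_peak_date"].map(lambda d: d.toordinal())
        diff = (t[t.warmed]["ord"].mean() - t[~t.warmed]["ord"].mean())
        assert diff == pytest.approx(-20, abs=2)

    def test_zero_noise_site_curves_identical(self, zero_noise_env):
        cfg, specs, design, env, _ = zero_noise_env
        ndvi, _ = generate_ndvi(env, specs, design, cfg, seed=3,
                                sampling_interval_days=7)
        plots = design[(design.site == "northern") &
                       (design.treatment == "drought")]["plot_id"]
        ref = ndvi[ndvi.plot_id == plots.iloc[0]]["ndvi"].to_numpy()
        for p in plots.iloc[1:]:
            assert np.allclose(ref, ndvi[ndvi.plot_id == p]["ndvi"].to_numpy())


class TestFlowering:
    def test_counts_nonnegative_integers(self, default_experiment):
        f = default_experiment.flowering
        assert (f["open_flowers"] >= 0).all()
        assert (f["flowering_individuals"] >= 0).all()
        assert f["open_flowers"].dtype.kind in "iu"

    def test_full_zero_inflation_gives_all_zero_site(self):
        cfg = SyntheticConfig().zero_noise()
        design = full_design()
        import phenoclim.synthetic as syn
        orig = syn.SITE_FLOWERING
        syn.SITE_FLOWERING = {**orig, "southern": (0.4, 1.0, -12.0)}
        try:
            surveys, _ = generate_flowering(design, cfg, seed=4)
        finally:
            syn.SITE_FLOWERING = orig
        south = surveys[surveys.plot_id.str.startswith("S-")]
        assert (south["open_flowers"] == 0).all()

    def test_noise_free_daily_peak_matches_truth(self):
        cfg = SyntheticConfig().zero_noise()
        design = full_design().head(20)  # one site
        surveys, truth = generate_flowering(
            design, cfg, seed=5,
            sampling_interval_days={"southern": 1, "central": 1, "northern": 1})
        from phenoclim.flowering import peak_flowering_date, first_flowering_date
        for (sp, plot), grp in surveys.groupby(["species", "plot_id"]):
            trow = truth[(truth.species == sp) & (truth.plot_id == plot)].iloc[0]
            grp = grp.sort_values("date")
            pfd = peak_flowering_date(grp)
            if trow["true_peak_flower_date"] is None:
                assert pfd is None or grp["open_flowers"].max() == 0
            else:
                assert pfd == trow["true_peak_flower_date"]
                assert first_flowering_date(grp) == trow["true_onset_date"]

    def test_biweekly_ffd_within_14_days_of_onset(self):
        """Biweekly sampling bounds the FFD error by one sampling interval."""
        cfg = SyntheticConfig().zero_noise()
        design = full_design()
        surveys, truth = generate_flowering(
            design, cfg, seed=6,
            sampling_interval_days={"southern": 14, "central": 14, "northern": 14})
        from phenoclim.flowering import first_flowering_date
        n_checked = 0
        for (sp, plot), grp in surveys.groupby(["species", "plot_id"]):
            trow = truth[(truth.species == sp) & (truth.plot_id == plot)].iloc[0]
            if trow["true_onset_date"] is None:
                continue
            ffd = first_flowering_date(grp.sort_values("date"))
            if ffd is None:  # pulse may fall entirely between surveys
                continue
            assert abs((ffd - trow["true_onset_date"]).days) <= 14
            n_checked += 1
        assert n_checked > 50

    def test_abundance_increases_south_to_north(self):
        cfg = SyntheticConfig()
        design = full_design()
        surveys, truth = generate_flowering(design, cfg, seed=7)
        m = truth.merge(design[["plot_id", "site"]], on="plot_id")
        means = m.groupby("site")["true_individuals"].mean()
        assert means["southern"] < means["central"] < means["northern"]

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            generate_flowering(full_design(), SyntheticConfig(), seed=1,
                               species={"ACHMOL": (125, 1.0)})
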