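"""Statistical layer: group tests, collapsing, ANOVA, repeated measures,
count-family selection and the 15-model AICc machinery."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st_
from hypothesis import given, settings, strategies as st

from phenoclim import models
from phenoclim.design import full_design


class TestCompareTwoGroups:
    def test_identical_groups(self):
        r = models.compare_two_groups([10, 12], [10, 12])
        assert r.difference == 0 and r.p_value == pytest.approx(1.0)

    def test_textbook_welch(self):
        w, a = [100, 102, 104], [110, 112, 114]
        r = models.compare_two_groups(w, a)
        assert r.difference == pytest.approx(-10)
        ref = st_.ttest_ind(w, a, equal_var=False)
        assert r.p_value == pytest.approx(float(ref.pvalue))

    def test_permutation_rank_agreement(self):
        """Welch p-values order small samples the same way a permutation
        test does."""
        rng = np.random.default_rng(5)
        cases = [(rng.normal(0, 1, 4), rng.normal(d, 1, 4)) for d in (0.2, 1.5, 4.0)]

        def perm_p(x, y):
            obs = abs(x.mean() - y.mean())
            pool = np.concatenate([x, y])
            count = 0
            combos = list(itertools.combinations(range(8), 4))
            for idx in combos:
                mask = np.zeros(8, bool)
                mask[list(idx)] = True
                if abs(pool[mask].mean() - pool[~mask].mean()) >= obs - 1e-12:
                    count += 1
            return count / len(combos)

        welch = [models.compare_two_groups(x, y).p_value for x, y in cases]
        perm = [perm_p(x, y) for x, y in cases]
        assert np.argsort(welch).tolist() == np.argsort(perm).tolist()

    def test_untestable_zero_variance(self):
        r = models.compare_two_groups([5, 5], [7, 7])
        assert r.untestable and r.difference == -2


class TestCollapseTreatments:
    def test_identical_values_collapse(self):
        design = full_design()
        values = pd.Series(1.0, index=design["plot_id"])
        d = models.collapse_treatments(values, design)
        assert d.collapsed and d.p_control_vs_drought == 1.0

    def test_within_pair_difference_blocks_collapse(self):
        design = full_design()
        trt = design.set_index("plot_id")["treatment"]
        values = pd.Series(0.0, index=design["plot_id"])
        rng = np.random.default_rng(0)
        values[:] = rng.normal(0, 0.1, len(values))
        values[trt == "warming_ppt"] += 50.0  # warming pair differs hugely
        d = models.collapse_treatments(values, design)
        assert not d.collapsed
        assert d.p_warming_vs_warmingppt < 0.10 <= d.p_control_vs_drought

    def test_deferred_with_tiny_groups(self):
        design = full_design().head(6)  # one treatment has < 2 plots
        values = pd.Series(1.0, index=design["plot_id"])
        assert models.collapse_treatments(values, design).deferred


class TestAnova:
    def test_two_level_factor_F_equals_t_squared(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"y": rng.normal(0, 1, 20),
                           "g": ["a"] * 10 + ["b"] * 10})
        res = models.anova_with_posthoc(df, "y", ("g",))
        F = res["anova"].loc["C(g)", "F"]
        t = st_.ttest_ind(df.y[df.g == "a"], df.y[df.g == "b"], equal_var=True)
        assert F == pytest.approx(t.statistic**2, rel=1e-9)

    def test_tukey_separates_distinct_site(self):
        """True means 0/0/10, sigma = 1, n = 5: the distinct group separates
        in (almost) every simulation."""
        rng = np.random.default_rng(2)
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            df = pd.DataFrame({
                "y": np.concatenate([rng.normal(0, 1, 5), rng.normal(0, 1, 5),
                                     rng.normal(10, 1, 5)]),
                "site": ["s1"] * 5 + ["s2"] * 5 + ["s3"] * 5,
            })
            tuk = models.anova_with_posthoc(df, "y", ("site",))["tukey"]["site"]
            frame = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
            vs3 = frame[(frame.group1 == "s3") | (frame.group2 == "s3")]
            if vs3["reject"].astype(bool).all():
                hits += 1
        assert hits / n_sim >= 0.95

    def test_interaction_term_present_with_two_factors(self):
        rng = np.random.default_rng(3)
        design = full_design()
        df = design.copy()
        df["y"] = rng.normal(0, 1, len(df))
        res = models.anova_with_posthoc(df, "y", ("site", "treatment"))
        assert "C(site):C(treatment)" in res["anova"].index


class TestRepeatedMeasures:
    @staticmethod
    def _long(cov, n_subj=20, seed=0, occasions=None):
        rng = np.random.default_rng(seed)
        k = cov.shape[0]
        occasions = occasions or [f"t{i}" for i in range(k)]
        vals = rng.multivariate_normal(np.zeros(k), cov, n_subj)
        rows = [{"subj": s, "occ": occasions[j], "y": vals[s, j]}
                for s in range(n_subj) for j in range(k)]
        return pd.DataFrame(rows)

    def test_two_occasions_never_corrected(self):
        df = self._long(np.eye(2), seed=1)
        res = models.repeated_measures(df, "y", "subj", "occ")
        assert res["epsilon_gg"] == 1.0 and not res["sphericity_violated"]

    def test_compound_symmetry_epsilon_near_one(self):
        cov = 0.5 * np.eye(4) + 0.5
        df = self._long(cov, n_subj=40, seed=2)
        res = models.repeated_measures(df, "y", "subj", "occ")
        assert res["epsilon_gg"] > 0.85

    def test_ar1_epsilon_below_one_and_p_not_smaller(self):
        rho = 0.9
        cov = rho ** np.abs(np.subtract.outer(np.arange(5), np.arange(5)))
        df = self._long(cov, n_subj=30, seed=3)
        # add a within effect so p is meaningful
        df["y"] += df["occ"].map({f"t{i}": 0.3 * i for i in range(5)})
        res = models.repeated_measures(df, "y", "subj", "occ")
        assert res["epsilon_gg"] < 1.0
        t = res["table"]
        row = t[t["Source"] == "occ"].iloc[0]
        assert row["p_GG_corr"] >= row["p_unc"] - 1e-12

    def test_single_occasion_rejected(self):
        df = pd.DataFrame({"subj": [1, 2], "occ": ["a", "a"], "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            models.repeated_measures(df, "y", "subj", "occ")

    def test_logit_transform_bounds(self):
        x = np.array([-1.0, 0.0, 0.5, 1.0])
        z = models.logit_transform(x)
        assert np.isfinite(z).all()
        assert z[1] == pytest.approx(0.0)


class TestCountModelSelection:
    def test_all_zero_flagged(self):
        design = full_design()
        counts = pd.Series(0, index=design["plot_id"])
        sel = models.select_count_model(counts, design)
        assert sel.all_zero and sel.family == "none"

    def test_site_effect_detected_poisson(self):
        rng = np.random.default_rng(4)
        design = full_design()
        lam = design["site"].map({"southern": 2, "central": 6, "northern": 15})
        counts = pd.Series(rng.poisson(lam), index=design["plot_id"])
        sel = models.select_count_model(counts, design, factors=("site",))
        assert sel.family in ("poisson", "negative_binomial")
        site_row = sel.effects[sel.effects.term == "site"]
        assert site_row["p"].iloc[0] < 0.001

    def test_lr_type_I_near_nominal(self):
        """No-effect Poisson counts: the LR test rejects near alpha."""
        rng = np.random.default_rng(6)
        design = full_design()
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            counts = pd.Series(rng.poisson(5, len(design)),
                               index=design["plot_id"])
            sel = models.select_count_model(counts, design, factors=("site",),
                                            families=("poisson",))
            if sel.effects["p"].iloc[0] < 0.05:
                rejections += 1
        assert 0.01 <= rejections / n_sim <= 0.10


class TestAICcMachinery:
    def test_aicc_formula_worked_example(self):
        """logL = -10, k = 3, n = 20: AIC = 26, AICc = 27.5."""
        assert models.aicc(-10, 3, 20) == pytest.approx(27.5)

    def test_aicc_approaches_aic_for_large_n(self):
        aic = -2 * (-10) + 2 * 3
        assert models.aicc(-10, 3, 10**6) == pytest.approx(aic, abs=1e-4)

    def test_weights_for_delta_0_2_4(self):
        w = models.akaike_weights([100.0, 102.0, 104.0])
        assert w == pytest.approx([0.665, 0.245, 0.090], abs=5e-4)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_models_share_weight(self):
        w = models.akaike_weights([10.0, 10.0, 50.0])
        assert w[0] == pytest.approx(0.5, abs=1e-6)

    def test_candidate_set_is_15_models(self):
        terms = models.candidate_model_terms()
        assert len(terms) == 15
        assert sum(len(t) == 2 for t in terms) == 9
        assert sum(len(t) == 1 for t in terms) == 6


def _random_candidate_set(seed):
    rng = np.random.default_rng(seed)
    terms = models.candidate_model_terms()
    table = pd.DataFrame({
        "terms": terms,
        "k": [len(t) + 2 for t in terms],
        "n": 40,
        "logLik": rng.normal(-50, 3, 15),
    })
    table["AICc"] = [models.aicc(l, k, 40) for l, k in zip(table.logLik, table.k)]
    table["delta"] = table["AICc"] - table["AICc"].min()
    table["weight"] = models.akaike_weights(table["AICc"])
    table = table.sort_values("delta", ignore_index=True)
    return models.CandidateModelSet(response="r", table=table)


def brute_force_report(table, delta_equiv=2.0):
    """Direct application of the two reporting rules."""
    aicc_of = {tuple(t): a for t, a in zip(table["terms"], table["AICc"])}
    out = []
    for _, row in table.iterrows():
        terms = tuple(row["terms"])
        if row["AICc"] - min(aicc_of.values()) >= delta_equiv:
            continue
        if len(terms) == 2 and any(
                aicc_of[(t,)] < row["AICc"] for t in terms if (t,) in aicc_of):
            continue
        out.append(terms)
    return out


@pytest.mark.parametrize("seed", range(25))
def test_rank_and_filter_matches_brute_force(seed):
    mset = _random_candidate_set(seed)
    reported = models.rank_and_filter(mset)
    got = [tuple(t) for t in reported["terms"]]
    assert sorted(got) == sorted(brute_force_report(mset.table))


def test_filter_excludes_unparsimonious_pair_despite_small_delta():
    """Pair at 10.5 with a submodel at 10.0 is dropped even though its
    delta from the best model (9.5) is only 1.0."""
    terms = [("MAT_C", "MAMP_kPa"), ("MAT_C",), ("MWT_C",)]
    table = pd.DataFrame({
        "terms": terms, "k": [4, 3, 3], "n": 40,
        "logLik": [0.0, 0.0, 0.0],
        "AICc": [10.5, 10.0, 9.5],
    })
    table["delta"] = table["AICc"] - 9.5
    table["weight"] = models.akaike_weights(table["AICc"])
    mset = models.CandidateModelSet(response="r", table=table)
    got = [tuple(t) for t in models.rank_and_filter(mset)["terms"]]
    assert ("MAT_C", "MAMP_kPa") not in got
    assert set(got) == {("MAT_C",), ("MWT_C",)}


@settings(derandomize=True, max_examples=40)
@given(st.integers(0, 10**6))
def test_weights_sum_to_one_and_importance_bounds(seed):
    mset = _random_candidate_set(seed)
    assert mset.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
    imp = models.relative_importance(mset)
    assert ((imp["importance"] >= 0) & (imp["importance"] <= 1)).all()
    assert imp["is_max"].sum() >= 1


def test_equal_likelihood_importances_in_closed_form():
    """All 15 models equal logL: singles (k=3) and pairs (k=4) give two
    distinct weights; importances follow by counting."""
    terms = models.candidate_model_terms()
    n = 40
    table = pd.DataFrame({"terms": terms, "k": [len(t) + 2 for t in terms],
                          "n": n, "logLik": -50.0})
    table["AICc"] = [models.aicc(-50.0, k, n) for k in table.k]
    table["delta"] = table["AICc"] - table["AICc"].min()
    table["weight"] = models.akaike_weights(table["AICc"])
    mset = models.CandidateModelSet(response="r", table=table)
    imp = models.relative_importance(mset)
    a3 = models.aicc(-50.0, 3, n)
    a4 = models.aicc(-50.0, 4, n)
    w4 = np.exp(-(a4 - a3) / 2)
    w_single = 1 / (6 + 9 * w4)          # weight of each k=3 model
    w_pair = w4 * w_single
    expected = w_single + 3 * w_pair     # every predictor: 1 single + 3 pairs
    assert np.allclose(imp["importance"], expected, atol=1e-12)


def test_importance_recovery_from_named_predictor(default_bundle):
    """A response built from MST plus weak noise puts maximum importance
    on MST."""
    clim = default_bundle["climate_summary"]
    clim = clim[clim["season"] == "2017"]
    rng = np.random.default_rng(8)
    y = pd.Series(
        2.0 * clim["MST_C"].to_numpy()
        + rng.normal(0, 2.0 * clim["MST_C"].std() / 5, len(clim)),
        index=clim["plot_id"])
    mset = models.build_candidate_set(y, clim, response_name="synthetic")
    imp = models.relative_importance(mset)
    assert imp.loc[imp["is_max"], "predictor"].iloc[0] == "MST_C"
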