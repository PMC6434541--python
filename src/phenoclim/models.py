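"""Inferential layer: treatment collapsing, group tests, count-model family
selection, repeated measures, and the 15-model AICc variable-importance
procedure.

The attribution question — is a phenology response driven more by soil
temperature or soil moisture? — is answered by information-theoretic
multimodel inference. The three temperature predictors (MAT, MWT, MST) are
strongly mutually correlated, as are the three moisture predictors (MAMP,
DFWP, DBWP), so instead of one multiple regression the candidate set holds
15 ordinary linear models per response: the 9 one-temperature +
one-moisture pairs and the 6 singletons. Models are ranked by AICc,

    AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1),

with k counting intercept, slopes and the residual variance. Akaike
weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2) are computed over
the full 15-model set, and the relative importance of a predictor is the
sum of the weights of every model containing it. Reporting applies the
delta-AICc < 2 equivalence band plus a parsimony rule: a two-predictor
model is not reported if either of its own single-predictor submodels has
a lower AICc. The weights are never renormalized for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import itertools
import warnings

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

TEMPERATURE_PREDICTORS = ("MAT_C", "MWT_C", "MST_C")
MOISTURE_PREDICTORS = ("MAMP_kPa", "dfwp_days", "DBWP")

# ---------------------------------------------------------------------------
# two-group comparison and treatment collapsing


@dataclass(frozen=True)
class GroupComparison:
    difference: float        # warming - ambient (negative = advancement)
    se: float
    p_value: float
    untestable: bool


def compare_two_groups(warming, ambient) -> GroupComparison:
    """Two-tailed unequal-variance t test, reported as warming - ambient."""
    w = np.asarray(warming, dtype=float)
    a = np.asarray(ambient, dtype=float)
    if len(w) < 2 or len(a) < 2:
        raise ValueError("need >= 2 values per group")
    diff = float(w.mean() - a.mean())
    if w.var(ddof=1) == 0 and a.var(ddof=1) == 0:
        return GroupComparison(diff, 0.0, np.nan, untestable=True)
    se = float(np.sqrt(w.var(ddof=1) / len(w) + a.var(ddof=1) / len(a)))
    res = st.ttest_ind(w, a, equal_var=False)
    return GroupComparison(diff, se, float(res.pvalue), untestable=False)


@dataclass(frozen=True)
class CollapseDecision:
    p_control_vs_drought: float
    p_warming_vs_warmingppt: float
    collapsed: bool
    deferred: bool = False


def collapse_treatments(values: pd.Series, design: pd.DataFrame,
                        collapse_alpha: float = 0.10) -> CollapseDecision:
    """Decide whether the 4 treatments collapse to ambient vs warming.

    Runs two-tailed mean-difference tests within each pair (control vs
    drought; warming vs warming + ppt); the treatments collapse only if
    both pairs are indistinguishable at `collapse_alpha`. `values` is a
    response indexed by plot_id.
    """
    trt = design.set_index("plot_id")["treatment"]
    groups = {t: values[trt[values.index] == t].dropna() for t in
              ("control", "drought", "warming", "warming_ppt")}
    if any(len(g) < 2 for g in groups.values()):
        return CollapseDecision(np.nan, np.nan, collapsed=False, deferred=True)

    def pair_p(x, y):
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
            return 1.0 if x.mean() == y.mean() else 0.0
        return float(st.ttest_ind(x, y, equal_var=False).pvalue)

    p_cd = pair_p(groups["control"], groups["drought"])
    p_ww = pair_p(groups["warming"], groups["warming_ppt"])
    return CollapseDecision(p_cd, p_ww,
                            collapsed=(p_cd >= collapse_alpha and p_ww >= collapse_alpha))


# ---------------------------------------------------------------------------
# ANOVA with Tukey post hoc, repeated measures


def anova_with_posthoc(data: pd.DataFrame, response: str,
                       factors: tuple[str, ...]) -> dict:
    """Fixed-effect ANOVA with all-pairs Tukey-adjusted comparisons.

    With two factors the interaction is included. Tukey comparisons are
    produced per factor (and for the factor combination when there are
    two). Returns {"anova": table, "tukey": {factor: results}}.
    """
    if not 1 <= len(factors) <= 2:
        raise ValueError("one or two factors supported")
    data = data.dropna(subset=[response, *factors]).copy()
    terms = " * ".join(f"C({f})" for f in factors)
    fit = smf.ols(f"{response} ~ {terms}", data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-residual designs warn
        table = anova_lm(fit, typ=2)
    tukey = {}
    for f in factors:
        if data[f].nunique() >= 2:
            tukey[f] = pairwise_tukeyhsd(data[response], data[f])
    if len(factors) == 2:
        combo = data[factors[0]].astype(str) + ":" + data[factors[1]].astype(str)
        if combo.nunique() >= 2:
            tukey["interaction"] = pairwise_tukeyhsd(data[response], combo)
    return {"anova": table, "tukey": tukey, "fit": fit}


def logit_transform(x, eps: float = 1e-6):
    """Logit for NDVI-like responses bounded in [-1, 1]: maps via (x+1)/2."""
    p = np.clip((np.asarray(x, dtype=float) + 1.0) / 2.0, eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def repeated_measures(data: pd.DataFrame, response: str, subject: str,
                      within: str, between: str | None = None,
                      transform: str = "none", alpha: float = 0.05) -> dict:
    """Repeated-measures ANOVA with Greenhouse-Geisser sphericity handling.

    Subjects (plots) observed at every within-factor occasion enter;
    incomplete subjects are listwise-deleted (count reported). When the
    sphericity test rejects at `alpha`, within-subject p-values are
    GG-corrected; epsilon and the correction status are always reported.
    `transform="logit"` applies the bounded-NDVI logit before modelling.
    """
    import pingouin as pg

    data = data.dropna(subset=[response, subject, within]).copy()
    if data[within].nunique() < 2:
        raise ValueError("repeated measures needs >= 2 occasions")
    if transform == "logit":
        data[response] = logit_transform(data[response])
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")

    counts = data.groupby(subject)[within].nunique()
    complete = counts[counts == data[within].nunique()].index
    n_dropped = int(len(counts) - len(complete))
    data = data[data[subject].isin(complete)]

    if between is None:
        table = pg.rm_anova(data=data, dv=response, within=within,
                            subject=subject, correction=True, detailed=True)
    else:
        table = pg.mixed_anova(data=data, dv=response, within=within,
                               subject=subject, between=between, correction=True)

    two_occasions = data[within].nunique() == 2
    spher = None
    if not two_occasions:
        spher = pg.sphericity(data=data, dv=response, within=within, subject=subject)
    eps = 1.0 if two_occasions else float(
        pg.epsilon(data=data, dv=response, within=within, subject=subject,
                   correction="gg")
    )
    violated = (spher is not None) and (spher.pval < alpha)

    table = table.copy()
    if "p_GG_corr" in table.columns:
        table["p_reported"] = np.where(
            violated & table["p_GG_corr"].notna(),
            table["p_GG_corr"], table["p_unc"],
        )
    else:
        table["p_reported"] = table["p_unc"]
    return {
        "table": table,
        "epsilon_gg": eps,
        "sphericity_violated": bool(violated),
        "sphericity_p": float(spher.pval) if spher is not None else np.nan,
        "n_subjects_dropped": n_dropped,
    }


# ---------------------------------------------------------------------------
# count-model family selection


COUNT_FAMILIES = ("poisson", "negative_binomial", "zip", "zinb")


def _fit_count(family: str, formula: str, data: pd.DataFrame):
    kwargs = dict(formula=formula, data=data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "poisson":
            model = smf.poisson(**kwargs)
            return model.fit(disp=0)
        if family == "negative_binomial":
            model = smf.negativebinomial(**kwargs)
            return model.fit(disp=0, maxiter=200)
        if family == "zip":
            model = sm.ZeroInflatedPoisson.from_formula(
                formula, data, inflation="logit")
            return model.fit(disp=0, maxiter=200, method="bfgs")
        if family == "zinb":
            model = sm.ZeroInflatedNegativeBinomialP.from_formula(
                formula, data, inflation="logit")
            return model.fit(disp=0, maxiter=200, method="bfgs")
    raise ValueError(f"unknown family {family!r}")


@dataclass
class CountModelSelection:
    family: str
    fit: object
    aic_table: pd.DataFrame
    gof_chi2: float
    gof_df: int
    gof_p: float
    effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_site: dict = field(default_factory=dict)
    all_zero: bool = False


def select_count_model(counts: pd.Series, design: pd.DataFrame,
                       factors: tuple[str, ...] = ("site", "treatment"),
                       families: tuple[str, ...] = COUNT_FAMILIES,
                       interaction_alpha: float = 0.05) -> CountModelSelection:
    """Best-AIC count GLM among Poisson / NB / zero-inflated families.

    `counts` is an integer abundance per plot (indexed by plot_id). The
    winner is the converged family with lowest AIC; goodness of fit is a
    chi-square on the Pearson statistic against the residual df; factor
    effects are likelihood-ratio chi-square tests of nested fits in the
    winning family. On a significant interaction (both factors supplied)
    the selection is repeated within each site.
    """
    y = counts.dropna().astype(int)
    if (y < 0).any():
        raise ValueError("counts must be nonnegative integers")
    if (y == 0).all():
        return CountModelSelection(family="none", fit=None,
                                   aic_table=pd.DataFrame(),
                                   gof_chi2=np.nan, gof_df=0, gof_p=np.nan,
                                   all_zero=True)
    data = design.set_index("plot_id").loc[y.index, list(factors)].copy()
    data["count"] = y.to_numpy()
    usable = [f for f in factors if data[f].nunique() >= 2]
    rhs = " * ".join(f"C({f})" for f in usable) if usable else "1"
    formula = f"count ~ {rhs}"

    rows, fits = [], {}
    for fam in families:
        try:
            res = _fit_count(fam, formula, data)
            if not np.isfinite(res.llf):
                raise ValueError("non-finite log-likelihood")
            converged = getattr(res, "mle_retvals", {}).get("converged", True)
            fits[fam] = res
            rows.append({"family": fam, "aic": float(res.aic),
                         "llf": float(res.llf), "converged": bool(converged)})
        except Exception as exc:  # non-convergence excludes the family
            rows.append({"family": fam, "aic": np.nan, "llf": np.nan,
                         "converged": False, "error": str(exc)[:80]})
    aic_table = pd.DataFrame(rows)
    ok = aic_table.dropna(subset=["aic"])
    if ok.empty:
        raise RuntimeError("no count-model family converged")
    winner = ok.loc[ok["aic"].idxmin(), "family"]
    best = fits[winner]

    mu = np.asarray(best.predict())
    pearson = float(np.sum((data["count"].to_numpy() - mu) ** 2 / np.maximum(mu, 1e-10)))
    gof_df = max(int(best.nobs - best.df_model - 1), 1)
    gof_p = float(st.chi2.sf(pearson, gof_df))

    effects = _lr_effects(winner, data, usable)
    sel = CountModelSelection(family=winner, fit=best, aic_table=aic_table,
                              gof_chi2=pearson, gof_df=gof_df, gof_p=gof_p,
                              effects=effects)

    inter = effects[effects["term"] == "interaction"]
    if len(usable) == 2 and len(inter) and inter["p"].iloc[0] < interaction_alpha:
        for site, grp in data.groupby(usable[0]):
            sub_counts = pd.Series(grp["count"].to_numpy(), index=grp.index)
            sub_design = design[design["plot_id"].isin(grp.index)]
            try:
                sel.per_site[site] = select_count_model(
                    sub_counts, sub_design, factors=(usable[1],),
                    families=families)
            except Exception:
                sel.per_site[site] = None
    return sel


def _lr_effects(family: str, data: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """Likelihood-ratio chi-square tests for each factor and the interaction."""
    if not factors:
        return pd.DataFrame(columns=["term", "lr_chi2", "df", "p"])

    def fit_rhs(rhs):
        res = _fit_count(family, f"count ~ {rhs}", data)
        return float(res.llf), int(res.df_model)

    rows = []
    full_rhs = " * ".join(f"C({f})" for f in factors)
    try:
        ll_full, df_full = fit_rhs(full_rhs)
        if len(factors) == 2:
            add_rhs = " + ".join(f"C({f})" for f in factors)
            ll_add, df_add = fit_rhs(add_rhs)
            lr = 2 * (ll_full - ll_add)
            df = max(df_full - df_add, 1)
            rows.append({"term": "interaction", "lr_chi2": lr, "df": df,
                         "p": float(st.chi2.sf(max(lr, 0), df))})
            base_ll, base_df = ll_add, df_add
            for f in factors:
                others = [g for g in factors if g != f]
                red_rhs = " + ".join(f"C({g})" for g in others) or "1"
                ll_red, df_red = fit_rhs(red_rhs)
                lr = 2 * (base_ll - ll_red)
                df = max(base_df - df_red, 1)
                rows.append({"term": f, "lr_chi2": lr, "df": df,
                             "p": float(st.chi2.sf(max(lr, 0), df))})
        else:
            ll_null, df_null = fit_rhs("1")
            lr = 2 * (ll_full - ll_null)
            df = max(df_full - df_null, 1)
            rows.append({"term": factors[0], "lr_chi2": lr, "df": df,
                         "p": float(st.chi2.sf(max(lr, 0), df))})
    except Exception:
        pass
    return pd.DataFrame(rows, columns=["term", "lr_chi2", "df", "p"])


# ---------------------------------------------------------------------------
# 15-model AICc candidate set


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """exp(-delta/2) normalized over the candidate set."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def candidate_model_terms(
        temperature: tuple[str, ...] = TEMPERATURE_PREDICTORS,
        moisture: tuple[str, ...] = MOISTURE_PREDICTORS) -> list[tuple[str, ...]]:
    """The 15 model term-sets: 9 temperature x moisture pairs + 6 singletons."""
    pairs = [(t, m) for t, m in itertools.product(temperature, moisture)]
    singles = [(p,) for p in (*temperature, *moisture)]
    return pairs + singles


@dataclass
class CandidateModelSet:
    response: str
    table: pd.DataFrame   # terms, k, n, logLik, AICc, delta, weight
    dropped: list = field(default_factory=list)


def build_candidate_set(response: pd.Series, climate: pd.DataFrame,
                        response_name: str = "response",
                        temperature: tuple[str, ...] = TEMPERATURE_PREDICTORS,
                        moisture: tuple[str, ...] = MOISTURE_PREDICTORS
                        ) -> CandidateModelSet:
    """Fit the 15-model AICc candidate set for one response.

    `response` is indexed by plot_id; `climate` holds one row per plot_id
    with the six predictor columns. Missing values are deleted pairwise
    per model (n is recorded per model). Constant predictors drop the
    models containing them; k counts intercept, slopes and the residual
    variance.
    """
    clim = climate.set_index("plot_id") if "plot_id" in climate.columns else climate
    merged = clim.join(response.rename("_y"), how="inner")

    constant = [p for p in (*temperature, *moisture)
                if merged[p].dropna().nunique() <= 1]
    rows, dropped = [], []
    for terms in candidate_model_terms(temperature, moisture):
        if any(t in constant for t in terms):
            dropped.append(terms)
            continue
        sub = merged[["_y", *terms]].dropna()
        n = len(sub)
        k = len(terms) + 2  # intercept + slopes + residual variance
        if n <= k + 1:
            dropped.append(terms)
            continue
        X = sm.add_constant(sub[list(terms)].to_numpy())
        fit = sm.OLS(sub["_y"].to_numpy(), X).fit()
        rows.append({"terms": terms, "k": k, "n": n, "logLik": float(fit.llf),
                     "AICc": aicc(float(fit.llf), k, n)})
    if not rows:
        raise ValueError(f"no fittable models for response {response_name!r}")
    table = pd.DataFrame(rows)
    table["delta"] = table["AICc"] - table["AICc"].min()
    table["weight"] = akaike_weights(table["AICc"])
    table = table.sort_values("delta", ignore_index=True)
    return CandidateModelSet(response=response_name, table=table, dropped=dropped)


def rank_and_filter(model_set: CandidateModelSet,
                    delta_equiv: float = 2.0) -> pd.DataFrame:
    """Models reported as equivalent: delta < 2, minus unparsimonious pairs.

    A two-predictor model is excluded from the report when its AICc
    exceeds that of either of its own single-predictor submodels. Weights
    are not renormalized.
    """
    table = model_set.table
    by_terms = {tuple(t): a for t, a in zip(table["terms"], table["AICc"])}
    keep = []
    for _, row in table.iterrows():
        if row["delta"] >= delta_equiv:
            continue
        terms = tuple(row["terms"])
        if len(terms) == 2:
            subs = [by_terms.get((t,)) for t in terms]
            if any(s is not None and row["AICc"] > s for s in subs):
                continue
        keep.append(row)
    out = pd.DataFrame(keep).reset_index(drop=True)
    return out if len(out) else table.iloc[0:0].copy()


def relative_importance(model_set: CandidateModelSet,
                        temperature: tuple[str, ...] = TEMPERATURE_PREDICTORS,
                        moisture: tuple[str, ...] = MOISTURE_PREDICTORS
                        ) -> pd.DataFrame:
    """Per-predictor importance: sum of Akaike weights over containing models.

    Computed over the full candidate set (never the filtered report). The
    single highest value is flagged as the most important predictor.
    """
    table = model_set.table
    rows = []
    for p in (*temperature, *moisture):
        mask = [p in terms for terms in table["terms"]]
        rows.append({"response": model_set.response, "predictor": p,
                     "importance": float(table.loc[mask, "weight"].sum())})
    out = pd.DataFrame(rows)
    out["is_max"] = out["importance"] == out["importance"].max()
    return out
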