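# Methods

`phenoclim` implements the analysis of a factorial climate-manipulation
experiment on Mediterranean-climate prairie: three sites along a
latitudinal gradient, each with four treatments (control, drought,
warming, warming + additional precipitation) in five replicate plots.
The pipeline has four scientific layers — soil-water summarization,
community (NDVI) phenometrics, population (flowering) phenometrics, and
information-theoretic attribution — plus a synthetic-experiment
generator that provides ground truth for validation. This note records
the models, the parameters that matter, and the choices made where the
design was genuinely open.

## Soil water and climate summaries

Volumetric water content (VWC) is not comparable across soils, so each
site's texture (sand, clay, organic-matter mass fractions) is converted
to a moisture-retention curve with the Saxton–Rawls pedotransfer
regressions: anchors θ₁₅₀₀ (VWC at −1500 kPa, permanent wilting point),
θ₃₃ (−33 kPa, field capacity) and θs (saturation). Between θ₁₅₀₀ and
θ₃₃ tension follows the power law ψ = −A·θ^(−B) with
B = ln(1500/33)/ln(θ₃₃/θ₁₅₀₀) and A = 33·θ₃₃^B; below θ₁₅₀₀ the power
law is extrapolated (so values below the wilting point remain
representable); above θ₃₃ tension falls linearly to zero at θs. The
air-entry tension from the regressions is retained as curve metadata
but the wet segment is taken to zero so ψ(θ) is continuous — the
difference is a few kPa near saturation and is immaterial to every
downstream summary, which is governed by the dry end. Gravel, salinity
and density adjustments of the full pedotransfer system are omitted:
only ψ from VWC is used.

Six climate summaries are computed per plot over a Jul-15 → Jul-15
annual window (half-open; daily means first, then statistics):

* **MAT, MWT, MST** — mean annual, winter (Dec 1–Feb 28) and spring
  (Mar 1–May 31) soil temperature, °C. The seasonal windows are encoded
  half-open as [Dec-1, Mar-1) and [Mar-1, Jun-1) so the stated inclusive
  end dates are covered.
* **MAMP** — mean annual matric potential after clamping at −1500 kPa.
* **DFWP** — date of first wilting point, the first day whose daily-mean
  ψ is strictly below −1500 kPa (also exported as days since the window
  start, for regression). Missing when never reached (mesic plots);
  such plots drop out of DFWP models pairwise.
* **DBWP** — count of days below the wilting point. Strict inequality
  throughout: a day at exactly −1500 kPa does not count, matching the
  clamping convention ("any value < −1500 became −1500").

## NDVI phenometrics

All detectors operate on the sampled dates themselves — no
interpolation, smoothing or curve fitting — so the date resolution
equals the sampling interval. Per plot and Jul→Jul season:

* **Peak biomass**: maximum NDVI; ties break to the earliest date.
* **Date of senescence**: first sampled date after the peak with
  NDVI ≤ 0.80 × peak. Never crossed ⇒ censored flag, not a date.
* **Rate of senescence**: among all runs of three consecutive samples
  (two allowed where senescence is too fast for three to be linear),
  the run maximizing the endpoint decline (first − last) is selected and
  the least-squares slope of NDVI on day over that run is returned.
  Endpoint decline is used rather than summed pairwise drops because
  "greatest decline" most plainly means total decline, and the two
  criteria coincide on monotone windows; least squares because a slope
  over three unevenly spaced points is otherwise ill-defined. A best
  run that increases is returned with a nonsenescent flag. By default
  the search covers the whole season window; a post-peak restriction is
  available as a switch.
* **Green-up**: first sampled date after the summer minimum with
  NDVI ≥ 1.25 × minimum. For minima at or below a floor (default 0.05)
  the multiplicative rule degenerates, so an additive rule
  (minimum + 0.05) substitutes, flagged. The summer minimum is searched
  in the first 92 days of the season window (mid-July to mid-October).
* **Growing season length**: integer days from fall green-up to the
  following date of senescence; undefined (excluded pairwise) if either
  is censored.

## Flowering phenometrics

From repeated counts of open flowers (reproductive stalks for the
grass) and flowering individuals per plot × species: FFD is the first
survey date with any open flower; PFD the date of maximum open flowers
(earliest on ties). The plot-season abundance is the maximum
flowering-individual count over the surveys — a plant that flowered in
any week is counted once and cross-week double counting is avoided;
this is an interpretive choice, since weekly tallies do not define a
unique season abundance. Treatment tables report the median over the
five replicates, zeros included.

Temperature sensitivity of an event is computed per warmed plot as
(date_warm − mean ambient date)/ΔT with ΔT = 2.5 °C; negative values
are advancement. When both groups are internally constant the contrast
is flagged untestable rather than given a p-value. Species present at
only one site are excluded from cross-site environmental models;
combinations flagged uncountable in the field are excluded by a config
list.

## Statistical layer

* **Treatment collapsing**: the four treatments reduce to ambient
  (control, drought) vs warming (warming, warming + ppt) only when
  two-tailed within-pair tests both fail to reject at
  `collapse_alpha` = 0.10 (configurable; chosen because the observed
  within-pair contrasts in this design are reported against a 0.10
  marginal-significance convention).
* **Group comparisons**: Welch (unequal-variance) two-tailed t tests,
  reported as warming − ambient. ANOVA with Tukey-adjusted all-pairs
  post hoc comparisons; adjustment only within a post-hoc family, no
  across-response correction.
* **Repeated measures**: within-subject effects are Greenhouse–Geisser
  corrected whenever the sphericity test rejects at 0.05; ε and the
  correction status are always reported. NDVI-valued responses can be
  logit-transformed via x ↦ logit((x+1)/2) with a 10⁻⁶ clip.
* **Count models**: flowering abundances are fit by Poisson, negative
  binomial, zero-inflated Poisson and zero-inflated negative binomial;
  the lowest-AIC converged family wins, goodness of fit is a Pearson
  chi-square against residual df, factor effects are likelihood-ratio
  chi-square tests on nested fits, and a significant site × treatment
  interaction triggers per-site refits.
* **Attribution**: the three temperature and three moisture summaries
  are strongly correlated within pools, so each response gets a
  15-model candidate set (9 temperature × moisture pairs + 6
  singletons) of ordinary linear regressions, ranked by
  AICc = −2logL + 2k + 2k(k+1)/(n−k−1) with k counting intercept,
  slopes and the residual variance (the Burnham–Anderson convention —
  stated explicitly because conventions differ). Akaike weights are
  computed over the full set; a predictor's relative importance is the
  summed weight of its models. Reporting applies the δAICc < 2
  equivalence band minus any two-predictor model beaten by one of its
  own single-predictor submodels; weights are never renormalized for
  reporting, because importance is defined over all models. Models are
  fit across all plots pooled over sites by default; per-site fitting
  is available.

## Synthetic experiment

The generator's defaults are the study conditions: +2.5 °C canopy
offset with a damped 0.8× soil offset, 40% infiltration exclusion on
drought plots, a nightly 5-mm irrigation pulse for warming + ppt plots
on days below 95% of the same-site control-mean VWC, a 20-day warming
advance of the NDVI peak/senescence phase, a flowering sensitivity of
2.8 d/°C (≈7 d advance at ΔT = 2.5), NDVI noise σ = 0.02, weekly NDVI
sampling (biweekly at the southern site), and zero-inflated
negative-binomial reproductive abundances whose mean rises and
zero-inflation falls from south to north. Simulation runs daily from
November 2015 through August 2018 so both Jul→Jul analysis seasons are
covered and the first window contains a natural wet→dry transition.

Daily canopy temperature is a site sinusoid plus shared AR(1) noise and
independent plot noise. Soil temperature adds site-level winter/spring
anomalies and persistent per-plot microsite offsets with independent
annual/winter/spring components; these make MAT, MWT and MST strongly
but imperfectly correlated (r ≈ 0.55–0.9), the regime the attribution
machinery assumes — without them the three would be affine images of
(site, treatment) and no method could separate them. Soil water is a
single-layer 300-mm bucket: shared site rainfall (wet-season
Bernoulli × gamma) minus temperature-driven evapotranspiration, bounded
between a residual and the texture's saturation; this produces the
Mediterranean regime of near-saturated winters and summers below the
wilting point, ordered south → north. Site soil textures are plausible
placeholders (no site-specific measurements exist to copy).

Latent greenness is a rising logistic (midpoint tied to the first
post-summer day the plot's matric potential exceeds −1500 kPa, plus a
10-day lag) times a falling logistic (senescence midpoint, advanced
20 d under warming) times a slow spring-growth tilt (0.004/day) that
pins a pronounced peak ≈25 d before the senescence midpoint, so the
injected advance propagates to the peak nearly 1:1. Observed NDVI is
latent + Gaussian noise clipped to [−1, 1]. Open-flower counts follow a
deterministic rounded Gaussian pulse (σ = 7 d) scaled by the plot's
drawn number of individuals. Ground truth for every phenometric is
computed by applying the definitional detectors to the noise-free daily
latent curves, so with zero noise and daily sampling the pipeline must
recover truth exactly — and does, which validates the plumbing, not the
field realism of the curves.

What the generator does **not** emulate: mechanistic plant physiology,
spatially explicit rainfall, multi-layer soils, observation error in
counts, species-specific climate responses, or the idiosyncratic
site × species abundance patterns of real prairie. Passing recovery
tests therefore demonstrates that the estimators are consistent with
their definitions under the assumed noise structure, not that the
assumed structure matches any particular prairie.

## Numerical choices and problem sizes

Ties in maxima/minima always break to the earliest date (stable and
consistently biased). Censored detector outputs propagate as missing
values and exclude plots pairwise. Candidate models with n ≤ k + 1
(AICc undefined) or containing a constant predictor are dropped with
the set size reported. Count-model families that fail to converge are
excluded from the AIC comparison and logged.

Validation problem sizes were chosen to keep the full suite fast on one
CPU: 1,000 randomized series for the detector/oracle sweep, 100 seeded
experiments for peak-advance recovery, 200 runs each for attribution
recovery and count-family selection, and 1,000 replicates for the
collapse-rule calibration.

## Known limitations

The pedotransfer regressions are least reliable for extreme textures
(very high sand or organic matter); textures whose regressions produce
non-ordered anchors are rejected rather than patched. The
repeated-measures wrapper supports one between-subject factor (site and
treatment are combined into one factor when both are needed). DFWP is
undefined for plots that never reach wilting, which biases DFWP models
toward drier plots; this mirrors the field situation and is handled by
pairwise deletion, not imputation.
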