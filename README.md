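# phenoclim

Analysis pipeline for **warming × moisture manipulation experiments on
plant phenology**, built for factorial climate experiments in
Mediterranean-climate grasslands: several sites along a climate
gradient, each with control / drought / warming / warming + added
precipitation plots, monitored with dataloggers (canopy and soil
temperature, volumetric water content), repeated plot-level NDVI
surveys, and flowering counts of focal species.

It answers the question such experiments are built for: *is the timing
of plant phenology driven more by soil temperature or by soil
moisture?* — and provides every step in between:

* **Soil water** (`phenoclim.soil_water`) — texture-based pedotransfer
  (Saxton–Rawls moisture regressions) converts VWC to matric potential
  ψ (kPa), then summarizes each plot-year as MAT/MWT/MST (mean
  annual/winter/spring soil temperature), MAMP (mean annual ψ clamped
  at the −1500 kPa wilting point), DFWP (date of first wilting point)
  and DBWP (days below wilting point).
* **NDVI phenometrics** (`phenoclim.ndvi_phenology`) — date of peak
  biomass (max NDVI), date of senescence (first date ≤ 80% of peak),
  rate of senescence (least-squares slope over the steepest 3-point
  decline), fall green-up (first date ≥ 125% of the summer minimum) and
  growing season length, all on sampled dates with explicit censoring.
* **Flowering phenology** (`phenoclim.flowering`) — first and peak
  flowering dates (FFD/PFD), reproductive abundances, and temperature
  sensitivity (date_warm − mean date_ambient)/ΔT in days/°C.
* **Statistics** (`phenoclim.models`) — treatment collapsing into
  ambient vs warming categories, Welch t tests, ANOVA + Tukey,
  repeated measures with Greenhouse–Geisser correction, count-model
  family selection (Poisson/NB/zero-inflated), and the 15-model AICc
  candidate sets whose Akaike-weight sums give each predictor's
  **relative variable importance**:

  AICc = −2 log L + 2k + 2k(k+1)/(n−k−1),  ω_i = exp(−δ_i/2)/Σ exp(−δ_j/2),
  importance(x) = Σ ω_i over models containing x.

* **Synthetic experiments** (`phenoclim.synthetic`) — a generator that
  emulates the full design (3 sites × 4 treatments × 5 replicates,
  +2.5 °C warming, 40% rain exclusion, feedback irrigation, Mediterranean
  soil-moisture seasonality, treatment-shifted greenness and flowering)
  with stored ground truth, so the whole pipeline is testable with no
  field data.

## Worked example

```python
from phenoclim import AnalysisConfig, run_pipeline
from phenoclim.synthetic import generate_experiment

exp = generate_experiment(seed=1)          # 60 plots, 2 seasons, with truth
textures = {s: spec.texture for s, spec in exp.specs.items()}
bundle = run_pipeline(AnalysisConfig(), exp.design, exp.env,
                      exp.ndvi, exp.flowering, textures)

m = bundle["ndvi_metrics"].merge(exp.design, on="plot_id")
peak = m[m.season == "2018"].dropna(subset=["peak_date"])
by_cat = peak.groupby("temperature_category")["peak_date"].apply(
    lambda s: s.map(lambda d: d.toordinal()).mean())
print(f"peak advance under warming: {by_cat['ambient'] - by_cat['warming']:.1f} d")

imp = bundle["importance"]
print(imp[imp.is_max & (imp.response == "peak_date_2018")]
      [["response", "predictor", "importance"]].to_string(index=False))
```

prints

```
peak advance under warming: 18.7 d
      response predictor  importance
peak_date_2018     MAT_C    0.752957
```

that is: across the 60 plots the warming-category plots reached peak
biomass 18.7 days earlier than ambient plots (the generator injected a
20-day advance; weekly sampling quantizes the estimate), and among the
six climate predictors the mean annual soil temperature carries the
highest relative importance for the peak date — a temperature, not
moisture, attribution.

The same stages are scriptable from a shell:

```bash
phenoclim simulate  --seed 1 --out-dir sim/
phenoclim run-all   --in-dir sim/ --out-dir results/
```

which writes `climate_summary.csv`, `ndvi_metrics.csv`,
`flowering_metrics.csv`, `sensitivity.csv`, `collapse.csv`,
`model_tables.csv` and `importance.csv`, each with provenance recorded
in `provenance.json`.

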