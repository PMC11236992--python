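# thermoshift

Thermophilization analysis for repeatedly censused forest plots.

As climate warms, tree communities are expected to shift toward species
affiliated with warmer conditions — *thermophilization*. This package
implements the full analysis chain used to detect and dissect that signal
in forest inventory data, for ecologists working with plot re-census
campaigns, occurrence archives and gridded climatologies:

1. **Species climate affiliations** — clean and grid-deduplicate occurrence
   records, extract a climatology, and estimate each species' thermal
   optimum (mean MAT across its occurrence cells), precipitation optimum,
   and niche breadth (q95 − q5 of MAT), with an error-versus-record-count
   curve behind the inclusion threshold (default ≥ 10 records).
2. **Community indices** — the community temperature index of a plot census
   is the community-weighted mean of stem optima,
   `CTI = Σ w_i T_opt(s_i) / Σ w_i`, with `w_i = 1` (CTI_Stem) or basal
   area `π(D_i/2)²` (CTI_BA); same machinery for CPI or any species trait.
3. **Demographic partition** — change between first and last census splits
   exactly into recruitment + mortality (+ growth under basal-area
   weighting) via the Alive_F / Alive_L / Survive_F / Survive_L stem sets,
   plus jackknife per-species contributions
   `(ΔCTI_-s − ΔCTI_all)/ΔCTI_all` and size-class summaries.
4. **Carbon dynamics** — plot-level Weibull / log-log height–diameter
   models, the pantropical allometry `AGB = 0.0673 (ρD²H)^0.976` with
   AGC = 45.6% AGB, and census-interval-corrected gain/loss fluxes.
5. **Inference** — exact one-sample Wilcoxon signed-rank (V statistic),
   percentile bootstrap CIs, Spearman/Kruskal–Wallis, climate trend slopes
   and the cross-sectional CTI-vs-MAT regression.
6. **Synthetic study generator** — climate grids, occurrence clouds and
   multi-census stem dynamics with a tunable, known thermophilization
   signal, so every stage is validated by parameter recovery.

See `docs/methods.md` for models, conventions and design decisions.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with known truth (script 01 writes the input bundle the rest read):

```bash
python analysis/01_simulate_study.py
python analysis/02_thermal_optima.py
python analysis/03_community_trends.py
python analysis/04_carbon_budget.py
python analysis/05_validation_experiments.py
```

Script 03 prints, for the default bundle (seed 1):

```
dCTI_stem: mean +0.0286 degC/y (bootstrap 95% CI +0.0248..+0.0323), V = 153, P = 0.000; 17/17 plots increasing
dCTI_basal_area: mean +0.0194 degC/y (bootstrap 95% CI +0.0149..+0.0238), V = 153, P = 0.000; 17/17 plots increasing
partition (stem): recruitment +0.0168, mortality +0.0118, growth +0.0000 degC/y
```

The simulated community warms at +0.029 °C/y under stem weighting (the
simulator's event-log truth is +0.028 °C/y — the pipeline recovers it), the
basal-area metric responds more slowly because large stems turn over
slowly, and the imposed recruitment bias shows up as the dominant partition
component, with a smaller mortality share. The trend is significant by the
signed-rank test (V is the sum of positive ranks over the 17 per-plot
rates). Script 04 closes the carbon budget:

```
mean annual fluxes (interval-corrected, Mg C/ha/y):
    gain_growth        +1.38
    gain_recruitment   +0.28
    loss_mortality     +1.12
    net                +0.54
17/17 plots acted as a carbon sink
```

and script 05 checks the estimators against ground truth:

```
trend recovery: slope 1.002 (target 1), R^2 0.998 over 200 replicate studies
null calibration: Wilcoxon rejects 6.0% at alpha = 5% over 500 null studies
```

Equivalent shell entry points exist (`thermoshift simulate|optima|cti|
carbon|run ...`); `thermoshift run --config run.yaml --out-dir out/` drives
everything from one YAML file and writes CSV tables, `report.json` and a
reproducibility `manifest.json`.

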