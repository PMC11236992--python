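# Methods

`thermoshift` implements a complete thermophilization analysis for
repeatedly censused forest inventory plots: from occurrence records and
stem tables to species climate optima, community-weighted indices, the
demographic anatomy of their change, and the plots' aboveground carbon
budget. This note records the models, the conventions that the numbers
depend on, and the design choices made where the design was genuinely open.

## Species climate affiliations

A species' **thermal optimum** `t_opt` is the arithmetic mean of the mean
annual temperature (MAT) of the climatology grid cells holding its cleaned
occurrence records; the precipitation optimum `p_opt` is defined identically
on the MAP grid. **Niche breadth** is the 95th minus 5th percentile of those
MAT values. Quantiles use linear interpolation between order statistics
(`h = (n-1)p + 1`); the convention is fixed here so tests can be exact.

Cleaning is ordered: provider-flagged records, then (optionally) records
before a year cutoff, then records over nodata cells (water, outside the
climatology), and finally deduplication to one record per species per grid
cell. Dedupe runs last so the retained cell representative is always a
clean record. Deduplication is per species: two species co-occurring in one
cell each keep a record. Grid cells are half-open `[edge, edge + size)` on
both axes with the origin at the south-west edge, so every in-bounds point
falls in exactly one cell.

Optimum precision grows with record count. `threshold_error_curve`
subsamples a species' records **without replacement** (100 replicates per
size by default, seeded) and reports the mean absolute deviation of the
subsampled optimum from the full-record optimum. The inclusion threshold is
deliberately a configuration value (default 10 records, with presets 0 and
30 for sensitivity analyses) rather than an automated change-point: the
curve is the evidence, the choice is the analyst's.

## Community indices and their decomposition

For a plot census, the community temperature index is the weighted mean of
living stems' species optima, weighted equally per stem (`CTI_Stem`) or by
basal area `pi (D/2)^2` (`CTI_BA`); the same machinery serves `CPI` and any
other species attribute (e.g. wood density). Stems whose species carries no
attribute — species below the record threshold, or genus/family-only
determinations (recorded under an `Indet` sentinel) — are dropped and the
weights renormalized over the covered remainder; the covered fraction is
reported as `coverage`. Renormalization (rather than dividing by all stems)
keeps the index on the attribute's scale; it moves levels, not trends.

Annual rates of change use the first and last census only:
`(I_last - I_first) / interval`, with intervals as decimal-year differences.
Per-interval rates are also emitted for interval-level analyses.

Change is decomposed with four stem sets: `Alive_F` (alive at first
census), `Alive_L` (alive at last), and the survivors valued at first-census
(`Survive_F`) and last-census (`Survive_L`) sizes. Under stem weighting the
survivor index is size-free, and

    mortality   = I(Survive)  - I(Alive_F)
    recruitment = I(Alive_L)  - I(Survive)

Under basal-area weighting the package uses the three-term chain

    mortality   = I(Survive_F) - I(Alive_F)
    growth      = I(Survive_L) - I(Survive_F)
    recruitment = I(Alive_L)   - I(Survive_L)

which is the unique ordering that telescopes exactly to the total while
reducing to the stem-weighting formulas as a special case. A literal
two-term variant (`Survive_L - Alive_F` / `Alive_L - Survive_F`), which does
not telescope under basal-area weighting, is available behind
`literal_two_term=True` for comparison. Survivor species identity is taken
from the first census when determinations conflict. Additivity of the
components to the total (within 1e-10) is asserted property-style in the
test suite on hundreds of random census pairs.

**Jackknife contributions.** The baseline trend is the unweighted mean of
per-plot endpoint annual rates across plots. Each species is removed in
turn — its stems dropped entirely, not treated as attribute-missing — and
the contribution formed as `(rate_jackknife - rate_all) / rate_all`;
negative values mark species that strengthen the trend. For reporting, the
signed square root (transform absolute values, reapply sign) compresses the
heavy tail while preserving order and sign. Contributions are undefined
when the baseline trend is zero; that is an error, not a zero.

**Size classes** are half-open on diameter: `[10,30)`, `[30,50)`, `[50,70)`,
`>=70` cm, evaluated on the first census only so each stem enters once.

## Carbon stocks and fluxes

Tree aboveground biomass uses the pantropical allometry
`AGB = 0.0673 (rho D^2 H)^0.976` (kg; wood density rho in g cm^-3, D in cm,
H in m), and aboveground carbon is 45.6% of AGB. Wood density resolves at
the finest taxonomic level available — species, genus mean, family mean,
dataset mean — with the level recorded per species so matching is
auditable.

Heights always come from a plot-level height–diameter model (measured
heights inform the fit, not individual trees). Both a three-parameter
Weibull `H = a (1 - exp(-(D/b)^c))` and a log-log `ln H = a + b ln D` model
are fitted to the plot's measured pairs (about 60 per plot in the
generator, floor 10 configurable); the family with lower residual standard
error on the height scale is selected, each family's parameter count
charged to its degrees of freedom. A non-convergent Weibull falls back to
log-log with a warning. No Baskerville-style back-transform correction is
applied to the log-log predictions; with the small residual scatter of
plot-level fits the correction is well under the allometry's own
uncertainty, and omitting it keeps predictions strictly reproducible from
the two parameters.

Per interval `T`, uncorrected fluxes (Mg C ha^-1 y^-1) are growth of
survivors, final AGC of recruits, and initial AGC of deaths, each summed
and divided by `T`; dead trees are valued at their last live measurement.
Because dynamics between visits are unobserved, two correction terms are
estimated from the plot's own annualized per-capita rates and added to a
gain and to the loss simultaneously (net is unchanged; corrected gains and
losses never fall below uncorrected):

* **Growth of trees that died within the interval.** Under a uniform
  death-time assumption each dead tree grew `ghat T/2` before dying, with
  `ghat` the survivors' mean annual AGC increment.
* **Stems that recruited and died unobserved.** With recruitment rate `r`
  (stems/y) and annual per-capita mortality `m` (from the interval's death
  count), the expected count is `r * int_0^T (1 - (1-m)^(T-t)) dt`
  — `O(r m T^2 / 2)` — each valued at the mean AGC of an observed recruit.

Both terms vanish as `T -> 0` at fixed rates; the closed forms are exposed
as `dead_tree_growth_carbon` and `unobserved_recruit_carbon` and tested
against their limit bounds.

## Statistics

The cross-plot trend test is the one-sample Wilcoxon signed-rank test.
Exact zeros are dropped before ranking (the standard signed-rank
convention). For n <= 25 the two-sided p-value is exact: the null
distribution of `V` (sum of positive midranks, the R convention) is built
by generating-function convolution over the observed ranks, which remains
the exact permutation distribution under ties. Larger samples use the
normal approximation with tie correction and a continuity correction.
Confidence intervals of mean rates use the percentile bootstrap (1000
resamples with replacement by default, seeded); the percentile method was
chosen over BCa as the simplest verifiable match to the reporting style
used for this kind of trend. An intercept-only OLS (equivalent to the
one-sample t-test) is emitted as a secondary cross-check, as is a
leave-one-plot-out loop re-running the Wilcoxon test.

Spearman rank correlation (midrank ties), Kruskal–Wallis (tie-corrected,
chi-square on k-1 df; all-identical data gives H = 0 by convention), annual
climate trends (OLS slope on year) and the cross-sectional CTI-versus-MAT
regression (slope, SE, t, R^2, plus a `lag` flag when the slope is below 1)
delegate to scipy/statsmodels behind a thin, typed surface.

Out of scope by design: the mixed-effects (Satterthwaite) test of
size-class optima — the package emits the descriptive per-class summary and
leaves the model to dedicated mixed-model tooling — and all-subsets
AIC-weight model averaging of species-contribution correlates; bivariate
Spearman correlations serve that purpose here.

## The synthetic study

The generator emulates the study design this analysis targets, with known
ground truth. Its defaults are fixed to the emulated conditions: 17
one-hectare plots evenly spaced on a 10–23 °C MAT gradient, three censuses
at 2010.5 / 2016.5 / 2022.5, 560 initial stems per plot (>= 10 cm), 200
species, occurrence counts 3 + Exponential(89) per species (mean ~92, SD
~89), niche width sigma_s = 3 °C, and a 10-record inclusion threshold.
Demographic rates are field-typical for montane tropical forest and were
chosen once: baseline mortality 1.5 %/y, recruitment 8 stems/ha/y, diameter
growth 0.20 +/- 0.15 cm/y, initial diameters 10 + Exponential(8 cm) for a
reverse-J size structure (a `large_stem_preset` triples the scale to skew
mass toward very large stems). The default biases — recruitment 0.2 and
mortality 0.1 log-odds per °C of species optimum — impose a clear,
detectable thermophilization signal (realized trend about +0.03 °C/y at
defaults); weaker, study-like signals are a configuration choice, and the
recovery experiments sweep the bias deliberately.

Mechanics worth knowing when interpreting results:

* The MAT grid is a deterministic lapse-rate ramp along the x axis
  (warmest at column 0); MAP ramps along y. A full-width band of nodata
  rows (a "lake") exercises cleaning without shifting column means.
* Occurrences per species are placed in cells whose MAT is drawn from
  Normal(mu_s, sigma_s) truncated to the ramp support, so `t_opt` targets
  `mu_s` up to grid discretization (~0.3 °C cells) and truncation at the
  pool edges. A configured fraction is provider-flagged or placed on
  nodata cells.
* Mortality per stem per year is `logistic(logit(m0) - b_m (mu_s -
  MAT_plot))`; recruits arrive Poisson(r0 T) with species drawn
  proportional to suitability times `exp(b_r mu_s)`. The recruitment bias
  shifts composition, not stem counts, so density is trend-stationary
  under the null and thermophilization is isolated from densification.
* Growth is species-independent by default, giving the basal-area growth
  component a known zero expectation; `growth_optimum_corr` couples them
  when wanted.
* Ground truth records per-plot realized stem-weighted index rates
  computed from the simulator's own event log with true optima — the
  recovery target for the pipeline.

What the generator does **not** emulate: spatial structure within plots,
neighborhood competition, disturbance events, taxonomic error, measurement
error in diameters, and any real covariance between wood density, stature
and climate niche. Passing recovery tests therefore demonstrates the
correctness and calibration of the estimators under the stated process
model, not robustness to these field realities.

## Validation experiments and problem sizes

Three experiments (in `thermoshift.experiments`, driven by
`analysis/05_validation_experiments.py` and `scripts/acceptance.py`) run on
a scaled-down study — 10 plots of 80 stems, 40 species, 60 records per
species — chosen so the full battery completes in well under a minute while
leaving Monte-Carlo error far below the tolerances tested:

1. **Optimum recovery.** Pools of 80 species with exactly n in {5, 10, 30,
   100} clean records; mean |t_opt - mu_s| is compared against an
   independent Monte-Carlo of the sampling expectation (the
   sqrt(2/pi) sigma/sqrt(n) law adjusted for grid snapping and dedupe) and
   must fall monotonically in n.
2. **Trend recovery.** 200 replicate studies across recruitment biases 0 to
   2 log-odds/°C; pipeline-estimated cross-plot trends regress on event-log
   realized trends with slope 1 (tolerance +/- 0.1).
3. **Null calibration.** 500 replicate studies with both biases zero; the
   plot-level Wilcoxon at alpha = 5% must reject within the binomial 99%
   band. True optima are used as the attribute table here so the test's
   calibration is isolated from optimum-estimation noise.

## Numerical conventions and degenerate inputs

* Tags are unique within a plot census; a tag never resurrects (validated
  at read time with line-numbered rejection reports; readers are total —
  accepted plus rejected rows always equals input rows).
* Weighted means drop NaN attributes and renormalize; an index over zero
  covered stems is NaN with a warning, and a trajectory endpoint of NaN
  yields a NaN rate that downstream cross-plot means skip.
* Partition additivity tolerance is 1e-10 (pure floating-point
  telescoping); index-versus-oracle equivalence is asserted at 1e-12.
* Weibull fitting starts at `a = 1.2 max(H)`, `b = median(D)`, `c = 0.9`
  with bounds a in [1, 150], b in [1, 500], c in [0.05, 5]; degenerate
  height data (all diameters equal, or fewer pairs than the floor) raise
  rather than fit.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; derived seeds stay below 2^31.

## Known limitations

* The plain-text climate grid is the only raster format; real Chelsa /
  Worldclim GeoTIFFs must be converted upstream (the format is seven header
  lines plus one row of values per line).
* Species names are matched verbatim; no synonymy resolution.
* No error propagation on the allometry: stocks and fluxes are
  deterministic point estimates given diameters, heights and densities.
* The interval corrections assume demographic rates constant within an
  interval and uniform arrival/death times; they are first-order
  corrections, adequate for the 5–6 year intervals of the emulated design.
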