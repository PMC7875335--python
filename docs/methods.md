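# Methods

`snakerisk` implements a municipality-level analysis pipeline for snakebite
surveillance of the kind run on Brazil's SINAN notifiable-disease database:
descriptive epidemiology, spatial cluster detection, environmental and
socioeconomic driver regression, and a quartile-based instrument that grades
municipalities into four risk levels for antivenom-allocation decisions.
Because the real inputs (SINAN extracts, census demographics, forest-loss
rasters, ecoregion and snake-range maps) cannot be redistributed, the package
ships a synthetic-country generator that reproduces the *structure* of those
data; every stage is exercised and tested end-to-end against it.

## Synthetic country generator

Municipalities are the cells of a `grid_rows x grid_cols` unit-square
lattice; queen contiguity is therefore analytically known, which lets the
spatial-weights construction be tested exactly. States are contiguous
row-major blocks of the lattice (27 by default, grouped into 5 regions), so
within-state quartiles are meaningful. Defaults: a 52x107 lattice, i.e.
5,564 municipalities — the administrative division used by the Brazilian
surveillance categorisation.

Each covariate field is drawn i.i.d. standard normal per cell, smoothed
`spatial_smoothing_passes` times (default 3) by averaging each cell with its
queen neighbourhood, then mapped onto a nominal physical scale (temperature
around 24 °C +/- 3.5, precipitation around 1,400 mm, elevation around 337 m —
the Brazilian mean —, lognormal GDP per capita, and so on). Smoothing
induces the positive spatial autocorrelation the cluster stage needs;
a property test confirms positive global Moran's I for every smoothed field.
The tropical/non-tropical habitat layer thresholds its own smoothed latent
field at the `tropical_fraction` quantile (default 0.55: slightly more than
half the territory tropical). Venomous snake richness is the count of four
genus presence layers (*Bothrops* ~90% of territory, *Crotalus* ~55%,
*Lachesis* ~30%, *Micrurus* ~50%), each a thresholded latent field. Every
field uses its own named pseudo-random stream derived from the single seed,
so adding a covariate never perturbs existing ones.

Counts follow a negative-binomial (gamma–Poisson) model on standardised
covariates z (the habitat dichotomy enters raw, so its coefficient is
per-category):

    log mu_i = beta0 + sum_k beta_k z_ik,    y_i ~ NB(mu_i, theta),
    deaths_i ~ Binomial(y_i, fatality_prob).

Default coefficients are the logs of the nine multivariate rate ratios
reported for the real data (tropical habitat 1.925, temperature 1.647,
urbanisation 0.507, richness 1.177, precipitation 1.229, elevation 1.235,
forest loss 1.066, GDP per capita 0.957, forest cover 1.003), so synthetic
effect sizes are realistic. `theta = 1.2` and `fatality_prob = 0.0038`
reproduce the observed strong overdispersion (five-year maximum near 900
against a mean of ~24), a small zero-count share, and the 0.38% case
fatality. Because of Jensen's inequality on the log link, the realized mean
exceeds `exp(beta0)` by `E[exp(sum beta_k z_k)]`; the default intercept is
`log(24.37) - 0.85`, calibrated once so the generated country mean sits near
the observed 24.37 cases per municipality. With the defaults and seed 1 the
generator yields mean 24.4, maximum 779, 6.9% zero-count municipalities and
0.36% fatality.

What the generator does **not** emulate: real municipal geometry (areas span
four orders of magnitude in Brazil), population–covariate dependence (urban
municipalities are more populous), reporting artefacts (under-notification,
the death-without-case inconsistencies real registries contain), and
between-state heterogeneity beyond what smoothing induces. Passing tests
therefore demonstrate correctness of the *methods* under a known model, not
robustness to real-data pathologies.

## Descriptive statistics

Annual average = `round(total/years)`; incidence = `(cases/years)/population
x 100,000`; case fatality = `deaths/cases x 100`. Rounding is half-up to two
decimals everywhere, matching how surveillance tables are printed; the
annualised rate formula is the one under which the verified rows of the
published state table reproduce exactly (the table's separate cumulative
figure of 13.31 per 100,000 is a different, non-annualised quantity and is
not computed here). A zero-case municipality has an undefined fatality rate
and is reported as missing, never as zero. The published state table ships
with the package as a small CSV and is the worked-example surface; its
printed region row for the North disagrees with the sum of its state rows
(45,492 vs 45,585 — two states print identical counts), so aggregation tests
pin only rows that recompute cleanly, and `aggregate` always recomputes from
its members instead of trusting printed subtotals.

Natural-breaks classification is the exact Fisher–Jenks dynamic programme
(O(k n^2), vectorised inner loop), returning upper-bound breaks; it is tested
against exhaustive minimum-SSD partition search for n <= 12 and against the
property that its within-class SSD never exceeds equal-interval or quantile
classifications.

## Local Moran's I

Weights are queen contiguity (any shared boundary point), row-standardised.
With deviations `z_i = x_i - mean(x)` and `m2 = sum z^2 / n` (population
moment), `I_i = z_i/m2 * sum_j w_ij z_j`; the mean of the `I_i` equals global
Moran's I under this scaling. The analysed variable is the raw case count by
default (rates can be passed instead). Inference is conditional permutation:
the focal value is held fixed and the remaining n-1 values are reassigned to
its neighbour slots — 9,999 samples by default (floor 1/10,000 < 0.0001), or
exhaustive enumeration over all C(n-1, k) neighbour subsets on tiny maps,
where the pseudo p equals the exact enumeration fraction (the observed
arrangement counts as extreme; a 1e-9 relative tolerance guards the
floating-point tie at the observed subset itself). P-values are two-sided on
|I|. Significant units are labelled HH/LL/HL/LH by the quadrant of
(z, spatial lag); isolated polygons get a missing p and NS rather than an
error. One shared pool of permutations serves all units of a map, the
standard conditional-randomisation implementation; calibration is checked
empirically (null rejection within 3 Monte-Carlo SEs of alpha over 200
maps).

## Driver regression

Continuous drivers are standardised to mean 0, SD 1, so rate ratios are per
1-SD and comparable across covariates with wildly different units; the
habitat dichotomy passes through raw. Univariate screening fits one
single-covariate NB model per driver and retains it when the 95% Wald CI of
its RR excludes 1. Collinearity control: pairwise Pearson filtering at
|r| > 0.8 (the pair member with the weaker screening association drops;
deterministic name-order tie-break) followed by VIF = 1/(1-R^2) with a flag
at VIF > 5. Multivariate Poisson (IRLS) and NB2 (joint ML with dispersion,
via statsmodels) are both fitted on the retained set; intervals are Wald
(+/- 1.96 se), matching the symmetric intervals such analyses print. No
population offset by default — the modelled outcome is the raw count — but a
log-exposure offset is available.

Model choice uses DIC from a Laplace approximation: with flat priors the
coefficient posterior is ~N(beta_hat, Cov); the Bayesian deviance
D = -2 log p(y|beta) (comparable across families, unlike residual deviance,
which is relative to each family's own saturated model) is averaged over
Monte-Carlo draws with the NB dispersion held at its MLE, and
`DIC = D(beta_hat) + 2 p_D`, `p_D = Dbar - D(beta_hat)`. Holding theta fixed
undercounts NB complexity by roughly one unit; on equidispersed data the two
models agree to within ~2 DIC units, and on overdispersed data the NB margin
is orders of magnitude larger, so the simplification is immaterial. AIC is
always reported alongside. Zero-inflated families are deliberately not
implemented — with only ~4% structural zeros they add nothing here — though
the family argument leaves an obvious extension point.

The high/low-incidence contrast splits municipalities at the median
incidence rate (strictly above = high) and runs a Welch t-test per driver,
reporting group medians, t and p; degenerate groups are skipped with a
reason, and two identical groups report t = 0 rather than NaN.

## Risk instrument

Epidemiological class uses *within-state* quartiles of case counts and
rates: a municipality is High when it reaches the top quartile (>= q3) of
either, or recorded any death (OR across criteria, deaths forcing High —
both configurable; OR is the sensitive choice for a decision-support tool,
and the criteria are tested separately rather than pooled into one score).
Driver cutoffs are *national* quartiles with a declared risk direction per
driver: risk-increasing drivers (tropical habitat, temperature,
precipitation, elevation, snake richness, forest loss) count at >= q3,
protective drivers (urbanisation, GDP per capita — RRs below 1) count at
<= q1, and the tropical dichotomy counts when tropical. A driver without a
declared direction is an error, never a silent default. Forest cover is
excluded from the instrument (borderline association), leaving 8 candidate
drivers; `d_i >= 4` means "many" drivers. The final grade is a 2x2
combination table — (High, many)=High, (High, few)=MediumHigh,
(Low, many)=MediumLow, (Low, few)=Low — carried as configuration and
serialised with every output. Quartiles use linear-interpolation
percentiles; since raising one sample value raises any percentile by at most
the same amount, the perturbed municipality's driver count and grade are
monotone in risk-increasing drivers even when cutoffs are recomputed, which
the perturbation tests verify.

## Engineering choices

Tables are UTF-8 CSV (declared decimal separator for decimal-comma sources);
geometry is GeoJSON with a required `muni_id` property, Polygon or
MultiPolygon, treated as planar (real inputs must be in a projected CRS;
there is no reprojection). Invalid surveillance rows go to a rejection
report instead of being silently dropped. Zonal statistics use the
cell-centre rule and population SD, the common raster-zonal convention.
All randomness flows from explicit integer seeds; CLI outputs embed a
provenance record (parameters with basenamed paths, seed, config hash,
version) so identical configurations reproduce byte-identical artifacts.

Problem sizes in the test-suite simulations: lattices of 100–900 cells for
spatial tests, 200 null maps of 400 cells for calibration, 100 replicates of
n = 5,000 for NB recovery, exhaustive enumeration only for n <= 9 (Moran)
and n <= 12 (Jenks). The acceptance script uses 50 null maps and 25 recovery
replicates — enough for the reported rates to be stable to a few percent.

## Known limitations

- Conditional permutation p-values are valid per unit but not adjusted for
  testing thousands of municipalities simultaneously; the analysis applies a
  fixed threshold by design, and no FDR control is offered.
- The NB fit can be fragile under complete separation or extreme dispersion;
  failures raise with the optimiser trace rather than degrading silently.
- The DIC is a Laplace/plug-in approximation, not MCMC; it is intended for
  Poisson-vs-NB comparison, not general Bayesian model averaging.
- The instrument's combination table and OR rule are a reconstruction of a
  decision flowchart whose branch logic is configuration here; alternative
  conventions (AND across criteria, pooled quartile scores) are one config
  entry away but untested against real decisions.
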