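# Methods

This note documents the models behind each stage, the defaults and why,
what the synthetic generator does and does not emulate, and the numerical
choices a maintainer would want to know.

## Flight curves

Counts `y_w` at Julian days `d_w` (one season, one site, one species) are
modelled as `y_w ~ Poisson(μ(d_w))`, `log μ = Σ_j θ_j B_j(d)`, with a
cubic B-spline basis of dimension `k = min(10, n_weeks − 1)` on the
sampled span and a second-order difference penalty `λ θᵀDᵀDθ` (a
P-spline). Fitting is penalized IRLS; the smoothing parameter is selected
by maximising the Laplace approximation to the restricted marginal
likelihood (LAML) over a 13-point log-spaced grid `λ ∈ [10⁻², 10⁶]` —
the same criterion modern GAM software calls REML smoothing. The penalty
null space (constants and lines) is handled through the `rank(S) = k − 2`
term of the LAML.

- The curve is evaluated on a daily grid restricted to the sampled season
  (first to last visit day); boundary points are never peaks, which
  avoids edge artifacts from the spline extrapolating.
- Peaks are strict local maxima retained when their height reaches 5% of
  the curve maximum (the prominence default; there is no canonical value,
  and 5% suppresses numerical ripples without hiding genuine second
  broods).
- A unit needs ≥ 5 weeks with the species *present* (count > 0);
  presence, not visits, is what carries flight-curve signal.
- Convergence failures and peakless fits are logged as filter decisions,
  never silently dropped.
- Accuracy, measured by simulation: for unimodal curves at peak intensity
  ≥ 20/week the first-peak day is unbiased with error sd ≈ 1–2 days;
  coarser bases bias, finer bases inflate variance (the suite pins this
  at ±4 days for ≥ 95% of community-distributed replicates).

The annual abundance index is `log(Σ counts / recording events)`, natural
log; recording events are the distinct visit days of the transect that
year, independent of species. Doubling counts shifts the index by exactly
log 2; the index is undefined (and the unit excluded) at zero total.

Dataset-level inclusion rules run before any fitting: sites need ≥ 10
monitored years; species flagged migratory or with heavily overlapping
broods are excluded by configuration; species need ≥ 3 surviving
populations (site x species with ≥ 1 usable year). Every exclusion is
logged with exactly one primary reason, so the filter log partitions the
input units.

## Trend estimation

Population trends are OLS slopes of the annual response (log abundance or
peak day) on calendar year, requiring ≥ 3 years (the minimum for a
p-value). Species trends pool a species' populations in a Gaussian
random-intercept mixed model `response ~ year + (1 | site)`.

The mixed model is fitted by profiling the variance ratio
`ψ = σ²_u/σ²` analytically (single random intercept ⇒ blockwise Woodbury
identities) and optimising the resulting one-dimensional ML or REML
log-likelihood, with an explicit ψ = 0 boundary check. Fixed-effect
p-values are Wald t with `n − p` residual degrees of freedom — simple and
documented; finer df approximations (Satterthwaite etc.) are out of
scope. AIC is `2k − 2ℓ` with `k` = fixed effects + 2 variance
parameters. The implementation agrees with statsmodels MixedLM to ~1e−5
(asserted in the suite) and reduces to OLS at zero between-group
variance and for single groups (with a warning).

Significance classes use α = 0.05 throughout (conventional; nothing in
the analysis depends on the exact value).

## Critical periods and sensitivity

Candidate windows are every contiguous run of 1–3 calendar months in the
13-month span from September of the previous year to September of the
focal year — 36 in total. Window mean temperature is the unweighted mean
of its monthly means; span indices 1–4 (Sep–Dec) read the year before the
focal year. Per window, `peak_day ~ T_window + (1 | site)` is fitted by
ML (fixed effects differ across windows, so REML criteria would not be
comparable); the minimum-AIC window is the critical period, ties broken
deterministically towards the shorter then earlier window, and the
winning window is refitted by REML for the reported slope, SE and
p-value. Species need ≥ 10 phenology records across ≥ 2 sites. Window
temperatures use `tmean` by default (configurable).

**Post-selection caveat.** The reported p-value does not account for the
selection of the best window. Under a simulated null (no temperature
effect, default temperature generator, 26 years x 10 sites) the fraction
of species classed significant at α = 0.05 is ≈ 0.46, not 0.05: the AIC
scan is effectively a min-p search over ~13 independent month blocks.
This is a property of the standard sliding-window procedure itself, not
of this implementation; selection-corrected inference (e.g. permutation
of the year linkage) would be required for calibrated significance
claims about weak-signal species. Sensitivity *point estimates* for
species with real signal are essentially unaffected (recovery
correlation ≈ 0.98 at default noise).

## Comparative PGLS

The Brownian covariance `C[i,j]` is the root-to-MRCA shared path length,
accumulated edge-by-edge from the Newick tree (dendropy). PGLS solves the
GLS normal equations after a Cholesky whitening of `C_λ` (Pagel λ scales
off-diagonals only; λ = 1, pure Brownian, is the default — an optional
profiled-λ grid fit exists but nothing in the default pipeline uses it).
SEs use the unbiased GLS residual variance; t and p use `n − p` df; model
comparison uses AICc with `k = p + 1` (small-sample correction matters at
n ≈ 50 species).

Trait models: for each response (sensitivity, phenology trend, abundance
trend), each of the six traits is fitted alone (treatment coding,
alphabetical reference level; HPI enters square-root transformed), and
traits significant at α enter one combined model. The
phenology–abundance models fit (1) `√|phenology trend| ~ sensitivity` on
the negative-sensitivity species only — positive-sensitivity species are
atypical responders and are excluded, with the exclusion list recorded on
the fit — and (2) abundance trend on each phenological variable alone and
together with the traits found significant for abundance trends,
mirroring the two-step structure of trait-then-phenology analyses.

## Climate fields

Monthly site temperatures come from a two-step interpolation: OLS of
station temperatures on altitude, latitude, continentality and solar
radiation (per month, and per year when the station table is yearly),
plus inverse-distance-weighted interpolation of the station residuals
(power 2 by default; IDW is an exact interpolator at stations for any
positive power, asserted as a property test). Constant predictor columns
are absorbed by the intercept and reported with coefficient 0; the
collinearity error is reserved for genuinely dependent predictors.
Raster densification is replaced by direct point prediction at site
coordinates — map-level bit-compatibility is not a goal. Regional trends
reuse the random-intercept machinery (`value ~ year + (1 | site)`);
implied change over the span is slope x (last − first year). The annual
mean is the unweighted mean of the 12 monthly means.

## Synthetic data

The generator emulates a Mediterranean monitoring scheme:

| parameter | default | rationale |
|---|---|---|
| sites x years | 59 x 26 (1994–2019) | scheme scale |
| species | 51 | community scale |
| visits | 30/season, ISO weeks 10–39, mid-week Julian day | weekly Mar–Sep sampling |
| monthly temperature trends | −0.02 °C/yr in Feb/Mar/May, +0.0383 elsewhere | mixed-sign seasonal trends; implied annual slope 0.0236 °C/yr (≈ 0.59 °C over the span) |
| temperature noise sd | 0.5 °C | typical interannual monthly residual |
| sensitivities | U(−8, 0) days/°C | advance-dominated community |
| true critical windows | 1–3 months within Nov–Apr | late-winter development |
| abundance trends | U(−0.05, 0.05) log units/yr | realistic decline/increase range |
| flight sd | U(8, 16) days; second brood +60–90 d for ~30% multivoltine | unimodal/bimodal curves |
| season totals | U(100, 600) | peak weekly intensities ~20–200 |
| visit missingness | 0.1 | weather-lost weeks |

Peak day for site s, year t is
`baseline + sensitivity x (T_window(s,t) − T_window_baseline(s)) + extra_trend x t`,
where the realised (noisy) window temperature drives the response and the
baseline is the noise-free window mean in the first study year. The
weekly intensity is a (mixture of) Gaussian(s) normalised on the sampling
grid so that the season total equals
`total x exp(abundance_trend x t)` exactly before Poisson noise. Counts
are independent Poisson draws; whole visits (shared by all species) drop
out with the missingness probability as absent rows.

Trees are pure-birth (Yule) with strictly positive branch lengths, drawn
directly from exponential waiting times so the draw is reproducible from
one numpy seed. Species-level effects can be generated as `Xβ` plus
multivariate-normal residuals with covariance `σ²C` for
phylogenetically correlated trends.

What the generator does **not** emulate — and what passing recovery
tests therefore do not establish for real data: spatial autocorrelation
between sites beyond shared trends, weather-dependent detectability,
migration, overdispersion relative to Poisson, observer effects, and
range shifts. Real monitoring data violate several of these; recovery
results here certify the estimation chain, not the field protocol.

## Reproducibility and sizes

All randomness flows from one root seed via named SeedSequence streams
(site baselines, temperature noise, counts, tree, species effects draw
from independent streams), so any stage is bit-reproducible in
isolation. The pipeline writes a manifest (SHA-256 per output, seed,
config hash); re-running a config reproduces identical hashes.

The recovery experiments in the test suite use 51 species x 10 sites x
26 years for the end-to-end sensitivity experiment and 200 replicates
for the focused ones; the acceptance script uses a 30-species, 8-site
scheme. These sizes give stable Monte-Carlo estimates (binomial se ≤ 3
percentage points on rates) while keeping a full run in the minutes
range on a single core.

## Known limitations

- Post-selection inference for critical periods (above) is uncorrected.
- Mixed-model p-values use naive `n − p` df; anti-conservative for few
  groups.
- The abundance index ignores within-season coverage differences beyond
  dividing by recording events (no area-under-curve weighting).
- Per-species peak-rule refinements are exposed only as generic hooks
  (`peak_rule: second_generation`); species-specific biology must be
  supplied by the user's configuration.
- PGLS assumes the supplied tree is correct and ultrametric-ish; λ is
  fixed at 1 unless profiled explicitly.
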