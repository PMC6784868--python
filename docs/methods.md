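# Methods

`rubmi` estimates trends in mean body-mass index (BMI, kg m⁻²) for rural and
urban populations from heterogeneous survey summary data, and attributes the
change in a population's mean BMI to rural change, urban change and
urbanisation.  This note documents the model, the synthetic data the package
is tested on, and the numerical and design choices a maintainer should know
about.

## The estimation model

The unit of data is a survey summary cell: one study × sex × age group ×
stratum with a mean BMI, its standard error and an effective sample size.
Sexes are analysed in fully separate fits.  For one sex, the rural mean BMI
surface over country *c*, year *t* and age *a* is

    μ_rural(c,t,a) = a_c + b_c (t − t₀) + u_c(t) + f(a) + g_c(a)

and the urban surface adds a country- and year-varying urban–rural
difference

    μ_urban(c,t,a) = μ_rural(c,t,a) + δ0_c + δ1_c (t − t₀).

* **Hierarchy.**  Country intercepts, slopes and gap parameters are sums of
  global, super-region, region and country deviations, each level with its
  own SD, so countries with little data shrink toward their region and
  regions toward the world.
* **RW2 deviation.**  `u_c` is a second-order random walk on the annual
  grid, re-expressed in a whitened eigenbasis of the second-difference
  penalty with the constant and linear directions removed, which makes it
  identifiable against `(a_c, b_c)`; the SD parameter is the innovation SD.
* **Age pattern.**  `f` is a cubic B-spline (default interior knots at ages
  30/45/60, boundary 18/85), centred so it vanishes at age 40; `g_c` are
  country-level deviations on the same basis, shrunk to zero.  Because the
  basis spans cubics, smooth generating age curves are inside the model
  family.
* **Observation model.**  Each summary row is linked to a weighted
  combination of model cells: 10-year input age groups spread over the
  5-year estimation groups they span with population weights, and rows not
  stratified by residence ("mixed") combine rural and urban cells through
  the year-specific urban population share.  The likelihood is
  `y ~ Normal(prediction + β_coverage + ν_study, se² + τ²_level)` with fixed
  coverage effects for subnational and community sources (national is the
  reference), study random effects whose SDs are ordered
  φ_national ≤ φ_subnational ≤ φ_community, and a per-level extra residual
  SD τ.
* **Priors.**  Normal(25, 10²) on the global intercept, weak zero-mean
  normals on other global terms, half-Normal priors on every SD
  hyperparameter with configurable scales (defaults in `ModelConfig`).

**Sampling.**  Conditional on its ~20 scalar SD hyperparameters the model is
linear-Gaussian, so it is sampled by blocked Gibbs: one joint Gaussian draw
of all regression coefficients per sweep (sparse normal equations, a single
dense Cholesky), univariate slice-sampling of each SD, and an
ancillary-sufficiency interweaving rescale of each coefficient block that
removes the funnel-shaped stickiness centred parameterisations otherwise
show.  This draws from the exact posterior — there is no approximation
beyond Monte Carlo error.  Split-R̂ and effective sample size are computed
on monitored scalars (arviz); a fit with any split-R̂ above 1.05 is flagged
(not discarded), which with short chains is mostly triggered by the
slow-mixing RW2 innovation SD rather than by the surfaces themselves.
The default draw count is 5,000 after burn-in; the heavier test and
acceptance fits use 400–800 retained draws as a problem-size choice, which
is ample for posterior means and 95% intervals.

## Postprocessing

Age-standardised means use WHO world standard population weights shipped as
a packaged table (single-year shares for ages 18 and 19 are one fifth of
the 15–19 share; the 85+ share is folded into the top group); any weight
table that is non-negative and sums to one is accepted.  National means
combine rural and urban by the year-specific urban share; regional and
global means are population-weighted country averages.  Credible intervals
are empirical 2.5th/97.5th percentiles with linear interpolation; the
direction probability is the fraction of draws sharing the sign of the
posterior mean.

## Decomposition

With endpoint stratum means and urban shares, the change in the
share-weighted population mean decomposes exactly into
`Δrural·(1−s₀) + Δurban·s₀ + Δs·(urban₁ − rural₁)`.  Percentage
contributions divide by the total change and are suppressed (NR) when the
|total| is below 0.5 kg m⁻², where the ratio is unstable.  Two modes exist:
draw-wise (posterior means and CrIs of per-draw percentages) and point mode
(deterministic ratios of point components, rounded half-away-from-zero),
the latter used for the packaged worked-example table
(`data/reference_contributions.csv`).  Because that table's absolute
components are printed to two decimals, a few derived percentages differ by
one integer from the published ones; the worked-example checks use the rows
that reproduce exactly.

## Crosswalk

Sources reporting only BMI-category prevalences (overweight ≥25, obesity
≥30, underweight <18.5) are converted to mean BMI by a linear regression of
mean BMI on the logits of the available prevalences with sex, a quadratic
in age-group midpoint, and a study random intercept (statsmodels MixedLM;
the quadratic age term is this package's choice of smooth age adjustment).
One model is kept per metric subset.  Conversion propagates every
uncertainty source by Monte Carlo: prevalences are drawn jointly from the
implied multinomial over BMI categories (they share one sample, so drawing
them independently would break the near-collinear cancellation in the
regression), coefficients from their GLS covariance, plus a new-study
random effect and a residual per draw.  Prevalences are clipped at half a
count, 1/(2n), before the logit — in training and application alike, so
extreme prevalences saturate identically in both — and training features
carry binomial sampling noise for the same errors-in-variables consistency.

## Cross-validation

Two holdout designs: withhold all data from ~10% of countries (sampled
within data-richness strata defined by sex-specific source counts:
rich ≥8/≥7, poor ≤3/≤2 for women/men), or withhold ~10% of sources, each
selected country losing either a random third of its sources or all of its
post-2000 sources.  Each repetition refits the model on retained data only.
Held-out rows are pooled into one cell per study × stratum (an
age-standardised mean over the reported age groups, weights renormalised)
and compared with the identically combined posterior draws.  Interval
coverage is assessed against posterior-*predictive* draws — estimate draws
plus coverage effect, study-effect and extra-residual noise and the
observation's own sampling SE — because the held-out quantity is data, not
the smooth surface, and at desk scale observation noise is not negligible
relative to posterior spread.  An estimate-only mode is available.

## Synthetic worlds

The generator draws worlds from the same structural family the model
assumes: hierarchical intercepts (level SDs 1.2/0.8/0.6 kg m⁻²) and slopes
(0.015/0.010/0.008 per year around a global +0.05), RW2 deviations
(innovation SD 0.03), a fixed concave adult age curve with country spline
perturbations (SD 0.3), and urban gaps around +1.2 kg m⁻² narrowing by
0.015 per year, with country spread 0.6.  Surveys land at random
country-years (Poisson, mean 8 per country; pre-2000 rate halved to mimic
sparser early data), are national/subnational/community with probability
0.6/0.25/0.15, carry fixed coverage offsets (0 / +0.2 / +0.35) and
study effects (SD 0.15/0.30/0.45), report rural and urban strata separately
in 75% of cases and a single "mixed" row otherwise, and have within-cell
BMI SD 4.0 (women) / 3.5 (men) with 100–600 subjects per cell, so the
reported SE is exactly σ/√n.  2% of rows are stripped to prevalences.
Random streams are split per (country, purpose): enlarging a world does not
perturb existing countries.

What this does **not** emulate: real-world model misspecification (survey
bias structures that are not mean shifts plus noise, non-normal within-cell
BMI, rural/urban reclassification, age-reporting heaping) — so passing
recovery and calibration tests shows the machinery is correct and
internally calibrated, not that real-data estimates would enjoy the same
error rates.  The default test world (3 super-regions × 2 regions × 4
countries, 1985–2017) and the 12-country world used for the repeated
holdout experiment are problem-size choices; calibration metrics are
scale-free, while absolute errors would shrink with more data.

## Numerical details and edge cases

* Percentile convention: linear interpolation between order statistics,
  everywhere.
* SD floors of 1e−4 keep Gibbs conditionals proper when a variance block
  collapses; the interweaving step is skipped below 1e−8.
* Age groups are closed integer intervals; the open-ended 80+ input group
  maps onto the 80–84 estimation group; ages are floored to integers.
* A cell with a single record gets a pooled-variance SE and a
  `sparse_cell` flag rather than being dropped.
* Countries whose population is entirely urban (or rural) in a cell return
  only the populated stratum from `posterior_stratum_means`.
* Cleaning bounds are inclusive (a 250 cm, 300 kg record is kept);
  unknown-residence records are dropped only in studies that recorded
  residence for someone.

## Known limitations

* The urban–rural difference is linear in time per country; a spline gap is
  out of scope, so sharp non-monotone gap reversals are smoothed.
* The coverage model is a scalar offset plus inflated noise; real
  subnational samples can be biased in age- or stratum-specific ways.
* The Gibbs sampler's dense Cholesky scales cubically in the coefficient
  count; hundreds of countries would need a sparse factorisation.
* Countries with no data in a stratum for all years are determined entirely
  by the hierarchical prior.
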