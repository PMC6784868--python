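# rubmi — rural and urban BMI trends from pooled survey summaries

`rubmi` is a Python package for estimating trends in mean body-mass index
(BMI, kg m⁻²) separately for rural and urban populations, from the kind of
heterogeneous evidence global health analyses actually have: survey summary
cells (study × sex × age group × place of residence) with means, standard
errors and effective sample sizes, mixed national, subnational and
community sources, surveys that never recorded residence, and a small
fraction of sources reporting only the prevalence of BMI categories.  It is
aimed at population-health researchers who need country–year–sex–age
estimates with honest uncertainty, and at methodologists who want a fully
testable, self-contained version of this estimation pipeline.

## What it does

* **Bayesian hierarchical trend model** (`rubmi.trend_model`).  For each
  sex, rural mean BMI follows

  μ_rural(c,t,a) = a_c + b_c (t−t₀) + u_c(t) + f(a) + g_c(a),
  μ_urban = μ_rural + δ0_c + δ1_c (t−t₀),

  with country intercepts/slopes and the urban–rural gap parameters shrunk
  hierarchically (country → region → super-region → global), a second-order
  random-walk deviation u_c for nonlinear trends, a cubic B-spline age
  curve f with shrunken country deviations g_c, fixed effects and inflated
  noise for subnational/community sources, and study random effects.  The
  linear-Gaussian structure is exploited by a blocked Gibbs sampler (joint
  coefficient draws + slice/interweaving updates for the variance
  parameters); convergence is monitored with split-R̂ and ESS.
* **Ingest** (`rubmi.ingest`): cleaning rules for microdata (adults 18+,
  non-pregnant, BMI 10–80, height 100–250 cm, weight 12–300 kg,
  residence-status handling) and design-weighted stratified summaries.
* **Crosswalk** (`rubmi.crosswalk`): regression-based conversion of
  BMI-category prevalences to mean BMI with every uncertainty source
  propagated through draws.
* **Postprocessing** (`rubmi.postprocess`): WHO-standard age
  standardisation, population-weighted national/regional/global aggregates,
  95% credible intervals, posterior direction probabilities.
* **Decomposition** (`rubmi.decomposition`): exact attribution of the
  change in population mean BMI to rural change, urban change and
  urbanisation, with draw-wise credible intervals and the NR suppression
  rule for small total changes.
* **Validation** (`rubmi.validation`): held-out cross-validation designs
  (10% of countries, or 10% of sources via one-third / post-2000 schemes)
  with median error, median absolute error and interval-coverage reports.
* **Synthetic worlds** (`rubmi.synthetic_world`): a generator of
  ground-truth BMI surfaces and survey-like observations with the full
  heterogeneity above, so every stage is testable without any external
  data.

## Worked example

Fit a synthetic world and decompose its global BMI change:

```python
from rubmi.synthetic_world import generate_world
from rubmi.trend_model import fit_world

world = generate_world(seed=1)            # 24 countries, 1985-2017, 2 sexes
draws = fit_world(world, "female", n_draws=800, burn=400, seed=3)
print(draws.diagnostics["max_rhat"])      # 1.08 on monitored scalars
```

Comparing the posterior surfaces against the generator's truth over
country-years with data gives a mean absolute error of **0.12 kg m⁻²** and
95% credible-interval coverage of **94.0%** (`scripts/acceptance.py`,
seed 1).

Point-mode percentage contributions reproduce the packaged worked-example
table: feeding the World–Men absolute contributions (1.24, 0.65,
0.30 kg m⁻²) into `percent_contributions` returns

```
rural 57%, urban 30%, urbanisation 14%
```

and a region whose total change is only 0.25 kg m⁻² comes back flagged
`NR` rather than as an unstable ratio.

The same pipeline is scriptable from the shell:

```
rubmi simulate --out world --seed 3
rubmi fit --obs world/observations_mean.csv --pop world/population.csv \
      --hierarchy world/hierarchy.csv --sex female --out draws.npz --seed 5
rubmi decompose --draws draws.npz --pop world/population.csv \
      --hierarchy world/hierarchy.csv --sex female --out decomp.csv
```

## Layout

```
src/rubmi/          library modules (schema, synthetic_world, ingest,
                    crosswalk, trend_model, postprocess, decomposition,
                    validation, cli)
src/rubmi/data/     WHO standard-population weights, worked-example table
tests/              pytest suite incl. end-to-end acceptance checks
docs/methods.md     model, priors, generator and design notes
scripts/acceptance.py
```
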