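# isomix

Stable-isotope diet analysis toolkit: a tested, reusable pipeline for
estimating consumer diet composition from two-tracer (δ13C, δ15N) isotope
data with a Bayesian concentration-dependent mixing model, plus the
up- and downstream stages such analyses need.

## What it does

- **isodata** — domain types, tidy CSV readers/writers, δ-notation
  utilities, prey-group summaries (mean ± SD, elemental concentrations).
- **corrections** — additive δ13C drift correction (oceanic Suess effect +
  temperature-mediated Laws term, centered on a reference year) and linear
  restoration of bulk δ15N for lipid-extracted historical samples, with an
  audit log and a double-correction guard.
- **multivar_stats** — from-scratch permutation statistics: one-factor
  PERMANOVA (Manhattan or Euclidean, add-one permutation p, exact
  enumeration for tiny designs), pairwise contrasts with Benjamini–Yekutieli
  adjustment, dispersion-based outlier screening, Mardia's bivariate
  normality check.
- **mixing_model** — Dirichlet-prior mixing model with concentration
  dependence and trophic discrimination factors; covariates (class, year,
  class×year, individual random effect) act in isometric log-ratio space;
  two error structures (multiplicative residual×process, process-only);
  adaptive Metropolis-within-Gibbs sampling with split-chain R-hat,
  simulated mixing-polygon goodness-of-fit, prior-vs-posterior comparison.
- **model_selection** — WAIC and PSIS-LOO (Zhang–Stephens generalized
  Pareto tail smoothing) on per-consumer pointwise log-likelihoods, with
  per-period ΔLOOic/ΔWAIC ranking tables.
- **diet_metrics** — per-individual specialization index
  Ɛ = ‖p − u‖ / √((K−1)/K) (0 = ultra-generalist, 1 = ultra-specialist),
  source merging (e.g. combining pelagic groups), inter-individual
  heterogeneity as distance to the class centroid with permutation
  dispersion tests, and PERMANOVA diet-difference tests.
- **synthetic_data** — seeded generators for prey groups and consumers with
  known diets, class/year effects, individual random effects and
  multiplicative error; used by the tests and parameter-recovery checks.
- **cli** — stage commands and a config-driven end-to-end pipeline.

## CLI

```sh
# generate a synthetic dataset (consumers.csv, prey.csv, truth.csv)
isomix simulate --scenario ci_small --out-dir scratch/demo

# individual stages
isomix correct consumers.csv --schema consumer --reference-year 2002 --out corrected.csv
isomix group prey.csv --period 2000s --out sources.csv
isomix fit consumers.csv sources.csv --model class+ind --chains 3 --iters 2000 --out fit.csv
isomix rank null=null.loglik.csv class=class.loglik.csv --period 2000s --out ranking.csv
isomix epsilon diet_estimates.csv --merge-map-json merge.json --out epsilon.csv
isomix dispersion diet_estimates.csv --grouping class --out dispersion.csv

# full pipeline from a JSON/YAML config
isomix run configs/run_example.json
```

The pipeline runs corrections → prey grouping → model fits → ranking →
diet estimates → Ɛ → heterogeneity and writes tidy CSVs plus a
`manifest.json` with seeds, config hash, per-stage wall time and R-hat
convergence flags. Non-convergent models are flagged and excluded from the
ranking with a warning — models combining the multiplicative error term
with an individual random effect have a weakly identified variance
trade-off and may need ~4000 iterations.

Model labels follow the candidate set: `null`, `class`, `ind`, `year`,
`class+ind`, `year+ind`, `class_x_year`, `class_x_year+ind`. (Note: read
ranking CSVs with `keep_default_na=False`, otherwise pandas turns the
label `null` into NaN.)

## Configuration notes

- Suess/Laws presets live in `configs/suess_params.json`; the shipped
  North Atlantic constants are reconstructed defaults for the published
  functional form, not measured values — edit them per region.
- δ15N restoration coefficients default to identity; supply per-taxon
  `intercept,slope` via `configs/n15_restoration.csv`.
- Validation bounds warn by default and raise under `--strict`.
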