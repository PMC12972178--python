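# ensembleage

Ensemble epigenetic clocks for DNA methylation data.

Single epigenetic clocks — penalized regressions predicting age from CpG
beta values — track chronological age well but often respond weakly, or in
the wrong direction, to interventions that actually change biological age.
`ensembleage` addresses this by treating clocks as a population: it trains a
library of penalized-regression clocks over a grid of recipes, benchmarks
every clock against a panel of controlled perturbation experiments with
documented directional effects (pro-aging *stress* vs. *rejuvenation*),
keeps the clocks that respond in the expected direction, and aggregates
them into two estimators:

- **dynamic**: for each new experiment, re-identify the *responsive* clocks
  (those whose treated-vs-control acceleration contrast has |Z| > 2 in that
  dataset) and report the per-sample **median predicted age across
  responsive clocks**, plus the median of their Z-scores (the ensemble Z);
- **static**: a single elastic-net clock distilled to predict the
  calibrated (dynamic, or most-responsive-clock) ages, trained on treated
  animals only, for screening data that has no stratum labels.

The package is aimed at researchers analyzing methylation-array or
RRBS-derived beta matrices from intervention studies (caloric restriction,
progeria models, reprogramming, ...) in mice or across species.

## The model

A clock is a linear model on the beta scale,

    g(age) = b0 + sum_j w_j * beta_j,

where `g` is an age transform: identity, a log-linear map (logarithmic
through development, linear after maturity, C1 at the knot), or relative
age `age / L` with `L` the species maximum lifespan (which puts human and
mouse on a common scale for joint training on shared CpGs).  Weights are
fitted by ridge, lasso or elastic-net regression with the regularization
strength chosen by seeded, tissue-stratified 10-fold cross-validation
minimizing MSE; CpGs can be pre-selected by an epigenome-wide association
study (EWAS) of beta on transformed age, thresholded at |z| > 2 with
z = sign(t) · Φ⁻¹(1 − p/2).

For benchmarking, per-stratum **age acceleration** is the residual of
predicted age from the control-fitted regression line on chronological age;
the treated-vs-control contrast of accelerations gives each clock a signed
Z per stratum, and confusion-matrix metrics (accuracy, error rate, stress
and rejuvenation detection rates, |z|-weighted correct-response ratio)
against the documented expected directions drive ensemble selection.

A synthetic benchmark generator with known ground truth (planted aging
slopes on a causal CpG subset, signed effective-age shifts per stratum)
makes the entire pipeline testable end to end with no external data.

## Worked example

Run the full pipeline on the built-in synthetic benchmark (1000 CpGs,
120 normal-aging samples for training, a 6-stratum perturbation panel of
8 controls + 8 treated each, ±0.5 y planted effective-age shifts):

```sh
ensembleage pipeline --seed 1 --out demo/
```

which prints

```
pipeline complete: 12 clocks, ensemble of 6 -> demo/
```

and writes, among other artifacts, `demo/report.json`.  From that run:

- every library clock reaches held-out R ≈ 0.99 against chronological age
  (`heldout_r` in the report), as expected on clean synthetic data;
- the ensemble Z per stratum was
  `{stratum00: 6.21, stratum01: -6.57, stratum02: 6.57, stratum03: -5.68,
  stratum04: 5.39, stratum05: -7.06}` against planted directions
  `{stratum00: stress, stratum01: rejuvenation, ...}` — positive Z for every
  stress stratum and negative for every rejuvenation stratum, i.e. the
  ensemble detects each perturbation and calls its direction correctly;
- `demo/static_median.csv` is the distilled static clock (a plain
  coefficient table usable on any matrix via `ensembleage predict`).

Individual stages are available as subcommands (`simulate`, `ewas`,
`train`, `predict`, `benchmark`, `select`, `dynamic`, `calibrate`,
`train-static`, `radar`, `enrich`); see `ensembleage --help`.

## Layout

- `src/ensembleage/io.py` — beta matrices, sample sheets, clock files
  (CSV + JSON sidecar), alignment/imputation
- `agetransform.py` — identity / log-linear / relative age transforms
- `ewas.py` — per-CpG OLS with signed z, pre-selection, Stouffer pooling
- `clocktrain.py` — penalized clock training, prediction, libraries
- `benchmark.py` — acceleration, stratum Z, confusion metrics, panel splits
- `ensemble.py` — selection, dynamic prediction, calibration, static
  distillation, radar scaling
- `synthetic.py` — ground-truth benchmark generator
- `enrich.py` — hypergeometric enrichment of EWAS hits
- `pipeline.py`, `cli.py` — orchestration and the command line

See `docs/methods.md` for the modeling choices and their rationale.
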