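# Methods

This note documents the statistical procedures implemented in
`ensembleage`, the defaults and their rationale, what the synthetic
benchmark does and does not emulate, and the design decisions taken where
more than one reasonable convention exists.

## Age transforms

Clock targets are transformed ages. Three transforms are provided, all
strictly increasing with exact closed-form inverses (predictions are
always reported back in years):

- **identity** — `f(a) = a`.
- **log-linear** — `f(a) = log(a + k)` for `a ≤ m`, and
  `f(a) = log(m + k) + (a − m)/(m + k)` for `a > m`. Both branches meet at
  `log(m + k)` with common derivative `1/(m + k)`, so the map is C1.
  Defaults `m = 0.16` y and `k = 0.06` y are configuration constants
  appropriate for mouse maturity, not fitted quantities; natural logarithm
  throughout.
- **relative** — `f(a) = a / L` with `L` the species maximum lifespan
  (defaults: mouse 4.0 y, human 122.5 y, configurable). Two species at the
  same life fraction map to the same value, which is the property that
  makes joint cross-species training on shared CpGs coherent. All ages are
  in years for every species.

## EWAS engine

Each CpG's beta values are regressed on a numeric predictor (plus optional
covariates) by ordinary least squares; the slope's two-sided t-test
p-value is mapped to a signed z through the probit,
`z = sign(t) · Φ⁻¹(1 − p/2)`, so |z| > 2 corresponds exactly to
p < 0.0455 and the sign carries direction. |z| is capped at 38, where
double-precision p-values underflow. CpGs with missing cells are tested on
complete cases; a CpG with fewer complete cases than parameters + 3 is
flagged untestable rather than dropped. Plain OLS is used rather than
moderated (empirical-Bayes) variance estimates; at the sample sizes of
perturbation panels the moderation correction is secondary, and the
signed-z contract is unaffected. Pre-selection keeps CpGs with
|z| > 2 (descending |z|, ties broken by CpG id); pooling across multiple
experiments is available via equal-weight Stouffer combination.

## Clock training

Predictors are raw beta values. Internally the design is standardized
(mean 0, sd 1 per CpG) before penalization — the convention that makes the
penalty scale-free — and coefficients are back-transformed to the beta
scale, so a saved clock is a plain linear model independent of any
training statistics except the stored per-CpG training means used to
impute absent probes at prediction time (a distribution-aware choice;
imputing 0.5 would bias predictions toward the middle of the beta scale).
Prediction refuses to proceed when more than 50% of a clock's CpGs are
absent (configurable); smaller gaps are imputed and logged.

Regularization strength is selected on a 100-point log-spaced path by
10-fold cross-validation minimizing MSE, with folds seeded and stratified
by tissue so no tissue is concentrated in one fold. A one-standard-error
rule is available (`cv_rule="1se"`) but the default is the MSE minimizer.
Ridge is solved by SVD (one decomposition per fold covers the whole path);
lasso and elastic net use coordinate descent with the elastic-net mixing
defaulting to 0.5. The final model is refit on the training set at the
selected strength; a `refit_all` flag refits on all samples after
validated selection. Identical (data, recipe, seed) triples yield
bit-identical coefficients. Sample splits are 70/30, stratified by tissue
within one sample of the target fraction; tissues with fewer than two
samples go to training with a warning. Predicted ages below 0.001 y are
floored with a warning (inverse transforms are total, but clocks can
extrapolate below zero on unusual inputs).

## Benchmarking against directional panels

A *stratum* is one perturbation experiment in one tissue with age-matched
controls. **Age acceleration** is defined as the residual of predicted age
from the regression line of predicted on chronological age fitted to the
stratum's controls. Residualizing against controls, rather than taking
predicted − chronological directly, removes each clock's calibration bias
(slope and offset errors) so clocks of different quality are compared on
their *response* rather than their calibration; with fewer than 3 controls
or constant control ages the fit is unreliable and the delta-age
difference is used instead (logged). The treated-vs-control contrast of
accelerations is tested by OLS on a treated indicator (equivalent to a
pooled two-sample t-test) and mapped to a signed z. A clock is
*responsive* in a stratum when |z| > 2.

Per-clock metrics over strata with documented expected directions:
correct ratio (sign of z matches direction), median direction-aligned z
(z for stress, −z for rejuvenation), accuracy P(responsive ∧ correct),
error rate P(responsive ∧ incorrect), stress detection P(z > 2 | stress),
rejuvenation detection P(z < −2 | rejuvenation), and a weighted correct
score Σ|z|·1[correct ∧ responsive] / Σ|z|. The weighted score is one
concrete reading of "correct responses weighted by significance"; it is
the primary ranking key and is deliberately simple (alternatives such as
per-category averaging are easy to add but were not needed). Panel splits
for selection vs. testing are stratified by expected direction (default
2/3 selection) so both splits contain stress and rejuvenation strata.

## Ensemble selection and the two estimators

Selection ranks clocks by weighted correct score, then median aligned z,
then correct ratio, then clock id, and keeps the top K (default 40; any
smaller library uses what it has). A balance guard swaps in the best
stress-detecting (resp. rejuvenation-detecting) clock when the top-K
contains none and one exists, so the ensemble can respond in both
directions.

**Dynamic**: for a new stratum, each ensemble clock is re-evaluated;
responsive clocks (|z| > 2 *in that stratum*) define the estimate — the
per-sample median of their predicted ages, and the median of their z as
the ensemble Z. Responsiveness is a property of an experiment, so dynamic
estimation requires stratum labels; unlabeled data should use the static
clock. When no clock is responsive the median over the whole ensemble is
returned and flagged (`fallback_used`), keeping the estimator total
rather than failing.

**Calibration** produces per-sample target ages for distillation: either
the dynamic medians, or the predictions of the single clock with maximum
direction-aligned z in each stratum ("top" mode, defined only for strata
with a documented direction). Samples sharing an identical calibrated
value are de-duplicated (first in sheet order kept) to avoid degenerate
repeated targets.

**Static**: an elastic-net clock fitted to transformed calibrated ages on
*treated samples only* — emphasizing perturbation-responsive CpGs — via
the same training engine; both a median-calibrated and a top-calibrated
variant are produced. The result is an ordinary clock file: prediction
depends only on the beta matrix and the coefficients.

**Radar scaling** maps a set of z-scores to [−1, 1] for plotting:
s = 0.1·z for |z| ≤ 2; z > 2 is linearly interpolated from 0.2 at z = 2
to 1 at the set's maximum positive z (symmetrically for z < −2 using the
set's most negative z). The anchor is per set; a lone boundary value maps
to ±0.2. The map is order-preserving within a set.

## Synthetic benchmark generator

The generator emulates the *structure* of a curated perturbation
benchmark: tissue-specific strata of age-matched controls and treated
animals whose methylomes are shifted by a signed effective-age delta
(positive for stress, negative for rejuvenation — signs are enforced at
construction). CpG j of sample i is
`clip(b0_j + s_j·g(eff_i) + offset_tissue,j + noise_sd·ε_ij, 0.001, 0.999)`
with baselines U(0.1, 0.9), causal slopes ±U(0.02, 0.15) on the causal
fraction (zero elsewhere), per-(tissue, CpG) Gaussian offsets, and i.i.d.
standard normal ε scaled by `noise_sd` — so runs differing only in noise
level reuse identical draws, which is what makes noise-degradation
comparisons exact. Clipping rather than logistic squashing keeps planted
slopes exactly linear mid-range, so closed-form oracles apply. CpG-universe
draws (baselines, causal set, slopes) are controlled by `universe_seed`
separately from sample-level draws, so a clock trained on one panel
transfers to another panel sharing the universe — the analogue of applying
a trained clock to a new experiment on the same array.

Defaults: 2000 CpGs, 10% causal, 12 strata of 10 + 10 samples, ages
uniform on 0.2–3.0 y (a mouse-like range), |delta| = 0.5 y, noise sd 0.05
on the beta scale, tissue-offset sd 0.02 — sizes at which every stage runs
in seconds while effects of a few tenths of a year remain detectable, and
comparable in per-stratum n to typical intervention experiments. Deltas
may alternatively be specified as a fraction of chronological age
(`relative_effects`), e.g. −0.2 for a 20% effective-age reduction. The
outcome variant adds `time_to_death = max(L − age − hazard·(eff − age) +
noise, 0.01)`, negatively coupling survival to effective-age excess.

What the generator does **not** emulate: probe-level array chemistry,
batch effects, RRBS coverage dropout, beta-value heteroskedasticity near
the boundaries, and correlated CpG blocks. Passing tests therefore
demonstrate the correctness and statistical behavior of the machinery
under a clean additive model, not performance on real arrays.

## Enrichment

Annotation content is a user input (named CpG sets); the package supplies
only the upper-tail hypergeometric test, with fold = (k/n)/(K/N), the
universe defaulting to all testable CpGs in the EWAS (not an array
manifest), annotation members outside the universe dropped with a logged
count, and depletion visible as fold < 1 without a second test. Signed
enrichment splits hits (default p < 1e−5) by the sign of z and adjusts
per direction across sets with Benjamini–Hochberg.

## Numerical choices and degenerate inputs

- z-cap 38 (p underflow); stratum z with zero pooled variance maps to
  ±cap (or 0 when groups are identical).
- Untestable strata/CpGs are flagged, never silently dropped.
- Empty hit lists: fold undefined (NaN), p = 1, flagged.
- All file formats are comma-separated UTF-8 with mandatory headers;
  missing beta cells are empty or `NA` on disk; floats are written with
  shortest-round-trip repr so read∘write is the identity.
- Every stochastic step (splits, folds, grids, simulations) is driven by
  explicit seeds; pipelines derive stage seeds from one root seed.

## Known limitations

- Dynamic estimation needs labeled strata with ≥ 2 controls and ≥ 2
  treated samples; it is undefined for single-sample experiments.
- The library grid is configurable but modest by default; the framework
  is designed for thousands of recipes, not millions, on one CPU.
- Plain OLS in the EWAS means no variance moderation for very small n.
- Survival handling is correlation only; no hazard models.
- Human-data specifics (composite mortality predictors, array manifests)
  are out of scope; cross-species support is limited to the relative-age
  transform and user-supplied shared-CpG subsets.
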