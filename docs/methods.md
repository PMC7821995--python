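# Methods

## Model

`amenbn` fits conditional linear Gaussian (CLG) Bayesian networks to mixed
feedstuff data. The joint distribution factorizes along a DAG; discrete
nodes (category, ingredient, animal) carry multinomial CPTs conditioned on
their (necessarily discrete) parents, and each continuous node (AMEn, CP,
EE, ash, CF) carries one ordinary-least-squares Gaussian regression on its
continuous parents per joint configuration of its discrete parents. CLG
legality — no continuous parent of a discrete child — is enforced at the
graph level (`add_arrow`, `check_clg_legal`), not just at scoring time, so
illegal structures can never be constructed, proposed or deserialized.

Assumptions inherited from the model class: within each discrete
configuration the target is linear in the covariates with homoscedastic
Gaussian noise; configurations are parameterized independently (no pooling
of residual variance across configurations, which is the more conservative
reading of per-configuration equations).

## Conditional-independence tests

* **G²** (discrete/discrete): 2·Σ o·ln(o/e) over stratified contingency
  tables; zero cells contribute 0 (0·ln 0 := 0); degrees of freedom use
  declared level counts, (|X|−1)(|Y|−1)·Π|Z|, **not** adjusted for empty
  strata. Simple, and exactly what the test-suite oracles recompute.
* **Fisher's z** (continuous/continuous): partial correlation via residuals
  of linear projections on the conditioning set, z = atanh(r)·√(n−|Z|−3).
* **CG likelihood ratio** (mixed): twice the log-likelihood difference
  between nested CLG local models for the continuous member of the pair,
  with the other variable entering as an extra regressor (continuous) or
  extra stratification (discrete); df = free-parameter difference, clamped
  to ≥ 1. When the pair and the conditioning set are all continuous the
  call delegates to Fisher's z to avoid a duplicated code path.
* Both-discrete pairs with continuous conditioning variables are tested by
  G² on the **discrete part** of the conditioning set: in a CLG-legal DAG
  every continuous node on a path between two discrete nodes is a collider,
  so conditioning on continuous variables can only open paths, never block
  them.
* Degenerate inputs (constant variables, one-level factors, too few rows)
  report independence (statistic 0, p = 1) instead of raising inside
  learning loops, keeping MMPC total; the same conditions raise typed
  errors when tests are called directly with insufficient data.
* The constraint-phase significance level defaults to α = 0.05
  (conventional choice; nothing in the problem fixes it).

## Structure learning

MMPC forward phase admits, per iteration, the candidate with the smallest
worst-case p-value (maximum over subsets of the current candidate set),
provided it is below α; candidates whose worst-case association loses
significance are discarded permanently. The backward phase removes any
admitted member independent of the target given some subset of the rest.
Test results are cached under a symmetric key and the dispatcher counts
actual test computations for reporting. The skeleton keeps edge {X, Y} only
if each endpoint is in the other's candidate set (AND rule).

The CLG-BIC score is ℓ − (k/2)·ln n per node: multinomial likelihood with
the full declared parameter count for discrete nodes; per-configuration
Gaussian regressions for continuous nodes counting (retained slopes +
intercept + variance) per non-empty configuration. A relative variance
floor (10⁻⁹ of the node's total variance) keeps exactly-interpolating
configurations finite without masking genuine near-determinism.

Hill climbing searches add/delete/reverse single-arrow moves from the empty
DAG, skipping cycle-forming and CLG-illegal moves, restricting additions to
skeleton edges when a restriction is given, and accepting the best move with
score gain > 10⁻⁹. Ties break lexicographically on (operation, parent,
child), making the search deterministic and seed-independent; the `seed`
argument exists for interface symmetry. In-degree is not capped — the
reference target node has seven parents — the skeleton is the only
restriction. `rsmax2(restrict_fn, maximize_fn)` generalizes the two-phase
recipe; the other constraint learners of the bnlearn family (GS, IAMB
variants, SI-HITON-PC, TABU) are deliberately out of scope and would plug
into that hook.

## Parameter fitting and equations

`fit_clg` computes maximum-likelihood CPTs (empirical conditional
frequencies; uniform rows for unobserved parent configurations) and
per-configuration OLS equations. Residual variance uses the MLE denominator
n_config for consistency with the BIC likelihood; coefficient standard
errors use the unbiased denominator. Rank-deficient or undersized
configurations drop covariates in reverse declaration order (for the AMEn
parents cp, ee, ash, cf: first cf, then ash, then ee, then cp) until the
design is estimable; dropped covariates are recorded on the equation and
rendered as "-" in tables. This order-based rule reproduces the reference
table's two missing cells (ash and CF absent from the energy/cockerel/
by-product row) and is a convention: whether those printed "-" cells meant
non-estimable covariates or unreported values is not knowable, so the
drop-to-full-rank reading was adopted once. A configuration with no rows at
all yields a flagged equation (n_config = 0) carrying the grand mean of the
target with every covariate dropped, keeping fitting total.

Equation tables order configurations category-major, then animal, then
ingredient, levels in declared order.

## Validation metrics

Errors are e = predicted − observed (positive bias = over-prediction);
MSE = mean e², MAD = mean |e|, MAPE = 100·mean(|e|/observed), bias = mean e,
PMSE = √MSE (i.e. RMSE, consistent with the published MSE/PMSE pair), r is
the Pearson correlation of predicted vs observed and R² := r². R² as
squared correlation was chosen over 1 − SSE/SST because the two published
fit statistics (r = 0.94, R² = 0.87) are mutually consistent only
approximately under either definition; the choice is documented, not
calibrated. Train/test splits are seeded permutations with
round(n·fraction) training rows. Head-to-head comparison counts, per
sample, which of two predictors is closer in absolute error; ties are
reported separately, never assigned.

## Synthetic-data generator

The generator emulates the (non-deposited) 568-experiment meta-analysis by
ancestral sampling down the reference DAG. Defaults encode the study
conditions where published: n = 568, 370/568 energy vs 198/568 protein, the
twelve published equations as AMEn mean structure, and per-variable
truncation envelopes set to the published training min/max (AMEn
[1170, 4386] kcal/kg, CP [1.47, 71.44] %, EE [0.03, 26.21] %, ash
[0.30, 12.61] %, CF [0.02, 26.50] %). Where the source data give only
summary statistics, shapes were chosen once as the simplest forms matching
them:

* CP per category: truncated Gaussians, energy (9.5, 4.0), protein
  (49.0, 10.0) — the 370/198 mixture reproduces the published overall mean
  (≈23.4%) and right-skewed median.
* EE ~ N(4.87, 4.0), CF ~ N(4.93, 4.5), matching published means.
* ash = 1.0 + 0.08·CP + 0.14·CF + N(0, 1), matching the published ash mean
  at the covariate means and realizing the cp→ash←cf structure.
* AMEn residual SD 150 kcal/kg — comparable to the per-ingredient spread of
  the published external-validation errors.
* Ingredient mixes are category-specific (energy 0.55/0.30/0.15, protein
  0.45/0.25/0.30) and animals split 0.6/0.4 chick/cockerel. Distinct
  ingredient mixes matter: identical mixes would make the
  category→ingredient arrow carry no dependence, leaving the generating
  distribution unfaithful to its own DAG and that arrow unlearnable in
  principle.

Truncation is per-variable rejection sampling (resample up to 1000 rounds,
then clip). It is approximate by design: rejection on a *child* variable
distorts its conditional distribution, so datasets with truncation enabled
are **not** exact draws from the generating CLG network. Concretely,
configurations whose equation mean approaches the AMEn envelope (about 1%
of rows, concentrated in two cockerel configurations) acquire
truncated-response bias of up to tens of standard errors in the OLS
coefficients. Parameter-recovery checks therefore sample with truncation
disabled — they test the fitter against its own model class — while
structure-recovery checks keep truncation on, since skeleton and
orientation discovery are robust to it. What passing tests show about real
data is correspondingly limited: the generator reproduces the dependency
structure, envelopes and first moments of the source material, but not
inter-experiment heterogeneity, non-Gaussian composition shapes, or
measurement-error correlation across covariates.

## Problem sizes and numerical choices

Structure-recovery experiments use n = 5000 (10 seeds, median structural
Hamming distance ≤ 3 expected, typically 0–1); coefficient recovery uses
2000 rows per configuration; test calibration uses 1000 null replicates.
These sizes give Monte-Carlo noise well inside the asserted bounds while
keeping the full suite fast. Variance floor 10⁻⁹·var(node); score-gain
threshold 10⁻⁹; CPT rows validated to sum to 1 within 10⁻⁹. The
false-admission rate of MMPC under the null is the theoretically expected
one for a level-α procedure (≈ α·(p−1) admissions per target, so ~82% of
targets come back empty with five independent variables at α = 0.05);
bounds in the null tests are set from that theory, not from observed runs.

## Known limitations

* No CPDAG/equivalence-class output: score-equivalent orientations of
  covered continuous–continuous edges are resolved by the deterministic
  tie-break, not reported as undirected.
* No pooled residual variance, no Bayesian posteriors, no prediction
  intervals.
* The CG-LRT's chi-square reference is asymptotic; in tiny strata its
  calibration degrades (the dispatcher's p = 1 fallback keeps learning
  total but conservative there).
* `CLGResults.simulate` samples untruncated; envelope truncation is a
  generator-level feature.
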