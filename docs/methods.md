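# Methods

## Model

A risk equation is an additive logistic model over binary clinical
conditions:

```
R(x) = Σ_{j ∈ S} w_j x_j + b,        P(y = 1 | x) = σ(R) = 1 / (1 + e^(−R)),
```

with `x_j ∈ {0, 1}` the indicator of a threshold rule (`value < lower`,
`value ≥ upper`, `a ≤ value < b`, `== category`), `S` the selected set,
`w_j` real weights and `b` a bias.  The model family is deliberately
restricted to addition so the fitted equation reads as a points system:
`score_j = round(w_j · scale)` with `scale = 100` by default.

Assumptions: conditions act additively on the log-odds; thresholds carry
the clinically relevant signal (information inside a reference range is
discarded by design); patients are exchangeable (no time-varying or
hierarchical structure).

## Condition generation

Continuous variables with only a clinical reference range `(lower,
upper)` emit the two out-of-range flags `< lower` and `≥ upper`; the
in-range state is their complement and would be redundant as a third
column.  When extra threshold cuts are configured, the ordered cut list
defines a full left-closed partition: `< c_0`, `[c_i, c_{i+1})` per
consecutive pair, `≥ c_k`.  Ties at a cut resolve left-closed /
right-open, so at most one partition condition is active per patient.
Ordinal variables (e.g. the 4-level serology class Negative < NegGray <
PosGray < Positive) emit both cumulative directions `≥ class` and
`< class` for every class above the lowest; nominal variables emit one
dummy per level; binary variables emit `== True`.

## Preprocessing

Decoding precedes filtering: clipped strings `">n"` / `"<n"` become `n`;
serology cells split into a numeric titer column (counted positives keep
their titer, counted negatives and `ND` become 0, count-free positives
stay missing) and a 4-level ordinal class column; an explicit `ND` is a
determination (titer 0), distinct from a missing cell, which is left for
imputation.  Columns with variance ≤ 0 (constants) or more than 50%
missingness are dropped; the outcome column never is.  Imputation is
Shapiro–Wilk guided (α = 0.05): continuous columns consistent with
normality get the mean, otherwise the median; categorical, ordinal and
binary columns get the mode (smallest on ties).  Stable patient-specific
measures flagged in the schema (height, weight) are mean-imputed and
gain a 0/1 missingness-indicator column, since their absence can itself
be informative.  Observed cells are never altered and row count is
conserved throughout.

The train/test split is stratified: the positive test count is the
nearest integer to `m · test_fraction` (ties toward more positives in
test), the negative count rounds the other way, so the outcome ratio is
preserved within one subject.  Stratified 5-fold CV labels are assigned
on the training portion.  Everything is deterministic given the seed.

## Evolutionary search

Candidate models are `+`-only expression trees whose leaves index the
condition pool; flattened, a program is a multiset of conditions.  For
fitness, the program's de-duplicated term set is refit by
ridge-penalized logistic regression minimizing
`mean log-loss + ridge·‖w‖²` (ridge 10⁻⁴, bias unpenalized; the tiny
ridge keeps weights finite under separation) and scored as that refit
training log-loss plus a parsimony penalty of 10⁻³ per program leaf.
Duplicated leaves therefore never multiply weights; they only pay extra
parsimony.  The per-term penalty was set so that a pure-noise binary
condition's expected in-sample gain (≈ 1/(2n) for n in the hundreds to
thousands) does not justify inclusion.

One generation: the elite (best program) survives unchanged; the rest of
the population is produced by mutually exclusive operations — crossover
of two tournament winners (p = 0.7), subtree / hoist / point mutation of
a tournament winner (p = 0.05 each by default), or plain reproduction.
Hoist mutation replaces a random subtree by one of its own subtrees and
can only shrink a program; point mutation swaps one leaf for a random
pool condition; subtree mutation grafts a fresh random tree.  Search
stops after `max_generations` or when the best fitness has not improved
by 10⁻⁴ for 5 consecutive generations.  Elitism makes the best-fitness
trace non-increasing by construction.

After the evolutionary loop a memetic refinement polishes the winning
term set under the same penalized fitness: greedy passes that drop a
term, swap a term for another condition *on the same variable*
(threshold neighbours are highly correlated and easily interchanged by
the stochastic search), or add the single best pool condition, until a
full pass finds no improvement (at most 3 passes).  This makes the
returned equation locally optimal in its 1-change neighbourhood; it can
be disabled via `GPConfig(local_search=False)`.

Defaults (`GPConfig`): population 1000, ≤ 50 generations, tournament
size 20.  The tests and the acceptance script use a reduced search
(population 150–400, ≤ 40 generations) — on pools of ~200 conditions
and cohorts of 245–2000 patients this reliably reaches the same
solutions the large configuration finds.

### Mutation-probability tuning

`tune()` minimizes 5-fold cross-validated log-loss (evolve on four
folds, score the held-out fold) over `(p_hoist, p_point, p_subtree) ∈
[0, 0.1]³` with Gaussian-process Bayesian optimization: 5 uniform
initial points, then expected-improvement acquisition on a Matérn-5/2
surrogate (scikit-learn `GaussianProcessRegressor`, normalized targets,
small white-noise term), maximized over a candidate cloud of 2048
uniform points plus 256 local jitters of the incumbent.  20 evaluations
total; a failed evaluation is recorded at the worst value seen so far
and the run continues.

## Evaluation

The empirical AUC is the mean of the tie-aware kernel φ(X, Y) = 1 if
X > Y, ½ if X = Y, 0 otherwise over all positive–negative score pairs,
computed via sorted-array placement values.  Its variance uses the
DeLong structural-components estimator `s²(V10)/m + s²(V01)/n` with
normal-approximation CIs clipped to [0, 1]; a degenerate zero variance
(perfect separation) collapses the CI to a point with a warning.  The
classification threshold maximizes Youden's J = sensitivity +
specificity − 1 over the unique observed out-of-fold scores, with the
rule `score ≥ threshold` and ties in J resolved to the smallest
threshold (within a 10⁻⁹ float margin, so mathematically tied J values
compare as ties regardless of rounding path).  Accuracy, recall and F1
get percentile bootstrap CIs (default 2000 unstratified patient-level
replicates; a replicate without positives is redrawn and logged).
Decision curves report `NB(p_t) = TP/N − (FP/N)·p_t/(1−p_t)` on a
default grid 0.00–0.60 (step 0.01) next to treat-all and treat-none.

## Univariate screening

Continuous variables use the Welch unequal-variance t-test — computable
from raw samples or from printed `mean (SD), n` summaries, which lets
published baseline tables be re-checked exactly.  (The Welch form, not
the pooled t, reproduces the published transfusion p-values 0.005 and
0.009 from the summary statistics.)  Categorical variables use the
Pearson chi-square test, by default without continuity correction and
with a Yates flag available, per-variable α = 0.05, no multiplicity
correction.

## Sequential reduction

`apply_cutoff` keeps terms whose integer presentation score is ≥ the
cut-off (so negative-weight terms fall at any non-negative cut-off) and
by default refits weights and bias over the survivors on the training
rows.  `reduction_trace` scans a cut-off grid and reports surviving size
and validation AUC, where validation is cross-validated on the training
folds only — weights refit per fold, fold-wise out-of-fold AUCs
averaged.  Fold-wise averaging rather than pooling matters: pooled OOF
predictions mix fold-specific intercepts, which systematically depresses
the measured AUC of coarse-grained (few-term) scores.  The held-out test
split is never consulted during reduction.  `select_cutoff` returns the
AUC-maximizing cut-off, ties resolved toward the larger cut-off (the
smaller model).  Because the reduced set was itself selected using all
training rows, this validation AUC is optimistically biased relative to
a fresh cohort; the test split gives the honest estimate.

## Synthetic cohorts

The generator emulates the raw-table pathologies the pipeline must
survive: per-variable missingness (completely at random), clipped
numeric strings for the top quantile of selected labs, serology cells
rendered in counted (`"Positive (32)"`) and count-free
(`"Negative Gray"`, `"ND"`) forms.  Covariates are drawn independently —
normal or lognormal for labs (skewed analytes lognormal, so both
imputation branches are exercised), categorical draws elsewhere — the
planted equation is evaluated on the pristine numeric values, and the
outcome is Bernoulli(σ(R)).  True probabilities are returned alongside,
and by construction the outcome is exactly calibrated to them.

`default_bsi_scenario` mirrors a 245-patient liver-transplant cohort:
~77 raw variables across seven categories (demographics, medical
history, preoperative clinical status, paired admission/preoperative
labs, viral serology, surgery), ~200 candidate conditions after
encoding, and a planted equation over transfusion volume (`RBC ≥ 12`,
w = 1.1), preoperative renal replacement (`CRRT == True`, w = 1.0),
intraoperative hypothermia (`Max OR Temp < 36 °C`, w = 0.9) and
non-positive hepatitis-B core antibody (`anti-HBc class < PosGray`,
w = 0.8).  The bias −1.823 was calibrated once, numerically, so the
expected prevalence equals the 82:163 case ratio; the planted model's
own AUC is ≈ 0.71.

What passing tests on these cohorts do **not** show: real EHR data has
correlated covariates, informative missingness beyond the optional
outcome-dependent mode, drifting assay scales and label noise — so
recovery rates and AUCs here bound the method's behaviour under its own
assumptions, not its clinical performance.

A caveat worth knowing: because the pool contains logically related
encodings of the same signal (cumulative ordinal cuts, their
complements, and the collinear titer column), the maximum-likelihood
solution on a finite cohort occasionally represents a planted serology
rule through an equivalent or neighbouring parameterization rather than
the exact planted cut.  Recovery is therefore assessed up to exact
complements (`1 − x` with refit intercept is the identical model), and
threshold instability of this kind should be expected on real cohorts
too.

## Numerical choices

Logistic refits use scikit-learn's lbfgs solver (`C = 1/(2 n ridge)`,
tol 10⁻⁸) and raise on non-convergence.  Fitness values are cached per
term set within one evolve call.  Sigmoids are computed in the
numerically stable split form.  All randomness flows from explicit
`numpy.random.default_rng` seeds; identical seeds give identical
equations term for term and byte-identical synthetic tables.

## Known limitations

No non-additive operators or continuous-feature leaves; no handling of
longitudinal or censored outcomes (screening is cross-sectional); the
bootstrap is unstratified and can redraw in tiny cohorts; Bayesian
tuning assumes a smooth objective and only three hyperparameters; the
generator draws covariates independently, so condition collinearity in
real data is understated except where encodings of the same variable
overlap by construction.
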