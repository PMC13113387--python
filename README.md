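# riskeq

Interpretable additive risk equations for clinical binary outcomes,
learned by **addition-only symbolic regression** over threshold
conditions derived from clinical reference ranges.

## The problem

Clinicians predicting a post-operative complication — the motivating
case is bloodstream infection after liver transplantation — need models
they can read, audit and apply at the bedside. `riskeq` trades raw
predictive power for transparency: instead of a black-box classifier it
searches for a risk equation

```
R  =  Σ_{j ∈ S} w_j · x_j  +  b,          ŷ = σ(R) = 1 / (1 + e^(−R)),
```

where every `x_j ∈ {0, 1}` indicates a clinically meaningful threshold
rule such as `BUN ≥ 23.6`, `RBC transfusion ≥ 12 units`, `CRRT == True`
or `anti-HBc Ab < PosGray`, `w_j` is its risk weight, and `b` is a
constant.  Rescaled and rounded, the weights become an integer points
system.  The package is aimed at biostatisticians and clinical ML
researchers building such score systems from EHR-style tabular data.

## What it does

* **Cohort encoding** (`riskeq.encoding`) — raw EHR tables with missing
  cells, clipped numeric strings (`">12.0"`) and 4-level serology labels
  (`"Positive (32)"`, `"Gray Negative (2)"`, `"ND"`, …) are decoded,
  filtered (variance and >50% missingness), imputed (Shapiro–Wilk test
  decides mean vs median; mode for categoricals; missing-value indicator
  columns for stable patient measures like height), and binarized into a
  patient × condition 0/1 design matrix using reference ranges and
  threshold cuts, with a stratified 80/20 split and 5-fold CV labels.
* **Symbolic-regression engine** (`riskeq.engine`) — a genetic program
  over `+`-only expression trees whose leaves are conditions.  Each
  candidate's weights are refit by ridge-penalized logistic maximum
  likelihood; fitness is the mean training log-loss plus a small
  parsimony penalty per term.  Tournament selection, elitism, hoist /
  point / subtree mutations, early stopping, and a memetic local
  refinement of the final term set.  The three mutation probabilities
  can be tuned by Gaussian-process Bayesian optimization over
  [0, 0.1]³ against 5-fold cross-validated log-loss.
* **Evaluation** (`riskeq.evaluation`) — empirical (Mann–Whitney) AUC
  with the tie-aware kernel, DeLong placement-component variance and
  normal CIs, Youden-J threshold selection from out-of-fold predictions,
  bootstrap CIs for accuracy / recall / F1, and decision-curve net
  benefit `NB(p_t) = TP/N − (FP/N)·p_t/(1−p_t)` against the treat-all
  and treat-none strategies.
* **Univariate screening** (`riskeq.stats`) — Welch t-tests (from raw
  data or from published mean/SD/n summaries) and chi-square tests.
* **Sequential reduction** (`riskeq.reduction`) — iteratively prune
  terms whose integer score falls below a cut-off, tracking per-fold
  validation AUC to find the most compact equation that keeps
  discrimination.
* **Synthetic cohorts** (`riskeq.simulate`) — a generator that emulates
  the raw-table pathologies above with the outcome drawn from a known
  planted risk equation, so the whole pipeline is testable end to end
  without any patient data.

## Worked example

```python
import riskeq as rq
from riskeq.simulate import schemas_for

cfg = rq.default_bsi_scenario(seed=1, n_patients=245)
raw, truth = rq.generate(cfg)                      # raw table + ground truth
clean, design, report = rq.encode_cohort(raw, schemas_for(cfg.variables), "BSI")
design = rq.stratified_partition(design, test_fraction=0.2, k_folds=5, seed=1)

gp = rq.GPConfig(population_size=200, max_generations=30, tournament_size=10,
                 early_stop_patience=8, seed=1)
eq = rq.evolve(design, gp)
print(rq.integer_score_table(eq).head(5).to_string(index=False))

te = design.test_mask
roc = rq.delong_interval(rq.ScorePair.from_labels(
    eq.predict_prob(design.X.loc[te]), design.y[te]))
print(f"test AUC {roc.auc:.4f} (95% CI {roc.ci[0]:.4f}-{roc.ci[1]:.4f})")

cuts = sorted({s for s in (int(round(w*100)) for _, w in eq.terms) if s >= 0} | {0})
trace = rq.reduction_trace(eq, design, cutoffs=cuts)
c, a = rq.select_cutoff(trace)
reduced = rq.apply_cutoff(eq, c, refit=True, design=design)
print(f"reduction: cut-off {c:g} keeps {len(reduced)} terms, validation AUC {a:.4f}")
```

Output:

```
           variable    range  score
      CMV IgM_preop      ≥10    585
   Neutrophil_preop     <1.5    491
CMV IgG_preop class <NegGray    422
             Na_adm     ≥146    401
   AntiHBc Ab_preop      <10    331
test AUC 0.5663 (95% CI 0.3664-0.7662)
reduction: cut-off 263 keeps 9 terms, validation AUC 0.7069
```

Reading it: on a 245-patient synthetic cohort (33% outcome prevalence,
198 candidate conditions) the evolved 46-term equation — like any model
this size fit to 196 training subjects — overfits, with a modest
held-out AUC of 0.57 on 49 test patients and a wide DeLong interval.
The sequential reduction then prunes it to 9 high-scoring terms at
cut-off 263, *raising* cross-validated AUC to 0.71: the compact score
system generalizes better than the full equation.  The score column is
`round(100·w_j)`; a patient's total maps to risk via the sigmoid.

The same workflow is available from the shell:

```sh
riskeq simulate --seed 1 --n 245 --out cohort.csv --schema schema.yaml
riskeq encode   --table cohort.csv --schema schema.yaml --out design.csv --seed 1
riskeq fit      --design design.csv --seed 1 --out model.json
riskeq evaluate --model model.json --design design.csv --out report.json
riskeq reduce   --model model.json --design design.csv --out trace.csv
```

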