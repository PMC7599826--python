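# Methods

`repairscore` builds and applies a gene-expression prognostic model for
cytogenetically normal AML (CN-AML) in which the unit of information is a
*dichotomized* gene: each candidate probe set is split at the expression
threshold that best separates overall survival, and the model is a frozen
collection of such thresholds, their Cox effect sizes, and downstream
grouping rules. This note documents the statistical machinery, the
defaults, and the choices made where the design was genuinely open.

## Model and procedure

**Endpoints.** Right-censored overall survival (OS, days) by default;
event-free survival (EFS: progression, relapse or death) is a drop-in
alternative endpoint. All tests are two-sided with alpha = 0.05.

**Per-gene cutpoints (maximally selected log-rank statistics).** For a
continuous marker x, every midpoint between consecutive distinct values is
a candidate threshold, restricted so the low group (x <= c) holds between
10% and 90% of patients (`minprop`/`maxprop`). For each candidate the
two-sample log-rank statistic is computed in its linear-rank form: with
log-rank scores a_i = d_i − Λ̂(t_i) (Λ̂ the Nelson–Aalen cumulative hazard
at the patient's own time), the statistic for the split is the score sum
of the high group standardized by its permutation mean and variance. The
cutpoint is the argmax of the absolute standardized statistic; equal
values can never be separated; ties in the argmax resolve to the smallest
threshold.

**Selection-adjusted p-values.** Because the statistic is maximized over
many correlated candidate splits, its null distribution is that of the
maximum of a dependent family. Three evaluations are provided:

* `approx` (default): the split statistics converge jointly to a Gaussian
  vector whose correlation between splits at low-group proportions
  p_i <= p_j is sqrt(p_i(1−p_j)/(p_j(1−p_i))). The distribution of the
  maximum absolute coordinate is evaluated by simulating that limiting
  vector (20 000 draws, fixed internal seed, cached per candidate grid),
  so the p-value is deterministic and exactly 1 at statistic 0. We chose
  this over the closed-form improved-Bonferroni bound because, on the
  dense candidate grids this pipeline produces, the bound is badly
  conservative: against a 2000-permutation reference on null data the
  bound's mean absolute error is ≈0.2 while the Gaussian evaluation's is
  ≈0.01, and its type-I rate at 0.05 sits inside [0.02, 0.09].
* `bonferroni`: the closed-form improved-Bonferroni upper bound from the
  bivariate margins of consecutive splits (Owen's T), kept for users who
  want a guaranteed bound.
* `permutation`: Monte-Carlo re-maximization on label-permuted scores;
  requires a seed; used in tests as the independent oracle.

**Dual-cohort gene screen.** Each candidate probe set receives a
selection-adjusted p-value per cohort; Benjamini–Hochberg adjustment is
applied *within cohort across all candidates* (one family per cohort and
endpoint), and a gene enters the panel only if adjusted p < alpha in both
cohorts. The membership decision is symmetric in the two cohorts, but the
frozen quantities — the cutpoint and the Cox beta — always come from the
designated training cohort. Beta is the Cox log hazard ratio of the
*dichotomized indicator* [expression > cutpoint], not of continuous
expression: the scoring weights are ±beta, so the effect size must live on
the same dichotomized scale.

**Pathway risk scores.** For pathway P with members i, the per-patient
score is sum_i beta_i * s_i, with s_i = +1 if expression_i is strictly
above the gene's cutpoint and s_i = −1 at or below it (ties take the low
branch). A probe set annotated to two pathways contributes fully to both.
Consequences used as test invariants: the score range is
[−Σ|beta_i|, +Σ|beta_i|], and moving one gene across its cutpoint moves
the score by exactly 2|beta_i|.

**Pathway dichotomization and retention.** Each continuous pathway score
is itself dichotomized by the same maxstat machinery (high risk = score
above its cutpoint); a constant score drops the pathway with a warning.
All pathway high/low flags then enter one multivariate Cox model, and
pathways with Wald p < alpha are retained (constant flags are excluded
beforehand and reported; univariate hazard ratios are reported alongside).

**Global risk groups.** With k retained pathways, patients with zero high
flags are group I, with all k high group III, and anything in between
group II. For the reference case k = 2 this is exactly the low/low,
mixed, high/high partition; the k ≠ 2 mapping is our generalization and
is so documented.

**Combined classification.** NPM1/FLT3-ITD points follow the established
CN-AML rule (NPM1-mutated without ITD: 0; ITD without NPM1 mutation: 2;
otherwise 1 — any ITD counts, since allelic ratios are typically not
available); DNA-repair points are 0/1/2 for groups I/II/III; totals span
0–4. Consecutive point classes are merged by a greedy ascending pass:
test class k against k+1 by log-rank; if p >= alpha merge and re-test the
merged block against the next class; otherwise advance. The traversal
order is a convention (the merge rule itself does not fix one); ascending
matches the natural reading of "consecutive groups" and produces the
{0,1} / {2} / {3,4} structure on risk ladders with breaks after 1 and 2
points. Final blocks are labelled A, B, C, … in ascending risk. Point
totals unobserved during training map to the block covering their
position, so frozen maps are total over 0–4 (validation cohorts with
empty classes are labelled by position, never refitted).

**Frozen application.** Applying a model to any cohort re-estimates
nothing: cutpoints, betas, pathway thresholds, retained set and merge map
are read from the model document (versioned JSON, lossless round-trip).
Application is deterministic and invariant to patient order.

## Survival machinery

Kaplan–Meier estimation, log-rank tests and Efron-ties Cox fits are
delegated to lifelines; Breslow-ties Cox to statsmodels PHReg; BH to
statsmodels. Conventions: KM confidence bands use the log-log
(exponential Greenwood) transform; the median is the smallest event time
with S(t) <= 0.5 and is reported as "NR" (not reached) when the curve
never gets there; median follow-up is the reverse-KM (censoring
distribution) median; Cox ties default to Efron (day-resolution survival
data has ties). Complete separation is reported as a flagged
non-converged fit (with lightly ridge-stabilized coefficients) rather
than an exception or silent garbage; constant and collinear covariates
are errors naming the offending columns.

## Synthetic cohorts

The generator produces the structure the pipeline assumes, so every stage
is testable without any download:

* 175 candidate probe sets over BER/NER/MMR/HRR/NHEJ/FANC (default sizes
  30/35/20/35/25/30); log-scale Gaussian expression, per-gene means drawn
  once per *gene universe* from U(5, 11), sd 1.0.
* Planted prognostic genes: survival hazard is multiplied by the gene's
  hazard ratio when its expression exceeds a cutpoint planted at a
  quantile of the gene's marginal distribution (default the median) — a
  step effect, matching what the method estimates. Defaults plant five
  HRR and five NER genes with hazard ratios 0.55–2.5, the range the
  reference panel reports.
* Planted genes of one pathway co-vary through a shared latent factor
  (default loading rho = 0.5; risk genes load +, protective genes −;
  marginals unchanged). This emulates the co-expression modules that make
  pathway-level deregulation observable in real microarray cohorts. It is
  also statistically necessary: with fully independent planted genes, ten
  multiplicative HR-2.2 effects act as mutual frailty and shrink every
  *marginal* dichotomized hazard ratio to ≈1.5, which no screening
  procedure can separate from noise at these sample sizes.
* Exponential survival (baseline 1.7e-4/day, calibrated once so a
  training-like cohort's median OS falls in the 250–550 day range
  observed for intensively treated CN-AML); NPM1 (prevalence 0.50,
  HR 0.55) and FLT3-ITD (prevalence 0.48 training / 0.22 validation,
  HR 2.0) multiply the hazard; EFS is min(relapse, death) with relapse
  hazard 1.6× the death hazard.
* Censoring: independent exponential, with the rate *solved by bisection*
  so the expected censored fraction matches the configured target
  (default 0.25), plus an administrative horizon at 2500 days.
* Two-cohort studies share one gene universe and truth record
  (`universe_seed`) with independent patient draws; identical configs
  reproduce byte-identical cohorts.

What the generator does **not** emulate: probe-level microarray
artifacts, normalization (expression is generated already normalized),
batch effects, gene-gene correlation outside planted modules, non-
proportional hazards, informative censoring, and competing risks. Passing
tests therefore demonstrate the statistical correctness and calibration
of the pipeline under its own assumptions, not performance on any real
cohort.

## Problem sizes and numerical choices

Test simulations use the scales the method targets: 160–200 patients per
cohort, 175 candidate genes, 100 replicates for null calibration and 50
for recovery; the maxstat oracle comparisons use 100 exhaustive datasets
(n ≤ 30) and 50 × 2000 permutations. Cox fits iterate Newton steps to
lifelines' defaults; the Gaussian max-distribution cache holds ≤128
grids; degenerate inputs (constant markers, empty candidate windows,
all-censored groups, single point classes) raise typed errors or warn and
degrade as documented above.

## Known limitations

* The analytic maxstat p-value is a normal approximation; for n below
  ~25 or extreme censoring the permutation method is preferable.
* The greedy ascending merge does not revisit earlier boundaries after a
  later merge; with pathological risk ladders a different traversal could
  yield a different (equally defensible) partition.
* Group assignments for k ≥ 3 retained pathways compress k−1 intermediate
  states into group II.
* The reference 23-gene panel ships without per-gene cutpoints (they were
  never published), so it documents membership and directions but cannot
  score patients; scoring requires training on cohorts.
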