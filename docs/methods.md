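# Methods

## Problem

Given training data with a binary response, p candidate features, a
strictly positive acquisition cost c_i per feature, and a hard budget
c_max, the task is to find the subset s minimizing a model-quality
criterion Q subject to the knapsack constraint

    sum_{i : X_i in s} c_i  <=  c_max.

All selectors in this package use Q = AIC of a logistic regression of the
response on the member features plus an intercept,

    AIC(s) = 2 (|s| + 1) - 2 loglik(s),

so that goodness of fit and model size are traded off inside the
criterion itself, giving greedy search an implicit stopping rule.  The
parameter count includes the intercept, matching the convention of
standard statistical software.

## Scoring model

The logistic fit is a Newton/IRLS iteration (weighted least squares per
step, minimum-norm solve for rank-deficient designs such as duplicated
columns).  Iterations are capped at 100 with convergence tolerance 1e-8
on the coefficient step.  Under complete separation the MLE diverges; the
fit then returns the achieved penalized likelihood with `converged=False`
and selectors treat the candidate as valid but flagged, so a search never
aborts on one pathological subset.  The test suite cross-checks
coefficients and AIC against an independent maximum-likelihood
implementation.  Predictive performance is the rank-based AUC of the
fitted linear predictor on held-out data (midrank ties), verified against
direct pairwise enumeration.

Budget comparisons use an absolute tolerance of 1e-9 so sets that fill
the budget exactly are not excluded by round-off.

## Selectors

**FS (naive forward selection).**  Iteratively adds the affordable
candidate with the largest raw AIC decrease; candidates whose individual
cost exceeds the remaining budget are excluded from the iteration.  Stops
when no affordable candidate improves the AIC.

**cFS family (benefit-cost ratio).**  Ranks affordable candidates by
BCR_xi = (AIC(s) - AIC(s + X_i)) / (c_i + xi).  xi = 0 is the pure ratio
(cFS); xi = mean(c) (cFS.mean) and xi = max(c) (cFS.max) shift the
ordering back towards raw benefit — as xi grows the ranking converges to
the FS ordering.  xi is resolved once on the full cost vector, not on the
shrinking candidate pool.  A custom xi is accepted for cost distributions
where mean or max are outlier-dominated.  Ties are broken by lowest
feature index.  Because the BCR shares its sign with the AIC gain, the
stopping rule is unchanged: stop when no affordable candidate has
positive gain.

**fGA (fitness-adapted genetic algorithm).**  Standard bit-vector GA
(linear-rank survivor selection, uniform crossover, single-feature toggle
mutation) with a graded fitness that encodes constraint violation:

    fitness(s) = 1 - costs(s)/c_max    if costs(s) > c_max   (negative)
               = 1 / AIC(s)            otherwise              (positive)

The graded negative branch gives the population a gradient from large
violations towards the feasible region; the sign encodes feasibility
exactly (a non-positive AIC inside the budget would break that contract
and raises).  Infeasible individuals never cost a model fit.  The default
start population includes each feature with probability
min(1, c_max / sum c_i), so the expected start cost equals the budget;
`init="uniform"` (coin-flip per feature) is available to study behaviour
when the search starts deep in the infeasible region.  The returned set
is the best feasible individual ever evaluated; when none was found the
result says so explicitly (`feasible=False`).

**cGA (cost-preserving genetic algorithm).**  All operators that could
create violations are replaced with budget-closed versions, so the
fitness is simply the negative AIC:

* *Initialization* — random forward selection: starting empty, each step
  returns the current set with probability p_stop (default 1/500, which
  favours large, budget-filling start sets), otherwise draws a uniformly
  random untried feature and adds it if it fits the remaining budget; the
  first unaffordable draw terminates.
* *Crossover* — features in both parents pass to both children; features
  in exactly one parent are visited in random order and assigned to one
  child by a fair coin, added only if that child's remaining budget
  allows.
* *Mutation* — the add/remove decision is made in advance with
  P(add) = 1 - costs(s)/c_max; an add picks uniformly among absent
  features that fit, falling back to a random removal if none does; a
  remove drops a uniform random member (an empty set is returned
  unchanged — under the decision rule that branch has probability zero
  but remains reachable through configuration).

Each operator maps feasible inputs to feasible outputs, so every
individual ever evaluated satisfies the budget (fuzz-tested).

Shared GA machinery: population 500, at most 150 generations, convergence
after 10 consecutive generations without best-fitness improvement
(absolute tolerance 1e-12), linear-rank selection (weight proportional to
fitness rank, worst 1 .. best m), crossover applied to 80% of selected
pairs and mutation to 10% of individuals per generation, and 1-elitism
(the best individual so far re-enters each generation unchanged), which
makes the best-so-far fitness non-decreasing.  Elitism and the operator
rates are configuration with those defaults.  AIC evaluations are
memoized by member set, which matters enormously once the population
concentrates.

**Filter baselines.**  Welch two-sample t-test p-values (lower is better)
and symmetric uncertainty SU = 2 I(X;Y)/(H(X)+H(Y)) after equal-frequency
discretization into 10 bins (higher is better), plus an adapter for any
external per-feature importance function.  The budget-constrained subset
is built top-down in rank order: affordable features are added,
unaffordable ones skipped (a skipped feature never blocks later
affordable ones; a strict stop-at-first-misfit variant is available as a
flag), and the walk stops when no remaining feature fits or the next
importance crosses a threshold (defaults: 0.05 for the t-test, 1e-6 for
symmetric uncertainty, none otherwise).  Features whose score cannot be
computed (zero variance in both groups) rank last.

## Budget definition

The simulation framework sets the budget relative to the total cost of
the truly relevant features through gamma >= 0:

    c_max = sum_{i relevant} c_i I(c_i <= q_gamma)          if gamma <= 1
          = sum_{i relevant} c_i + (gamma-1) c_bar p_rel     if gamma > 1

where q_gamma is the gamma-quantile of the relevant-cost distribution and
c_bar the mean cost of *all* features.  The quantile is implemented as
the inclusive empirical order statistic at ceil(gamma * p_rel), so
gamma = 0.5 with an even relevant count admits exactly the cheapest half;
the two branches agree at gamma = 1.  A consequence worth noting: the
budget admits at most the cheapest ceil(gamma * p_rel) relevant features,
so recall is hard-capped at ceil(gamma * p_rel)/p_rel — equal to gamma
exactly when gamma * p_rel is an integer, as it is in every shipped
setting.

## Synthetic settings

The default generative model draws y ~ Bernoulli(0.5) and then
X | y=1 ~ N_p(mu, Sigma), X | y=0 ~ N_p(0, Sigma) with Sigma = I_p; mu
has the effect size beta on the first p_rel coordinates and 0 elsewhere
(or the descending graded sequence p_rel/p_rel, ..., 1/p_rel for the
graded-effect settings).  Train size 500, test size 10 000, 100
replicates per setting by default; costs ~ U(0.1, 1) unless a setting
says otherwise.  Eleven presets (A-K) vary p in {30, 300, 1500}, p_rel in
{3, 15, 18, 20, 30}, beta in {0.3, 0.5, 1} and gamma in {1/3, 1/2, 2/3, 2}:

* Setting G replaces the class-conditional draw with X ~ N_p(0, Sigma)
  and y_i ~ Bernoulli(expit(x_i' mu)), because under correlated features
  the class-conditional construction creates artificially separable
  two-feature structures.  The covariance originally estimated from a
  proprietary metabolomics dataset is not available; a synthetic
  block-exchangeable substitute (consecutive blocks of 5 features with
  within-block correlation 0.7, unit variances — both configurable)
  emulates highly correlated covariables without claiming to reproduce
  the original structure.
* Setting H draws relevant costs ~ U(0.4, 1) (mean 0.7) and noise costs
  ~ U(0.1, 0.7) (mean 0.4), modelling expensive information.
* Setting J couples cost to effect: c_i ~ U(0.1 + mu_i/2, 0.5 + mu_i/2).
* Setting K replaces the Gaussian noise with a per-cell scale mixture:
  N(mu_i, 1) with probability 0.9 and N(mu_i, sd=5) with probability 0.1
  (variance 3.4, positive excess kurtosis).  The second component's
  spread is read as a standard deviation, the usual convention in the
  robustness literature for contamination mixtures; it is a configuration
  field (`heavy_tail_sd`) and no headline result depends on the exact
  value.

What the generator does *not* emulate: real measured-spectra feature
distributions (binned NMR intensities with many extreme outliers),
response imbalance from logistic generation on skewed features, and
empirically estimated covariance structure.  Passing tests on these
settings therefore demonstrate correctness of the algorithms under the
stated models, not performance guarantees on any particular real assay.

Replicate b of a study uses the seed master_seed + b, so every experiment
is exactly repeatable from one integer.

## Evaluation

Feature recovery is summarized by precision (selected ∧ relevant /
selected) and recall (selected ∧ relevant / relevant) from the 2x2
contingency of relevance against selection.  Precision of an empty
selection is reported as missing and excluded from aggregation rather
than forced to 0 or 1.  Two analytic references: random selection has
expected precision p_rel/p independent of subset size (hypergeometric
expectation), and expected recall c_max/(mean cost * p) (capped at 1)
after estimating the typical affordable model size as c_max/mean(c) —
the latter depends on the realized costs, so it is reported per
replicate.  Benchmark output is a tidy long-format table (setting,
method, replicate, metric, value) with per-setting reference rows;
aggregation reports the mean and the 0.05/0.95 quantiles, and a method
failure on one replicate is recorded as a diagnostic row rather than
aborting the study.

## Reproduction studies and problem sizes

`costselect.repro` re-derives the package's headline numbers at sizes
chosen for a single CPU; these are the package's own study conditions:

* the easy-setting replication (gamma=2/3, p=30, p_rel=3, beta=1) runs 30
  replicates with a 2 000-sample test set; the budget excludes exactly
  the most expensive relevant feature, so the expected outcome is mean
  recall 2/3 and precision 1;
* the recall-cap sweep uses the two p=30 presets plus a p=120/p_rel=12
  reduction of the strongly constrained p=300 scenario (keeping
  gamma * p_rel integral so the cap equals gamma), 3 replicates each,
  with the GA at population 100;
* the exhaustive-search oracle enumerates all feasible subsets at p=10
  and runs the cost-preserving GA 50 times with a generous budget
  (population 150, up to 200 generations, patience 40, mutation 0.3);
* the feasibility-crossing run uses 298 unit-cost features, budget 10,
  and the coin-flip start population, so the best-so-far fitness starts
  around -14 and must climb through the graded violation region;
* operator closure is fuzzed over ~12 000 individuals with random cost
  vectors (p in 5..60) and budgets.

`scripts/acceptance.py --seed S --out FILE` runs all of these and writes
the resulting numbers as JSON; everything is computed at run time.

## Known limitations

* The AIC restricts the scoring model to likelihood-based fits; other
  performance measures under cross-validation, and non-logistic learners,
  are out of scope.
* Costs are additive and per-feature; group-structured costs and
  soft-margin cost/performance trade-off objectives are not modelled.
* The JMIM and random-forest-impurity filters from the wider filter
  literature are supported only through the external-scorer adapter, not
  re-implemented.
* Greedy forward selection offers no approximation guarantee for the
  non-submodular AIC objective; the exhaustive-oracle study measures its
  gap only at toy scale.
* Run-time comparisons between methods are hardware-dependent and are
  reported per replicate as wall time without further analysis.
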