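# Methods

## Scope

`snakeswarm` implements a hybrid of the Snake Optimizer (SO) and Particle
Swarm Optimization (PSO) — here called PSSO — as a general bound-constrained
minimizer, and wraps it in a feature-selection + hyperparameter-tuning
engine for imbalanced clinical tabular classification: imputation,
standardization/one-hot encoding fitted on the training partition,
SMOTE-ENN rebalancing, wrapper search, multiclass evaluation, and a
perturbation-robustness protocol. All randomness flows from one root seed
through named substreams, so every reported number is recomputable.

## The optimizers

All three algorithms minimize an objective `f : R^d -> R` over an
axis-aligned box `[lower, upper]`, with a population of `N` candidates run
for `T` iterations, and are elitist: the best-ever solution (the "food"
position `L_food`) is never lost and the per-iteration trace of best
fitness is non-increasing by construction.

**Environment signals.** Two scalars gate snake behaviour as functions of
the iteration counter `C`:

    Q    = K1 * exp((C - T) / T)        (food quantity, K1 = 0.5)
    Temp = exp(-C / T)                   (temperature)

`Q` rises from `K1/e` to `K1` and `Temp` falls from 1 to `1/e` over the
run, moving the population from exploration toward exploitation.

**Snake Optimizer.** The population is split into `floor(N/2)` males and
the rest females. Each iteration runs one of three modes:

- *Exploration* (`Q < 0.25`): each snake moves around a random same-sex
  reference `S_R`, scaled by a foraging-ability coefficient
  `AB = exp(-f_R / f_i)`:
  `S' = S_R ± K2 * AB * ((upper - lower) * R + lower)`, `K2 = 0.05`.
- *Food-following* (`Q >= 0.25`, `Temp > 0.6`):
  `S' = L_food ± K3 * Temp * R * (L_food - S)`, `K3 = 2`.
- *Fight or mate* (`Temp <= 0.6`): one uniform draw per iteration selects
  fighting (attraction to the best of the opposite sex, coefficient
  `FA = exp(-f_oppbest / f_i)`) or mating (attraction to the food-scaled
  position of an index-paired partner, coefficient
  `MA = exp(-f_mate / f_i)`, displacement `K3 * MA * R * (Q * S_mate - S)`).
  After mating, with probability 0.5 ("egg hatching") the worst male and
  worst female are replaced by fresh uniform positions.

The `±` diversity operator is an independent Bernoulli(0.5) sign per
candidate per update. The exponential coefficients require positive
fitness values; objectives are shifted by `f' = f - f_best_seen + eps`
(`eps = 1e-9`), which preserves ordering for any objective sign.

**PSO.** Standard inertial velocity update

    V' = w*V + C1*r1*(P_i - X) + C2*r2*(P_g - X),   X' = X + V'

with per-dimension `r1, r2 ~ U(0,1)`, velocity clamped to
`±0.1 * (upper - lower)` per dimension (matching the 0.1 factor of the
velocity initialization `V0 = rand * 0.1 * (upper - lower)`), and positions
clipped to the box. Defaults `w = 0.5`, `C1 = 0.8`, `C2 = 0.9`.

**PSSO.** The hybrid adds a snake-derived environmental displacement to the
PSO velocity:

    V' = w*V + C1*r1*(P_i - X) + C2*r2*(P_g - X) + dSO

with, per candidate,

    dSO = ± K3 * Temp * R3 * (L_food - X)              if Q > 0.25
    dSO = ± K3 * FA * R3 * (S_oppbest - X)             otherwise, fight draw
    dSO = ± K3 * MA * R3 * (Q * S_mate  - X)           otherwise, mate draw

reusing the SO movement forms so the hybrid degrades gracefully toward SO
behaviour, with the same per-candidate `±` diversity sign. The sign and the
`Q`-scaled mate displacement matter in practice: attraction-only variants
collapse the swarm onto the incumbent best before the optimal corner of a
discrete (mask-encoded) search space has been visited, which shows up
directly as failures to match the exhaustive-enumeration optimum on
8-feature problems. A configuration scale `so_weight` multiplies `dSO`;
at 0 the hybrid update is bit-identical to plain PSO (verified exactly in
tests, via the named-substream RNG design).

**Seeding.** Each stochastic component (initialization, signs, mode gates,
snake draws, particle draws) uses its own `(root seed, name)` substream, so
changing how one component consumes randomness never shifts another's
stream — this is what makes the PSO-reduction identity exact rather than
approximate.

## Wrapper feature selection

A solution is one real vector: one dimension per candidate feature (raw
box `(0,1)`, bit = value >= 0.5, an empty mask repaired to the largest raw
value) plus the classifier's hyperparameter dimensions (raw box `(1,100)`,
mapped affinely for integers, log-affinely for SVM's `C` and `gamma`).
Fitness is

    fitness = alpha * Error + (1 - alpha) * n_selected / n_total

with `Error = 1 - mean stratified 5-fold CV accuracy` of the wrapped
classifier (RF, DT, RBF-SVM, or KNN) on the balanced training partition,
folds fixed by the seed. The held-out test partition is never touched
during the search (checksummed in the pipeline).

`alpha` defaults to 0.9. The choice is deliberate and sits between two
failure modes. The parsimony term contributes `(1 - alpha)/n_total` per
feature (≈ 0.003 at 31 features), which must exceed the fold-level
fluctuation of CV error between masks (a few tenths of a percent at these
sample sizes) for subset size to influence the search at all; with `alpha`
very close to 1 the selection degenerates to error-only search and retains
uninformative features at random. Pushed much lower (e.g. 0.85), the
penalty starts pruning features whose marginal value on the *balanced*
CV folds is small but whose absence costs noticeably more on imbalanced
held-out data — typically the sole marker of a rare class. Error remains
dominant at 0.9. Fitness evaluations are memoized on the decoded encoding
(identical mask + hyperparameters), which changes nothing numerically.

Joint optimization of mask and hyperparameters in a single vector was
chosen over a two-pass scheme as the simplest coherent reading of a
wrapper that does both.

## Preprocessing and balancing

- Rows missing more than half their feature cells are dropped; remaining
  numeric gaps take the column mean, binary/categorical gaps the column
  mode; duplicates removed. Idempotent.
- Standardization and one-hot encoding are fitted on the training
  partition only; unseen test categories map to all-zero blocks;
  zero-variance columns are scaled by 1 and flagged.
- The split is stratified (default 80/20). Unstratified slices of a
  50:20:15:10:5 class mix would frequently leave rare classes degenerate.
- SMOTE-ENN runs after the split, on the training partition only, on the
  encoded matrix (Euclidean distances): SMOTE oversamples each minority
  class to the majority count by `x + gap*(nn - x)`, `gap ~ U(0,1)`, `nn`
  among `k_smote = 5` same-class neighbours; ENN then removes, from all
  classes simultaneously, every sample whose label disagrees with a strict
  majority of its `k_enn = 3` nearest neighbours (ties keep the sample).
  Pre-split balancing is available behind a flag for protocol comparison
  but leaks synthetic copies of training information into the test set and
  is not the default. SMOTE parent indices and gaps are recorded so every
  synthetic point's collinearity with its parents is auditable.

## Metrics

One-vs-rest tallies per class; precision, recall, per-class accuracy, F1,
specificity from the usual formulas; zero-denominator metrics defined as 0
with a flag (keeping weighted averages defined on sparse classes).
Aggregation is support-weighted; overall accuracy is plain correct/total
and error rate its complement. AUC is the rank statistic (Mann-Whitney,
half credit for ties) per class one-vs-rest, exact against pair counting.
The with/without-optimizer comparison is a one-way ANOVA over repeated
accuracies.

## Synthetic data

The thyroid-like generator emulates a clinical screening table: 31 mixed
columns — half log-normal "lab analyte" columns, half Bernoulli "history
flag" columns — five classes with priors (0.50, 0.20, 0.15, 0.10, 0.05),
six informative features, and injectable uniform missingness. Each
informative feature *marks one class* (assigned round-robin): a numeric
marker is elevated by `effect_size` on the log scale (in units of the
within-class sd) for samples of its class; a binary marker's rate is
`logistic(effect_size/2)` for its class and the complement elsewhere. The
marker design mirrors how distinct analytes flag distinct thyroid
conditions and, unlike a shared monotone class gradient, makes every
informative feature necessary — so selection quality is meaningfully
scorable against the ground-truth mask. `effect_size` defaults to 4,
calibrated by pilot run so that a classifier restricted to the true
informative set reaches ≥ 0.95 held-out accuracy.

What the generator does **not** emulate: correlated analytes, measurement
ceilings/floors, label noise, covariate shift between sites, or any match
to a real cohort's joint distribution. Passing recovery tests therefore
demonstrates the machinery works under known ground truth, not clinical
performance.

## Robustness protocol

Perturbations are applied to the raw data before preprocessing so the
pipeline's own imputation is exercised: exactly `round(frac * n_cells)`
feature cells deleted (label never touched); Gaussian noise of sd `sigma`
on the standardized scale (scaled by each raw column's sd, equivalently);
induced imbalance in which every non-majority class loses `round(frac *
count)` random samples — at 0.5, each is halved. The default condition set
is 5/10/20% missingness, `sigma = 0.01` noise, and 50% imbalance.

## Problem sizes

Test and acceptance runs use: sphere 10-D, `N=30, T=100`, 20 seeds;
mask-enumeration oracle at `d=8` (256 masks), `N=20, T=50`, 20 seeds;
feature recovery at `n=2000, d=31`, `N=20, T=50`, DT wrapper, 10 seeds;
pipeline comparisons at `n=1200` with `N=10, T=25`. These sizes give
stable pass/fail statistics while keeping a full run of the suite and the
acceptance script in the minutes range on a single core.

## Known limitations

- The SO fight/mate mode is entered once per iteration (not per
  candidate); the source material does not fix this and the per-iteration
  gate mirrors the original SO.
- Temperature semantics follow the original SO (`Temp > 0.6` = hot =
  food-following); the alternative "chilly" reading is internally
  inconsistent.
- KNN's `n_neighbors` upper bound (100) is not tied to fold size; on very
  small datasets decoded values can exceed what a fold supports.
- SMOTE on one-hot blocks produces fractional indicator values for
  synthetic points; distances remain well-defined, but the synthetic rows
  are not valid categorical records. This matches the standard practice of
  resampling in the encoded space.
- No parallel evaluation, constraint handling beyond box bounds, early
  stopping, or discrete-specific SO variants.
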