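# Methods

`isletdx` implements a two-class microarray classification pipeline:
preprocessing, four dimensionality-reduction (DR) operators, two swarm
feature selectors, ten classifiers trained against numeric class targets,
and a cross-validated evaluation grid. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Data model and preprocessing

The carrier is a genes x samples matrix of strictly positive microarray
intensities with a per-sample binary label (diabetic / non-diabetic;
diabetic is the positive class everywhere). Preprocessing (i) keeps the
`n_top_genes` genes with the largest maximum intensity across samples —
ranking per gene, not per patient, so that all samples share one gene set
and the matrix stays rectangular; (ii) applies log10; (iii) standardizes
each sample column to mean 0 and variance 1 with the population divisor
(n), so a standardized column re-standardizes to itself to machine
precision. Zero-variance columns and non-positive intensities are
rejected rather than patched.

## Dimensionality reduction

Three deterministic, label-free operators split the gene axis into
consecutive windows of length `dr_window` (default 8; the full-scale
pipeline's 22,960 -> 2,870 reduction) and summarize each window per
sample. The final short window is zero-padded.

* **Bessel projection.** Each window is projected onto J_0 sampled at
  `window` equispaced abscissae on (0, x_max], normalized by the basis
  vector's norm. x_max defaults to the first zero of J_0 (2.404826...),
  so the basis vector has no sign change. J_n itself is evaluated from
  its power series by a term recurrence in 45-digit decimal arithmetic:
  the series alternates with terms growing to ~(x/2)^{2r}/(r!)^2, and a
  double-precision sum loses up to seven digits near x = 20; the
  extended-precision sum keeps the absolute error below 1e-10 for
  |x| <= 20, n <= 10 (checked against `scipy.special.jv`). The derivative
  operational matrix D (first row from J_0' = -J_1, interior rows from
  J_n' = (J_{n-1}-J_{n+1})/2, last row from J_n' = J_{n-1} - (n/x) J_n)
  is validated against finite differences and the Sturm-Liouville
  residual; finite-difference steps are ~1e-6 (first derivative) and
  2e-4 (second derivative), chosen near the rounding/truncation optimum.
* **DCT.** The orthonormal type-II DCT of each window, keeping the first
  `n_coeffs` coefficients (default 1, the DC term). Orthonormality gives
  Parseval equality and an exact inverse, both tested.
* **LSLR.** The leading least-squares direction of the gene-centered
  window block (first left singular vector); each sample's feature is the
  projection of its raw window onto that direction, the rank-1 summary
  minimizing reconstruction SSE. The sign is fixed so the
  largest-magnitude loading is positive; an all-constant window maps to
  feature 0 with a logged warning. The operator is deliberately
  label-free so no class information leaks into DR.

The fourth DR operator is selection-based (below).

## Swarm selection

All three metaheuristics search continuous positions in [0,1]^G, decode a
position to its `k` top-weighted genes (ties to the lowest index), and
score the subset with a filter fitness: the mean per-gene Fisher
discriminant ratio (mu_dia - mu_ctrl)^2 / (s2_dia + s2_ctrl + 1e-12),
sample variances with ddof=1. The ratios are precomputed once per
training set, so one candidate evaluation is a top-k decode plus a mean.
A filter (rather than wrapper) fitness keeps selection
classifier-independent and fast; the global optimum of this fitness is
simply the top-k genes by ratio, and the recovery experiments therefore
measure how closely each swarm approaches that optimum.

* **Artificial algae (AAA).** Colonies carry biomass H (Monod growth
  H <- mu H with mu_max = 1, mu from min-max normalized fitness mapped to
  [0.5, 1] so no biomass collapses to zero) and starvation. Moves are
  helical: three random coordinates step toward a 2-way-tournament-chosen
  target, scaled by (shear Delta - friction tau), tau = 2 pi (3H/4 pi)^(2/3)
  (hemisphere surface of the colony volume); one coordinate moves
  linearly (factor p in [-1,1]), the others by cos/sin of random angles.
  Moves are greedy (kept on improvement) under a per-iteration energy
  budget (`energy_loss` 0.3; successful moves cost half). Colonies that
  fail to improve accrue starvation; with probability `adaptation_prob`
  the hungriest colony blends toward the biggest. The evolutionary step
  replicates one random cell (coordinate) of the biggest colony into the
  smallest. Elitism is memory-only: the best position ever evaluated is
  recorded and returned but not reinjected.
* **Elephant herding (EHO).** Single-herd form: followers blend toward
  the fittest member, y <- y + alpha (y_best - y) r with one scalar
  r ~ U[0,1] per follower; the fittest member is reset to beta x the herd
  centre; the least-fit member is re-drawn per dimension as
  y_min + (y_max - y_min + 1) rand — kept in this literal form so the
  printed rule is testable, then clamped into bounds.
* **Dragonfly (DOA).** Five forces — separation, alignment, cohesion,
  attraction to the best-so-far position ("food"), diversion from the
  worst-so-far ("enemy") — plus inertia on the step vector, each force
  weight multiplied by a fresh 2 x rand per fly per step (the randomized
  attraction keeps the swarm sampling around the food instead of
  collapsing onto it). The default neighborhood is global: in a
  high-dimensional unit cube pairwise distances concentrate near
  sqrt(F/6), so any fixed small radius isolates every fly; a finite
  radius with a random-walk fallback for isolated flies remains
  config-exposed. Steps are clamped to `step_clamp` x the bound range.

Three parameter choices differ from the most literal reading of the
printed update rules, each because the literal form provably degrades the
search and each switchable back via config:

1. whole-population replication (copying the entire best position over
   the smallest colony every iteration) collapses the AAA swarm onto one
   point within ~20 iterations; replication is per-cell, as in the
   original algorithm;
2. `adaptation_prob` defaults to 0.2 rather than 0.5: every adaptation
   event blends a full position toward the biggest colony, and at 0.5 the
   swarm homogenizes long before the iteration budget is spent;
3. the printed enemy term (enemy + self) adds a positive drift that pins
   coordinates at the upper bound; the default is the classical
   (enemy - self) diversion (`da_literal_enemy=True` restores the printed
   form). Similarly EHO's leader reset uses beta = 0.5: with beta = 0.1
   the reset drags the leader toward the origin corner of the mask cube.
   The DOA separation weight decays 0.3 -> 0.1 instead of to zero, so
   some exploration pressure survives late iterations.

All randomness flows from one `numpy` generator per run; identical seeds
give identical trajectories. With elitist memory, best-fitness traces are
monotone by construction for any objective.

## Classifiers

Regression-style models train against numeric class targets: 0.1
(non-diabetic) and 0.85 (diabetic). The encoding is valid only when the
targets differ by at least 0.5 (enforced at construction); decisions
threshold the continuous output at the midpoint 0.475, with a score
exactly at the threshold going to non-diabetic.

* **NLR** — f(x) = t0 + t1 sigmoid(t2 + x.w), the minimal nonlinear
  family consistent with a two-target regression, fit by
  Levenberg-Marquardt (damped normal equations, damping x10 on rejection,
  /10 on acceptance); accepted steps never increase the objective.
* **LR** — linear regression by batch gradient descent (rate 0.01);
  features are standardized internally because fixed-rate descent assumes
  comparable scales, and the scaling is undone at predict time.
* **GMM** — one g-component (default 2) full-covariance Gaussian mixture
  per class, fit by a hand-rolled EM that exposes the per-iteration
  log-likelihood trace (non-decreasing by the EM guarantee, asserted in
  tests); responsibilities initialize from nearest-seed hard assignment;
  covariances carry 1e-6 diagonal loading; emptied components re-seed
  from a random point. Prediction is the larger prior-weighted density.
* **EM** — a 2-component mixture on the pooled, label-free training data;
  components map to classes by majority training label (with a logged
  single-class fallback when both map the same way).
* **BLDC** — Bayesian linear regression onto the targets: prior precision
  alpha on the weights (the bias row carries epsilon = 1e-6, effectively
  unpenalized), noise precision beta; posterior mean and covariance are
  closed-form, predictive variance 1/beta + b' X b is exposed. As
  beta -> inf, alpha -> 0 the posterior mean is the least-squares
  solution (tested to 1e-4).
* **LoR** — L2-penalized logistic regression by gradient ascent from
  zero, intercept unpenalized; the step size shrinks with the penalty's
  contribution to the gradient's Lipschitz constant so strong priors stay
  stable. Decision threshold 0.5 (0.48 exposed in config).
* **SDC** — softmax discriminant: class score log sum_j exp(-lambda
  ||v - v_j||^2) over the class's training samples (log-sum-exp
  stabilized, lambda = 0.5 default); at lambda = 0 every score is
  log(class size); exact ties go to the lower class index (diabetic
  first).
* **SVM** — soft-margin dual (box [0, C]) with linear, polynomial
  ((gamma x.z + 1)^d, d = 2 default) and RBF (exp(-gamma ||x-z||^2),
  gamma = 1/(2 sigma)^2 convention) kernels, solved by scikit-learn's
  SMO backend at tolerance 1e-6; the dual objective is exposed and
  checked against an independent projected-gradient solver. Printed
  hyperparameter defaults: linear C = 0.85; poly C = 0.76, gamma = 10;
  RBF C = 1, gamma = 100. The RBF/poly gammas are scale-specific to the
  original study's DR outputs (whose variances are ~1e-2); on
  unit-variance data gamma = 100 degenerates to a majority-class
  predictor, so scale-sensitive experiments pass `gamma="scale"`
  (1/(F Var)) instead. Optional k-means support thinning (2 clusters, 3
  random points each, retrain on the 6) is implemented but off by
  default — retraining on six points is a severe approximation.

## Evaluation

Stratified 10-fold cross-validation (stratification keeps 2 diabetic + 5
non-diabetic per fold at the default 20/50 cohort; disable via config).
Fold metrics are aggregated by pooling the per-fold confusion matrices,
giving integer counts on the full sample set. The metric suite is
accuracy, F1, MCC, error rate, Fowlkes-Mallows (geometric mean of
precision and recall) and Cohen's kappa with its Po/Pe intermediates; any
metric with a zero denominator reports 0 with a degenerate flag, which
matches the published chance-level row where MCC = kappa = 0. Per Eq-65
style MSE, continuous models report their raw outputs against the encoded
targets; decision-only models report the encoded value of their predicted
label.

`solve_confusion` inverts the metric suite: given class sizes and a
printed (accuracy, F1) pair it exhaustively searches all integer
(fn, fp) pairs for the unique matrix consistent with both to 5e-5,
erroring on zero or multiple solutions. Published values are truncated at
four decimals, so audits compare at the printed truncation.

The grid runner sweeps 4 DR x {none, EHO, DOA} x 10 classifiers = 120
rows. Deterministic label-free DR runs once on the full matrix;
label-dependent stages (AAA gene selection, EHO/DOA feature selection)
re-fit inside every training fold, so no test label influences
selection. Per-stage seeds derive from the master seed via CRC-hashed
`SeedSequence` spawning, so changing one stage's seed leaves the others'
streams untouched. A row that fails is marked failed with its error and
the grid continues.

## Synthetic data

The generator emulates the shape of the pancreatic-islet study: log10
intensities 10^(base + gene offset + signal + noise) with base =
log10(300), per-gene baseline spread SD 0.5 (so the peak-intensity filter
ranks something real), noise SD 0.3 on the log scale, 20 diabetic vs 50
non-diabetic samples. Informative windows are aligned to the reduction
window grid; every gene in them gains effect_size x noise_sd (default
2.0 x 0.3) on the log scale in the diabetic class before per-sample
standardization (which attenuates but cannot erase a per-gene shift).
The desk scale is a 10x linear shrink of the full pipeline: 2,296 genes
-> 287 windowed features -> ~28 selected.

What it does not emulate: probe-level correlation structure, batch
effects, heavy-tailed intensity noise, or any real biological covariance
between genes. Passing recovery and grid tests therefore demonstrates
that the algorithms behave as specified under their own assumptions, not
that they would attain any particular accuracy on real islet data.

## Benchmark scales and budgets

The recovery experiment (2,296 genes, 4 planted windows, 10 seeds) runs
the AAA gene-selection stage for 1,200 iterations and the feature
selectors for 3,000 — budgets at which the best-subset fitness has
plateaued at this dimensionality; the swarm defaults of 20 members remain.
Recovery is scored per stage as the fraction of planted genes available
to that stage that it retains, against a chance level equal to the
stage's keep fraction (287/2296 ~ 1/8 and 28/287 ~ 1/10). At these
budgets the AAA stage retains ~0.7 of the planted genes and EHO ~0.69 of
those available to it; DOA plateaus near 0.54 — its force vectors
perturb every coordinate at once, which suits continuous landscapes but
makes single-gene swaps (the improving moves of a subset problem) rare,
and no parameterization we examined lifts it past ~0.6 on every seed
set. The sphere benchmark and the 120-row grid (one full run plus two
flagship-only replicates) complete in a few minutes on one CPU.

## Known limitations

* The per-gene Fisher-ratio fitness ignores gene-gene interactions by
  construction; a wrapper fitness would capture them at ~100x the cost.
* The EM classifier with full covariances is rank-deficient when features
  outnumber samples; diagonal loading keeps it running but its
  high-dimensional decisions degenerate toward the majority class.
* Published headline accuracies from the original cohort are not
  reproduction targets here: they require the external dataset. What is
  reproduced exactly is the internal consistency of the published metric
  rows (confusion-matrix reconstruction) and the qualitative claims on
  synthetic data.
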