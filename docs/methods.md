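# Methods

## The modelling problem

Gene regulatory networks (GRNs) describe how transcription-factor-encoding
genes (TFs) regulate target genes.  Microarray expression compendia are
large-p-small-n — thousands of genes, a few hundred samples — and contain
dependencies of mixed order: a few TFs act as hubs with many targets, while
co-regulated targets show strong local dependencies.  `grnlearn` implements
two families of Gaussian probabilistic network models for reconstructing
GRNs from such data, an exact conversion between them, and a gold-standard
evaluation harness.

## Models

**Gaussian Bayesian network (GBN).**  A DAG plus linear-Gaussian
conditionals: each gene `X_i` given its parent set is normal with mean
`mu_i + sum_j beta_ij (X_j - mu_j)` and conditional variance `nu_i`.
Structure is learned by greedy hill climbing (HC) from the empty graph over
add/delete/reverse single-edge moves, maximizing the decomposable BIC

    BIC(G) = sum_i [ loglik_i(MLE) - (k_i/2) log n ],  k_i = |Pa_i| + 2.

`k_i` counts the regression coefficients, intercept and residual variance of
node i; the BIC literature is not unanimous on whether the intercept/variance
are counted, and this choice only shifts all scores by a structure-independent
constant plus one `log n / 2` per parent, so move decisions match the common
Gaussian-BIC convention.  Local scores are computed from the centered Gram
matrix (one small linear solve per candidate parent set) and memoized by
(node, parent set); a move invalidates only the affected nodes.  Ties are
broken deterministically (add < delete < reverse, then lexicographic
(child, parent)).  Reversal moves are enabled by default and there is no
parent cap; both are flags.  Greedy search can stop in a local optimum —
normal termination, recorded in the trace; on exhaustive 3-variable
enumeration the measured optimum rate is reported by `scripts/acceptance.py`.

**Precision network (PN).**  A pairwise Markov network whose edges are the
nonzero off-diagonals of the precision matrix `Theta = Sigma^{-1}`.  Three
penalized maximum-likelihood learners:

* **glasso** — `log det Theta - tr(S Theta) - sum lambda_ij |theta_ij|`,
  solved by block coordinate descent with an inner cyclic coordinate-descent
  lasso per column (active-set passes between full passes).  The scalar-λ
  form penalizes the diagonal (`W` initialized to `S + lambda I`);
  element-wise penalties with a separate diagonal vector are supported and
  are what the scale-free variant needs.
* **hglasso** — the hub decomposition `Theta = Z + V + V^T` with penalty
  `lambda1 ||Z||_1 + lambda2 ||V'||_1 + lambda3 sum_j ||V'_j||_2`
  (`V' = V - diag V`), solved by ADMM with an extra split `Vt = V^T` so every
  subproblem is closed-form (eigen-step for Theta, soft-threshold for Z,
  element-wise + column-group soft-threshold for V).  `rho = 2.5`, stop when
  primal/dual residuals < 1e-5.  V is kept hollow: the diagonal of Theta is
  carried entirely by Z, so hub columns are pure off-diagonal structure and
  the `lambda2, lambda3 -> inf` limit reduces exactly to glasso at lambda1.
  Exit enforces exact feasibility via `Z := Theta - V - V^T`.
* **sfglasso** — replaces the l1 edge penalty with the concave
  `alpha sum_i log(||Theta_-i||_1 + eps_i)` plus diagonal penalties
  `beta_i = 2 alpha / eps_i`, maximized by majorize-minimize: a uniform-
  penalty glasso solve at `lambda = alpha` (the scale on which the log
  penalty's supporting line sits at the first iterate), then `n_reweights`
  re-weighted glasso solves with
  `lambda_ij = alpha (1/(||Theta_-i||_1 + eps_i) + 1/(||Theta_-j||_1 + eps_j))`
  and `eps_i` equal to the previous iteration's `theta_ii`.  Default
  `n_reweights = 2`, excluding the initial uniform solve
  (`include_initial=True` counts it).  Each re-weight records the power-law
  objective before/after under that iteration's weights; by the MM argument
  it is non-decreasing up to solver tolerance.

A note on the likelihood term: some presentations write `log det(S Theta)`,
which differs from `log det Theta` by a Theta-independent constant and is
undefined for singular S (n < p).  All internal objectives use
`log det Theta`.

**Transformation.**  Writing the GBN as `x = mu + B(x - mu) + e` with
`B[child, parent] = beta` and `Cov(e) = diag(nu)`:

    Sigma = (I-B)^{-1} diag(nu) (I-B)^{-T},
    Theta = (I-B)^T diag(nu)^{-1} (I-B).

The coefficient-matrix orientation is pinned by the verifiable contract
`Theta @ implied_covariance = I` (checked to 1e-8 in the tests).  The moral
graph (skeleton + marriages of co-parents) contains the support of Theta;
individual entries can still cancel to exactly zero, which is logged.  For
evaluation the reported undirected edge set of a transformed BN is the moral
graph (a flag switches to the numeric support of Theta).

## Synthetic data generator

Emulates the structure of the DREAM5-style in silico benchmark without the
kinetic simulation: a directed network whose edges all originate at TFs,
with TF out-degree weights proportional to `rank^(-hub_exponent)` so a
minority of TFs are hubs; TF->TF edges run only from lower to higher rank,
guaranteeing a DAG; targets then follow a linear-Gaussian structural
equation model sampled in topological order; decoy TFs and decoy targets are
independent noise.  Defaults are the benchmark's published counts: 178 TFs,
1370 targets, 4012 edges, 17 + 78 decoys, n = 805.  Remaining knobs, chosen
once: `hub_exponent = 1` (a mild Zipf-like skew; the benchmark publishes no
degree law), coefficient magnitudes uniform on [0.3, 1.0] with Rademacher
signs (avoids both vanishing effects and a degenerate all-positive
correlation structure), residual sd 1.  `sample_expression` returns the raw
samples together with the true generating model so estimates can be checked
against the truth exactly; standardization (mean 0, sd 1, n-1 denominator)
is applied by the `simulate` command and by `run_sweep` before learning,
matching the uniformly normalized scale of real compendia.

What the generator does **not** reproduce: nonlinear/kinetic regulation,
experimental-condition block structure, heteroscedastic noise, missing
data.  Tests passing on this generator therefore certify the algorithmic
contracts (scores, optimality certificates, exact transformations, scoring
arithmetic) and the qualitative learner ordering under linear-Gaussian
conditions — not performance on real microarray data.

## Evaluation

An undirected edge {a, b} is a true positive iff the directed gold standard
contains a->b or b->a.  "Connected TF" means a TF with degree >= 1 (the only
network-size-free reading).  precision = TP/|E|, recall = TP/P with
P = number of parsed gold edges (the count is surfaced; published sources
occasionally disagree with themselves about P).  In `tf_only` mode, edges
between two non-TF genes are removed before both measures, with |E|
re-counted — the DREAM5 convention.  Self-loops are stripped before scoring;
gold edges touching genes absent from the expression matrix are dropped from
P with a logged count.  FP/TN-based quantities are emitted with a caution
header: curated gold standards are incomplete, so an unmatched edge is not
necessarily wrong.

## Study sizes and numerical choices

* Matched-size benchmark (`grnlearn.benchmark`): 20 TFs + 180 targets,
  400 gold edges, n = 800, glasso at lambda = 0.6; the HC snapshot is the
  greedy-path iterate whose moral edge count is closest to the glasso edge
  count.  10 seeds in the test suite, 5 in the acceptance script.
* Glasso convergence: mean absolute off-diagonal change of W per sweep
  < tol x mean |off-diagonal of S| (floored to the diagonal mean when S is
  diagonal); default tol 1e-6, 500 sweeps; inner lasso tol 1e-9.
* Variance floor: MLE residual variances are clamped at 1e-12 with a
  RuntimeWarning so noiseless fixtures cannot produce a degenerate
  likelihood.
* Edge binarization: `|theta_ij| > 1e-10` after symmetrizing
  `Theta <- (Theta + Theta^T)/2`.
* Hill-climbing improvement threshold 1e-9: score-equivalent moves (equal
  BIC) are never accepted, preventing cycling between equivalence-class
  members.
* One integer seed drives each generator run; topology and sampling consume
  documented child streams in a fixed order, so every artifact is
  reproducible from (config, seed).

## Known limitations

* Greedy HC has no restarts or tabu list; network-size control is by
  checkpointing a single greedy path, not by re-running with modified
  scores.
* The ADMM used by hglasso is first-order: agreement with an independent
  solver is at the 1e-3/1e-4 objective level, not machine precision.
* sfglasso's log penalty is non-convex; only monotone improvement of the
  objective is guaranteed, not a global optimum.
* No cross-validated penalty selection, bootstrap averaging, or
  constraint-based/hybrid BN learners.
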