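# Methods

## The model

`coslir` infers a signed, weighted, directed gene-gene interaction
matrix from *time-stamped cross-sectional* single-cell expression data:
two cohorts of cells measured at consecutive stages t and t+1, with no
correspondence between individual cells across stages.  The underlying
model is a linear transition on the expression vector X,

    X_{t+1} - X_t = A X_t + eps,      eps ~ (l, D) independent of X_t,

where `A[i, j]` is the regulatory strength of gene j (regulator) on
gene i (target), `l` is a deterministic environmental drift and `D` the
noise covariance.  Because cells are never tracked through the
transition, the cross-covariance between X_t and X_{t+1} is
unobservable and least squares does not apply.  Everything identifiable
lives in the first two moments of each stage:

    mu_{t+1}    = (A + I) mu_t + l,
    Sigma_{t+1} = (A + I) Sigma_t (A + I)^T + D.

These equations are underdetermined in A (p^2 unknowns against
~p(p+3)/2 constraints), so sparsity of A is assumed and the estimate is
the minimiser of the normalised moment-matching objective

    f(A) = ||Sigma_{t+1}^ - (A+I) Sigma_t^ (A+I)^T||_F^2 / ||Sigma_{t+1}^ - Sigma_t^||_F^2
         + eta * ||mu_{t+1}^ - (A+I) mu_t^||_2^2 / ||mu_{t+1}^ - mu_t^||_2^2
         + lam * ||A||_1,

with hatted quantities the per-stage estimates.  The two ratio terms
are dimensionless, which makes `eta` and `lam` comparable across data
sets.

## Moment estimation

Per stage, the mean is the arithmetic per-gene mean and the covariance
the sample covariance with the unbiased n-1 divisor (the identity blend
below dwarfs the n vs n-1 difference; the divisor is configurable via
`ddof`).  The covariance actually used is the convex blend

    Sigma~ = (1 - alpha) Sigma^ + alpha I,   alpha = 0.01 by default,

which is positive-definite whenever the sample covariance is
positive-semidefinite; its smallest eigenvalue is at least
`alpha + (1-alpha) eigmin(Sigma^)`.  An optional natural-log `log(x+1)`
transform can be applied before estimation (base e and pseudo-count 1;
RT-PCR-style panels are usually analysed on the log scale).  Users with
few cells relative to genes can bypass `estimate_moments` entirely and
hand the solver precomputed (e.g. shrinkage) moments through
`MomentSummary`; high-dimensional covariance estimators are not
implemented here.

## Solving the objective

The objective is quartic in A and non-convex.  Two facts shape the
solver design, both established empirically on simulated ground truth
(see below):

* The planted sparse solution is a *robust attractor* of the ADMM
  iteration described next: started anywhere in a large basin around
  the truth, the iteration converges to it.
* Started at `A = 0` with the tiny l1 weights of interest
  (lam ~ 1e-6), any plain descent scheme lands on a dense feasible
  matrix far from the sparse solution and stays there: the pull toward
  the l1-minimal point scales with lam per sweep and is negligible.

`admm_fit` therefore separates globalisation from polishing.

### Continuation initialisation

The target moments are morphed from the stage-t moments to the
stage-(t+1) moments along tau in (0, 1], solving a penalised problem at
each step, warm-started from the previous one.  The covariance target
at tau is

    S(tau) = Sigma_t + tau (Sigma_{t+1} - Sigma_t) + (tau^2 - tau) A~ Sigma_t A~^T,

where `A~` is the current estimate extrapolated to full strength
(A(tau)/tau).  If the solution tracks `tau * A`, this target equals
`(I + tau A) Sigma_t (I + tau A)^T` exactly, so the path stays on a
consistent branch; the mean target is linearly interpolated (it is
exactly linear in tau).  tau follows a quadratic ladder so that early
steps sit in the small-transition regime where the l1 subproblem is
essentially a linear-design LASSO and picks the right support.  Each
step is solved by monotone FISTA with backtracking on the exact
objective; a support-masked, penalty-free refit (debiasing) follows, so
the extrapolated correction is computed from unbiased values.

The path penalty is set relative to the instance's `lam_max` (the level
at which the empty matrix is stationary).  A small fixed portfolio of
path settings — (path eta, relative penalty, number of tau steps) —
covers instances where a single setting falls off the branch:

    (5, 3e-4, 40), (1, 3e-4, 40), (5, 1e-3, 40), (5, 1e-4, 40), (1, 3e-4, 200)

Each member is given a short ADMM polish and scored by the
model-selection indices; the sparsest candidate whose error score stays
below the ceiling wins.  Two consecutive members that agree on the
clipped estimate short-circuit the remaining members (on easy instances
only two members run).  The portfolio is deterministic — this is not
random restarting; every member starts from the identity transition.

### ADMM polish

The selected initial matrix seeds a three-block ADMM on the splitting
`A + I = (B + C)/2`, `B = C` (B and C split the two sides of the
bilinear covariance term):

* A-step: entrywise soft threshold of `(B+C)/2 - I - Pi2/rho` at
  `lam/rho` — the exact prox of the l1 term.
* B- and C-steps: the augmented Lagrangian is quadratic in each block,
  so each update solves one linear matrix equation `X K = R` with K
  symmetric positive-definite (Cholesky; if K is ill-conditioned a
  relative ridge `1e-10 tr(K)/p` is added with a warning).
* Duals: standard ascent, `Pi1 += rho (B - C)`,
  `Pi2 += rho (A + I - (B+C)/2)`.
* Update order A -> B -> C -> duals, fixed for determinism.
* rho: initialised to the curvature scale of the data terms
  (`2 ||Sigma_t||_2^2 / ||dSigma||_F^2 + eta ||mu_t||^2 / (2 ||dmu||^2)`)
  and adapted by residual balancing (factor 2 up/down when the primal
  residual and the dual-change proxy differ by more than 10x), clamped
  to [1e-8, 1e8].  A fixed rho = 1 is off the curvature scale by orders
  of magnitude on realistic covariances and stalls the iteration.

Convergence is declared when both primal residual norms fall below
`tol_primal * p` (default 1e-6 p) and the relative change of A falls
below `tol_change` (default 1e-8).  Exhausting `max_iter` returns
`converged=False` with diagnostics rather than raising.  The A block is
reported (it carries exact zeros from the prox); the consensus mismatch
`||A + I - (B+C)/2||` is kept as a diagnostic.

### Refinement

Two cheap post-passes run on the winning candidate:

* *Prune-and-refit*: entries below `prune_threshold` (default 0.005)
  are zeroed and the surviving support refit without penalty; repeated
  three times.  This removes structured near-threshold residue that the
  tiny l1 weight cannot.  The whole refinement (prune-refit, row repair,
  re-polish) is iterated up to four times while it keeps strictly
  sparsifying without degrading the fit.
* *Row repair*: with all other rows fixed, each row of A faces ~p+1
  constraints in p unknowns, so its feasible roots are isolated.  The
  joint solver occasionally returns a root of larger l1 norm for one
  row (one true edge traded for several small spurious ones).  Each row
  is re-solved from the empty row along a decreasing-l1 ladder (a tiny
  LASSO per row); the candidate row is accepted only when it lowers the
  row's l1 norm without degrading the fit.

A final ADMM polish follows, and the refined result is kept only if it
is at least as sparse and no worse in score.

## Model selection

With no cell-level pairing there is nothing to cross-validate, so
selection relies on three indices of a candidate A: the relative
covariance error `e_Sigma`, the relative mean error `e_mu` (square
roots of the two objective ratios) and the nonzero fraction `s0`.  The
identity `e_Sigma^2 + eta e_mu^2 + lam ||A||_1 = f(A)` ties them to the
objective exactly.

* Hyperparameters (lam, eta) are grid-selected on the full sample: the
  sparsest fit with both error indices at or below a ceiling (default
  0.3) wins; ties prefer the larger lam.
* The clipping threshold eps zeroes entries with magnitude strictly
  below it (entries exactly at eps survive).  It is chosen on the
  full-sample fit as the sparsest clipped matrix whose normalised score
  `(e_Sigma + eta e_mu)/(1 + eta)` stays at or below a ceiling (default
  0.5); ties prefer the larger eps.  "Below a reasonable level" is not
  quantified in the literature on this estimator; both ceilings are
  explicit configuration.

Both choices happen before bootstrapping and are then held fixed.

## Bootstrapping

Cells are resampled with replacement independently at each stage
(replicate r uses seed `base_seed + r`; two independent child streams
per replicate), moments re-estimated, the solver re-run, and the
replicate estimate clipped at eps.  Clipping is applied per replicate
*before* sign counting, so the confidence of an entry — the larger of
the fractions of replicates in which it is positive or negative —
reflects detectability at the chosen threshold; a post-hoc-only
clipping mode is available behind `clip_mode="final"`.  An entry enters
the final estimator only when its confidence strictly exceeds the
threshold (which must exceed 0.5 for a majority to exist; defaults:
0.9 for simulations, 50 replicates).  Its value is the mean over the
majority-sign replicates; averaging over all replicates (including
zeros and minority signs) is available behind `mean_mode="all"` but
dilutes the estimate through sign cancellation.  Replicates whose
solver run fails are dropped with a warning; more than 20% dropped is
an error.

## The simulator

`generate_truth` draws, per seed: a support of exactly
`round(sparsity p^2)` entries (a per-entry Bernoulli mode is available)
with standard-normal weights; a stage-t mean with N(0, 100) entries; a
stage-t covariance `P Lambda P^T` with `Lambda_ii = exp(i/p)` and
`P = I + R`, R standard normal (redrawn if P is numerically singular);
noise mean 0.1 per gene and noise covariance 0.01 I.  Stage-(t+1)
moments follow by exact propagation, and `sample_cells` draws the two
stages from the corresponding multivariate normals with independent
streams — there is deliberately no cell-level linkage.  Setting both
noise parameters to zero gives the oracle regime in which the truth
reproduces the stage moments exactly.

The simulator emulates the moment structure of the linear transition
and nothing else: no dropout, no library-size variation, no counts, and
values can be negative.  Passing tests on it validates the estimator
and its optimisation, not robustness to scRNA-seq technical noise.

## What recovery means here, and known limitations

True edge weights are N(0, 1), so a fraction ~0.8% of true edges falls
below the 0.01 clipping threshold; such edges are unrecoverable by
construction (a clipped estimate cannot carry an entry smaller than
the threshold), and the attainable recall of an instance is the
fraction of resolvable edges.  Separately, at p = 50 roughly one
instance in ten admits a spurious solution whose l1 norm and objective
value tie or beat the planted truth — typically one row trading a true
edge for several small entries.  No optimiser can be expected to
prefer the truth there; the package's oracle guarantee is therefore
*near-exact* recovery (precision and recall at least 0.95 per
instance, exact at p = 10 up to resolvability), which is what the test
suite asserts.  Edges whose true magnitude sits within ~1e-3 of the
clipping threshold can fall on either side of it after estimation.

In the sample case the moment estimates carry O(1/sqrt(n)) error, which
at n = 5000 produces occasional systematic spurious edges of magnitude
0.01-0.08 with stable sign; bootstrapping cannot remove them (they stem
from the base sample, not resampling noise).  Precision at a 0.9
confidence threshold is therefore high on average but not uniformly 1
per instance.

## Problem sizes and configurations used in the tests

The acceptance-style tests run the oracle regime at p = 10 (20
instances) and p = 50 (4 instances), and the sample regime at p = 10,
5000 cells per stage, 20 bootstrap replicates, 4 instances; bootstrap
replicates use a shortened two-member continuation
(`max_iter=1500, tol_change=1e-6`), which is also the configuration the
acceptance script uses.  These sizes are the package's desk-scale
defaults; the method itself has been exercised up to p = 50 in the
suite and scales as O(p^3) per sweep independent of the number of
cells (cells enter only through the moments).

## Numerical choices

* Degenerate stages (numerically identical moments) raise
  "stages indistinguishable" rather than dividing by ~0.
* Ranking ties in `rank_edges` break by (|value| desc, regulator index,
  target index); precision is NaN (never silently 0 or 1) when nothing
  is predicted.
* The rescaled edge weight `|A[i,j]| |mu_1[j]| / |mu_1[i] - mu_2[i]|`
  zeroes rows whose mean change is below tolerance and lists them as
  undefined; it is meant for the final post-bootstrap estimator only.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / `SeedSequence.spawn`); solver runs are
  seed-free and deterministic.
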