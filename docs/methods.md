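# Methods

## The inference problem

Given expression for `n` genes at `T` equally spaced time points, every
method here scores directed candidate edges `i -> j` by how much gene
`i`'s past helps predict gene `j`'s present — Granger causality under a
vector autoregression (VAR) of order `p`:

    y_t = sum_{l=1..p} A_l y_{t-l} + e_t .

Stacking the `m = T - p` usable equations gives `Y = X B + E` with
`Y (m x n)`, `X (m x n·p)` (lag blocks ordered lag 1 first, most recent
lag leftmost in each row) and `B (n·p x n)`; `B[(l-1)n + g, h]` is the
effect of gene `g` at lag `l` on gene `h`.  Models are intercept-free;
expression is z-scored per gene (population variance) before any fit.

The regime of interest is `n >> T`: OLS needs `T >= (n+1)p` and is
unavailable, the conditional F test has negative denominator degrees of
freedom, and pairwise tests drown in indirect-edge and coincidence false
positives.  The package's core method addresses this by regularizing the
under-determined VAR *toward prior biological knowledge* rather than
toward zero.

## Two-step prior ridge (CGC-2SPR)

Prior knowledge enters as a weighted directed graph over the gene set,
mapped to an `n x n` block `W'` (continuous weights rescaled linearly so
the largest magnitude is 1; discrete evidence mapped 0/1), tiled `p`
times vertically to `W (n·p x n)` since priors carry no lag information.
The estimator solves

    min_B 1/2 ||Y - XB||_F^2 + lambda1/2 ||B - lambda2 W||_F^2

with the closed form `B^ = (X'X + lambda1 I)^{-1}(X'Y + lambda1 lambda2 W)`.

Because prior weights are magnitudes while regulation may be repressive,
`W` is first *signed*: an ordinary ridge fit at the same `lambda1` gives a
preliminary `B*`, and each `W` entry takes the sign of the corresponding
`B*` entry (entrywise over all `n·p x n` positions — `B*` has per-lag
resolution, and the entrywise rule reduces to a per-pair rule when lags
agree; exact zeros keep the positive sign).  `lambda2` defaults to the
balance rule `max|B*| / max|W|`, which makes the prior target commensurate
with the data-driven coefficient scale; "max" is read as the maximum
absolute value, since a signed maximum would be unstable for
negative-leaning `B*`.  A zero prior degrades the method to ordinary
ridge (with a warning) rather than failing.

Intuition for why this works when `lambda1` is small: on the row space of
`X` the data dominate, but on the (large) null space of an
under-determined `X` the solution is exactly `lambda2 W` — the prior
decides precisely the directions the data cannot identify.

Edge scores are the lag-aggregated coefficient magnitudes
(`max` over lags by default; `sum` and `l2` selectable).  The
autoregressive diagonal is excluded from rankings: golden standards
contain no self-loops.

## Baselines

* **PGC** — bivariate GC per ordered pair: full model (both genes' lags)
  vs reduced (target's own lags), `F = ((RSS_2 - RSS_1)/p)/(RSS_1/(m-2p))`
  which is `F(p, m-2p)` under the null; edges ranked by `-log10 p`, ties
  by larger F then lexicographic.  The sweep shares one Gram matrix so
  each pair costs a 2p x 2p solve.
* **Ridge / Lasso / Elastic net** — penalized VAR, each target its own
  regression.
  Ridge uses the closed form, computed through the dual
  `X'(XX' + lambda1 I)^{-1}` route when `m < n·p` (identical to the primal
  to 1e-8).  Lasso is solved per target by the exact LARS homotopy — with
  `m ~ 17` the path has few knots, so this is both exact and much faster
  than coordinate descent near interpolation.  Elastic net
  (`lambda1[(1-a)/2 ||B||_F^2 + a||B||_1]`, mixing `a = 0.5` by default)
  uses warm-started pathwise coordinate descent from the dead-zone
  boundary (the GLMNET strategy), with sweeps vectorized across targets;
  it is validated against scikit-learn's single-target solver.
* **ARACNE / MRNET** and their time-delayed variants — mutual-information
  networks.  The default estimator is equal-frequency binning with
  `ceil(sqrt(T))` bins and the Miller-Madow bias correction (negative
  corrected values are clamped to zero); a Gaussian closed-form estimator
  (`-ln(1-rho^2)/2`) exists for exact tests.  ARACNE removes an edge when
  a third gene makes it the weakest in a triangle by more than
  `dpi_epsilon` (default 0); MRNET forward-selects predictors per target
  by relevance minus mean redundancy until the best score is
  non-positive.  Undirected results are reported as both orientations; TD
  variants take the maximum MI over source lags `1..max_lag` (ties to the
  smallest lag) and orient each surviving pair toward the direction with
  the larger lag-maximized MI.  The TD-ARACNE here is the simplified
  variant built like TD-MRNET, not the original dynamic-programming one.

## Penalty selection

`lambda1` is chosen by cross-validation over the `m` stacked equations:
contiguous-block folds by default (respecting serial dependence; shuffled
folds behind a flag), 5 folds, held-out mean squared prediction error on
a log-spaced grid `1e-4 .. 1e2` (25 points).  Two practical details:

* for the L1 methods the fold error is averaged over a deterministic
  subsample of at most 120 targets — the mean over hundreds of
  near-exchangeable per-target error curves has the same argmin as the
  full mean, at a fraction of the cost;
* selection uses the **one-standard-error rule** (largest `lambda` whose
  mean error is within one SE of the minimum), because in the `n >> T`
  regime the error curve saturates into a numerically flat plateau near
  interpolation where a plain argmin would select the grid edge on
  noise-level differences.  Plain `min` selection is available
  (`cv_rule="min"`).

CGC-2SPR reuses the ridge-selected `lambda1` for both of its steps.

## Monte Carlo edge significance (MCSE)

For a candidate edge `i -> j` with `n >> T`, the observed statistic is the
lag-aggregated `|coefficient|` of `i -> j` from the fitted model (the
prior-guided fit by default; plain ridge selectable).  The null replaces
gene `i`'s series with a random permutation of its own time points —
destroying temporal precedence while preserving `i`'s marginal
distribution and every other gene's data as conditioning context — and
refits the reference model (ordinary ridge at the same `lambda1`, no
prior).  The add-one empirical rule `p = (1 + #{null >= obs})/(R + 1)`
(default `R = 199`) bounds p away from zero.  Per-edge replicate streams
are seeded from a hash of `(seed, source, target)`, so batch results are
independent of list order, duplicates and worker count.  Each replicate
only re-solves the `m x m` dual system for the target column, so the cost
scales with `R`, not with `n·p`.

Practical note: with `n·p` close to `m` and very small `lambda1` the
near-interpolating reference hands sizeable coefficients even to permuted
surrogates, eroding the separation between signal and null; `lambda1` of
order 1 restores it.  Calibration: under independence with white-noise
sources the permutation null is exchangeable and the p-values are uniform
(checked by KS at level 0.01).

## The simulation benchmark

The generator emulates a hierarchical regulatory program measured briefly:

* **Topology** — a 1 -> 3 -> 9 module (13 genes, 12 edges) repeated 60
  times (780 base genes), plus 700 random cross-module perturbation edges
  (uniform source; target never a master, so masters stay purely
  AR(2)-driven and the gold standard matches the dynamics).  Each
  master regulator is active with probability 5/6; a module's genes
  survive the activation filter iff its master is active (expected ~650
  survivors).  Survivors are padded with isolated periodic background
  genes to 1000 total.  Retained edges get a lag uniform on `1..3` and a
  coefficient uniform on `(-1, 1)`; a typical realization retains
  ~1050-1100 edges.
* **Dynamics** — masters and isolated genes follow the periodic AR(2)
  `x_t = sqrt(3)·d·x_{t-1} - d^2·x_{t-2} + e` with per-gene decay
  `d ~ U(0.95, 1)`: the characteristic roots are `d·exp(±i·pi/6)`, giving
  a 12-point period (roots constructed as a complex-conjugate pair with
  `a = 2·d·cos(pi/6)`, `b = -d^2`; the sign-flipped `+d^2` variant, which
  is explosive, is available behind `ar2_positive_sign` for comparison).
  Effectors are linear in their parents' lagged values with the gold
  coefficients plus noise.  The first `max_lag` points are N(0,1); noise
  is N(0, sigma^2) with sigma = 1 by default (the noise sweep uses
  sigma in {0.5, 0.707, 1, 1.414, 2}); every gene is finally z-scored.
* **Prior** — the bidirectional clique over each module's surviving
  members, weight 1: deliberately coarse group knowledge whose accuracy
  is 12/156 ~ 7.7 % per full module; cross-module edges are never
  included.

What this emulates well: the `n >> T` shape, periodic co-expression,
lagged linear regulation, group-structured priors of realistic (low)
accuracy.  What it does not: nonlinear or combinatorial regulation,
measurement dropout, unequal sampling, hidden confounders — so passing
benchmarks here show correct behavior under the model's assumptions, not
performance on arbitrary real data.

## Evaluation

Methods are compared as rank lists over the universe of all ordered
non-self pairs (sparse outputs are padded with zero-score edges in
lexicographic order).  Precision-recall curves sweep every prefix; AUPRC
uses step interpolation.  The headline score is F1 on the top-`k` prefix
with `k = |golden standard|`, where precision = recall = F1.  The
benchmark driver (`grangernet benchmark` / `run_benchmark`) regenerates
the simulation per (seed, noise level), selects penalties by CV, runs all
methods and emits one row each with the resolved `lambda`s for audit.

Benchmark problem sizes: the reference table runs the full 1000 x 20
configuration over 5 seeds; the packaged noise sweep runs a half-scale
network (30 modules, 500 genes) over 3 seeds x 3 noise levels, which
preserves the `n >> T` regime while keeping the full sweep comfortably
interactive.

## Numerical choices and degenerate inputs

* OLS refuses rank-deficient designs (Cholesky pivot ratio below 1e-7)
  and points to the regularized estimators; the `T >= (n+1)p` condition
  is the boundary.
* F statistics that come out negative through ill-conditioning are
  clamped to zero with a warning; zero full-model RSS is an error (the
  F test is undefined on noiseless fits).
* PGC p-values are floored at 1e-300 before `-log10` scoring.
* Ranking ties break by secondary statistic (F for PGC), then (source,
  target) lexicographic — rankings are bit-stable across runs.
* Constant genes: z-scoring leaves them at zero; MI rows are zeroed with
  a warning; the Gaussian MI estimator treats their correlation as zero.
* All generator randomness flows from one seed through three independent
  substreams (network / expression / prior), so a config is reproducible
  bit for bit.

## Known limitations

* The activation filter is whole-module (a module lives or dies with its
  master), which makes the clique-prior accuracy exactly 12/156 per
  surviving module; partial-module filtering would shift it slightly.
* Elastic-net fits are iterative with a fixed sweep budget; at penalties
  deep inside the interpolation regime the reported coefficients are
  approximate (the fit warns), though rankings are stable in practice.
* MCSE refits one edge at a time; batching shares no work across edges
  beyond the observed-statistic fit.
* The MI estimators are not numerically identical to the minet R package;
  only the algorithmic behavior (DPI pruning, MRMR selection) is matched.
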