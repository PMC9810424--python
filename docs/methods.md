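# Methods

## Model

A population of `N` workers (default 100) is partitioned each step into
`K = N/n` disjoint games of `n = 5` players.  Worker `i`'s strategy is a
point `(x_i, y_i, z_i)` on the 2-simplex — the fractions of time spent on
a homeostatic task X, a thresholding task Y, and in inactivity; `z` is
stored implicitly as `1 − x − y`, so the simplex constraint is exact at
all times.

Group benefit couples the tasks multiplicatively and is shared equally:

    B(S_X, S_Y) = (1/n) · B_X(S_X) · B_Y(S_Y),

with `S_X, S_Y` the group's collective efforts.  Costs are borne
individually and add across tasks.  Worker `j`'s payoff is
`B − C_X(x_j) − C_Y(y_j)`.

The learning step is synchronous: (1) random uniform partition into
games; (2) payoffs; (3) Wright–Fisher resampling of the whole population
with softmax weights `exp(αΠ_l)/Σ_m exp(αΠ_m)` (max-shifted for overflow
safety) — the standard finite-population realisation of replicator-style
recruitment; a per-game or pairwise reading of the recruitment rule would
change the drift structure but not the deterministic limit; (4) with
probability μ per worker, Gaussian exploration of size σ on the free
traits, followed by exact Euclidean projection onto the feasible triangle
(the projection is onto the nearest of the three boundary segments, so it
is continuous and unbiased in the interior).

All randomness flows from a single seed through named substreams
(`partition`, `recruitment`, `mutation`, `optimizer`, `init`), so a
(seed, config) pair reproduces a run bit for bit and each substream can
be replayed in isolation.

## Functional forms

The environment enters only through the shapes of `B_X`, `B_Y`, `C_X`,
`C_Y`; all four are pluggable by name through the config and the
`register_*` hooks.  Defaults:

* **B_X (quadratic, clamped):** `max(0, b1·S + b2·S²)` on `S ∈ [0, n]`.
  `b2 < 0` makes the task homeostatic (unimodal benefit, over-investment
  hurts); `b2 ≥ 0` makes it maximizing.  Non-negativity is enforced by the
  clamp rather than a parameter restriction.
* **B_Y (normalized tanh):**
  `[tanh(γ(S/n − w)) + tanh(γw)] / [tanh(γ(1−w)) + tanh(γw)]` with
  steepness `γ = β²`.  Anchored exactly at `B_Y(0) = 0`, `B_Y(n) = 1`,
  inflection at per-capita effort `w`.  The quadratic steepness scale is a
  deliberate choice: at `β = 1` the ramp is essentially linear, while at
  `β ≥ 3` it is a near-hard threshold — the regime in which the
  thresholding task creates a genuine social dilemma.  A variant with
  steepness linear in β is registered as `tanh_soft`; with it the
  threshold at operating β is so shallow that no stable active/inactive
  dimorphism exists anywhere in the benchmark parameter ranges.
* **Costs (shifted power):** `C_T(e) = c_T·[(e + e0)^q − e0^q]` with
  `c_x = c_y = 1.5`, `q = 0.5`, `e0 = 0.2`.  Concave increasing
  ("marginally decreasing" — practice makes work cheaper at the margin)
  with `C(0) = 0` and a finite marginal cost at zero effort.  The offset
  matters: a plain power law (`e0 = 0`, registered as `power`) has an
  infinite marginal cost at zero, which makes the task edges `x = 0` and
  `y = 0` absorbing for the trait dynamics and drives the population into
  task-specialist pairs instead of mixed-task strategies.

### Calibration of the free cost parameters

The benefit coefficients `(b1, b2, w, β)` are swept experiment inputs;
the cost scale, exponent and offset have no printed values and were
calibrated once, before any acceptance quantity was computed, against the
qualitative region layout of the benchmark environment points
(`β = 3`, `b2 ∈ {−6, −4}`, `b1` from 14 to 30): poor environments must be
fully inactive from every initial condition, mid-range environments must
branch into coexisting activity levels, rich environments must stay
uniformly active.  The scan covered `c ∈ [0.4, 2.1]`, `q ∈ [0.3, 1.0]`,
`e0 ∈ {0, 0.1, 0.2, 0.3}` using the analytic region classifier, a
mean-field dimorphism analysis and simulation replicates.  The frozen
defaults reproduce the fully-inactive points in every probed seed and
give persistent z-bimodality at the branching points in a majority of
seeds.  The *compositions* of the branches (which task mix each branch
adopts) remain sensitive to the exact functional forms and to the seed;
with unknown true forms this residual is expected and is reported, not
hidden.

## Steady-state analysis

* **Window:** the final 10% of the run.  A trend guard (total drift of
  mean z across the window above 0.1) returns "unresolved" rather than a
  forced label.
* **Branch detection:** 1-D k-means on z for k ∈ {1, 2, 3}; k is accepted
  only if every cluster holds ≥ 10% of the population and adjacent
  z-means differ by > 0.2 — two orders of magnitude above the σ = 0.005
  mutation noise floor, so monomorphic populations never read as
  branched.  Branching requires k ≥ 2 in at least half of the window's
  snapshots (persistence).
* **Region labels:** mean z < 0.05 counts as fully active, > 0.95 as
  fully inactive (the 0.05 tolerances absorb mutation pressure away from
  the simplex vertices); single-run full activity is reported as the
  bistable region's active face.  Environment-level classification runs
  three canonical initial conditions — near-fully-active, near-fully-
  inactive, uniform — with replicates.  The biased inits are Dirichlet
  distributions concentrated near a simplex face (e.g. `Dir(1, 1, 0.05)`)
  rather than monomorphic points: at μ = 0.01, σ = 0.005 a monomorphic
  population moves at a mutation-limited crawl (~10⁻⁵ trait units per
  step), so a biased-but-variable population is the meaningful probe of
  basin membership on the 30 000-step horizon.
* **Activity ratio:** a worker counts as active when `z < 0.5` (used for
  the culling experiment's time series).

## Adaptive dynamics

Invasion fitness of mutant `m` against resident `r` is the payoff of a
single mutant in a group of `n − 1` residents minus the resident's payoff
in an all-resident group; it is exactly zero at `m = r`.  Selection
gradients are central finite differences (step 1e-5, one-sided on the
boundary); singular strategies are found by multi-start root finding
(tolerance 1e-8, dedup radius 1e-4) and classified by the standard
multivariate second-order conditions: mutant-Hessian definiteness for
local (un)invadability, eigenvalues of the Jacobian of the gradient map
for convergence stability; convergence-stable and invadable = branching
point.  Symbolic derivatives of the default forms (sympy) serve as an
independent oracle for the finite-difference gradients in the tests.

`predicted_region` integrates the monomorphic flow (projected gradient
ascent that can slide along the simplex boundary) from canonical starts
and classifies the attractors reached.  Known limitation: with
multiplicative benefits that vanish at zero effort, the inactive vertex
is *always* locally attracting in the mean-field flow, while finite
populations cross its shallow basin by drift; conversely, near the
Y-threshold, group-composition noise systematically favours inactivity
relative to the mean field.  Agreement between the analytic and
simulation classifiers is therefore structural, not exact — across the
random environment samples we measured, agreement ranged from roughly 60%
to just under 80%, with disagreements concentrated on basin-boundary and
threshold-straddling cases.

## Efficiency

The social optimum maximizes the group-mean payoff over the joint
2n-dimensional allocation by differential evolution (best/1/bin, F = 0.5,
CR = 0.7, popsize 15, tol 1e-8, 5 restarts by default), with the best
symmetric allocation solved separately for comparison.  The asymmetric
optimum is the denominator of the efficiency ratio, since branching
steady states are themselves asymmetric; with concave costs the
asymmetric optimum genuinely exceeds the symmetric one.  Relative colony
efficiency = time-averaged steady-state mean payoff over the optimum,
clamped to [0, 1] for reporting (negative achieved payoffs report 0);
SED = optimum − achieved is kept unclamped, and the identity
`sed = optimal − achieved` holds exactly by construction.  Cells whose
optimum is not positive are flagged undefined, never dropped.

## Problem sizes

Benchmark runs use N = 100, T = 30 000 (a few seconds each).  The test
suite scales sweeps down — T = 10 000 for the cross-layer concordance
sample and the efficiency grid — which leaves the qualitative structure
intact; slow transients that need more than the horizon (e.g. decay of a
near-active colony under pure cost) are exercised from the initial
conditions where they resolve, and noted where they do not.

## What the synthetic populations do and do not show

All inputs are generated: Dirichlet populations, constructed bimodal
fixtures and noisy blobs emulate the states the dynamics themselves
produce (uniform starts, branched colonies, mutation clouds).  They do
not emulate real colonies — no demography, no spatial structure, no
task switching costs, no individual heterogeneity beyond the traits —
so passing tests validate the model's internal consistency and its
game-theoretic predictions, not any empirical claim about a particular
species.
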