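# Methods

## Model

A hierarchy over J manifest variables is a partition into Q non-empty groups
(nodes 1..Q) plus Q−1 ordered binary merges (merge *i* creates node Q+*i*;
node 2Q−1 is the root). Each node *m* carries a non-negative variance
increment b²ₘ; the *level* of a node is the sum of increments from the node
to the root. The implied correlation between variables *j* and *l* is the
level of the lowest node containing both; the diagonal is closed by
uniquenesses ψⱼ = 1 − (path sum of increments above *j*), giving
Σ = ΛΛ′ + Ψ with Λ = Ṽ diag(b). Because increments are non-negative, levels
are non-increasing up every root path, which is exactly the condition for Σ
to be an ultrametric correlation matrix (every triplet's minimum attained at
least twice). Within this *cumulative* parameterization the within level of
a group always dominates the between levels *on its own root path*; it need
not dominate between levels on other branches. A strict global ordering
variant is available behind a flag in the level validator.

Assumptions: correlations are non-negative (enforced at fit time; an
`allow_negative` override exists, in which case negative block means are
clipped at zero), the input is positive definite (a diagonal-shift repair
with rescaling is applied otherwise, or an error under `strict`), and the
hierarchy is a full binary merge tree — non-binary aggregations are out of
scope.

## Estimation

The ML discrepancy F = log|Σ| + tr(Σ⁻¹R) − log|R| − J is minimized by
cycling block coordinate descent:

1.1 *Assignment sweep.* Variables are visited in order; each is moved to the
    group (labels 1..Q) minimizing F with the remaining blocks fully
    re-estimated per candidate. Moves that would empty a group are skipped;
    ties break to the lowest group label. A cheap approximate mode
    (levels held fixed during the sweep) is available via
    `FitConfig.exact_assignment=False`.
1.2 *Tree rebuild.* The merge sequence is rebuilt greedily: repeatedly merge
    the two active clusters with the largest average-linkage between
    correlation (mean of sample correlations over cross-cluster variable
    pairs); ties break to the smallest pair of node ids.
2.  *Levels.* Node levels are re-estimated as mean within-block and
    cross-block sample correlations and projected onto the ultrametric cone
    by upward clipping: a merge level is capped at the minimum of its
    children's levels, all levels are clipped to [0, 1 − 10⁻⁴]. Increments
    are level differences, hence non-negative.
3.  *Uniquenesses.* ψⱼ = 1 − communality, floored at 10⁻⁴ with a Heywood
    warning when flooring occurs.

Each block update is accepted only if it does not increase F, so the
iteration trace is non-increasing by construction — the mean-based level
updates are good heuristics rather than exact conditional minimizers, and
the guard turns monotone convergence into an enforced contract. Iteration
stops when the decrease falls below `tol` (default 10⁻⁶ absolute, typically
within a handful of iterations) or after `max_iter` (default 100).

**Multistart and split–merge refinement.** Starts are random
equal-probability multinomial partitions conditioned on no empty group
(default 50 starts; start *s* of seed *σ* uses the generator seeded with
(σ, s), so any start is re-runnable in isolation). The row-by-row sweep can
never empty a group, which makes solutions requiring a group to dissolve —
e.g. a true singleton group absorbed elsewhere — unreachable local minima
from almost all starts. The best-of-starts solution is therefore refined by
deterministic split–merge proposals: merge two groups, refill the freed
label with one half of a bisected group (split at the least-correlated pair
of members), re-descend, and accept only improvements. On a planted J=24,
Q=5 problem with a singleton group this raised the fraction of runs reaching
the global objective minimum from ~1% to 100% at negligible cost; it can be
disabled with `FitConfig.refine=False`.

**Singleton groups** have no within pairs; their level is pinned to the
parent merge level (zero increment) and flagged in the diagnostics. This
avoids spurious Heywood solutions and keeps the level ordering intact.

**An exact-ML polish of the levels was deliberately not adopted.**
Optimizing the increments by constrained ML with the structure fixed lowers
F slightly but fits sampling noise and worsens loading recovery on planted
benchmarks, so the mean-based updates are retained.

**PDFA.** The parsimonious disjoint model pins every merge increment at
zero (block-diagonal Σ, 2Q parameters). It is strictly nested in the
hierarchical model, whose parameter count is 3Q − 1 (one loading per group,
one per merge, one uniqueness level per group — independent of J). The
constrained variant freezes the converged PDFA partition and within levels
and estimates only the hierarchy above them.

## Model selection

Degrees of freedom use the standard ML factor-analysis count
df = J(J+1)/2 − npar by default; the off-diagonal-only convention
J(J−1)/2 − npar is available via `df_convention="offdiag"` and recorded in
output metadata. AIC = n·F + 2·npar and BIC = n·F + npar·log n on the
discrepancy scale — additive constants cancel when comparing values of Q, so
only differences are meaningful. GFI = 1 − tr[(Σ⁻¹R − I)²]/tr[(Σ⁻¹R)²] and
AGFI = 1 − [J(J+1)/(2 df)](1 − GFI). `select_q` reports the full table and
the optima of all three criteria, choosing by BIC unless configured
otherwise.

## Synthetic data

The generator emulates correlation matrices with planted hierarchical
structure: a random equal-probability partition (non-empty groups; a warning
is emitted when J < 2Q since singletons then become likely), a uniformly
random binary agglomeration tree, and top-down levels — root level uniform
on [0.10, 0.30], one uniform [0.05, 0.20] increment per non-root node. When
the largest communality exceeds 0.9 all levels are rescaled proportionally
(clipping would create level ties, i.e. zero increments, leaving the planted
tree unidentifiable). Planted merges are emitted in descending-level order,
the canonical order any agglomerative estimate produces, because the
tree-recovery score pairs merge levels by index. Noise is an elementwise
uniform perturbation on [−ε, ε] (one-sided [0, ε] behind a flag),
symmetrized, zero on the diagonal, clipped to [0, 1]; if the result is
indefinite, |λ_min| is added to the diagonal and the matrix rescaled back to
unit diagonal. Error-level presets are low = 0.05, medium = 0.15,
high = 0.30; the default scenario grid is J ∈ {12, 24} × Q ∈ {3, 5}.

What the generator does **not** emulate: finite-sample correlation noise
(available separately via multivariate-normal sampling), non-Gaussian
observations, missing data, negative correlations, and non-hierarchical
residual structure. Passing recovery tests therefore demonstrates that the
estimator inverts its own generative model under entrywise noise — not that
real batteries satisfy ultrametricity.

## Recovery metrics

Partition recovery uses the Hubert–Arabie adjusted Rand index. The tree
score is (ARI of the Q-group partitions + one ARI per merge level,
comparing the two-block splits induced by the *i*-th merges of the two
trees) / Q, clamped at 0; each merge-level ARI is computed over the
variables covered by both merges (fewer than two shared variables scores 0;
an alternative treating uncovered variables as a third block over all J is
available by flag). Loading error is the RMSE over all J×(2Q−1) entries
(structural zeros included) after optimal column matching — rectangular
assignment on column-wise squared differences, done separately within the Q
group columns and the Q−1 merge columns, since the loading matrix is unique
only up to relabelling.

## Numerical choices

- Level-equality and ultrametricity tolerance 10⁻⁸; the triplet check uses
  the "minimum attained at least twice" form for robustness.
- Discrepancy via Cholesky factorization; singular inputs raise with a
  condition-number message.
- Uniqueness floor 10⁻⁴ (Heywood guard); composed matrices are PSD by
  construction and verified to eigenvalue ≥ −10⁻¹⁰ in tests.
- All randomness flows through `numpy.random.Generator` seeded by explicit
  integer lists (master seed, scenario, replicate, start), so every
  replicate and every start is individually reproducible.

## Problem sizes used in the shipped studies

The test suite and the acceptance script run the recovery protocol at
J = 24, Q = 5 with 20 replicates and 50 starts (low noise), zero-noise
recovery at (12, 3) and (24, 5), and exhaustive-enumeration checks at
J ≤ 8, Q ≤ 3 — the scale at which the partition×tree space (Stirling numbers
times merge sequences) is still enumerable. These sizes exercise every code
path at desk scale; larger studies are a matter of the scenario grid.

## Known limitations

- The assignment sweep plus greedy tree rebuild is a heuristic search; the
  split–merge refinement removes the dominant failure mode but global
  optimality is only certified on enumerable problems.
- Mean-based level estimation is not exact conditional ML; F at convergence
  is a guaranteed-monotone approximation of the ML optimum.
- Merge-level pairing by index makes the tree score sensitive to merge order
  when level values nearly tie.
- No standard errors or tests on loadings; no factor-score estimation.
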