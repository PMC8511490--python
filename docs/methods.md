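# Methods

## Model

A subject is a pair (X, G): X is K×N (K time points, N regions; columns are
regional BOLD-like series), G is N×N symmetric nonnegative (fiber counts,
zero diagonal). The unified network W solves

    min_{W,U}  ‖X̃ − X̃W‖_F² + α‖W‖_* + β·tr(W L Wᵀ) + γ‖U‖_F²
               s.t.  X̃ = UX,  L = D − G,

with U an M×K projection (space alignment) and D the degree matrix of G.
The assumptions are: (i) each region's signal is reproducible from a few
other regions' signals, globally captured by the nuclear norm as a convex
rank surrogate; (ii) regions joined by many fibers have similar outgoing
weight profiles — tr(W L Wᵀ) equals ½·Σ_ij G_ij‖w_i − w_j‖² for columns w_i
of W (the conventional factor of two is absorbed into β); (iii) a learned
linear alignment of the temporal features can expose the dependence
structure better than the raw space.

Columns of X are z-scored before solving (zero mean, unit variance per
region), so the fit term and the Pearson baseline live on comparable
scales. This is switchable (`standardize=False`).

## ADMM

With auxiliaries P = W and Q = W, the augmented Lagrangian is minimized
block-wise in the fixed order W, P, Q, U, X̃, then multipliers. Writing
K = X̃ᵀX̃ and I for identities of matching size:

* W ← (K + Kᵀ + 2μI)⁻¹(K + Kᵀ + μ(P + Q) + Y1 + Y2)
* P ← SVT(W − Y1/μ, α/μ) — singular-value soft-thresholding, the proximal
  operator of the nuclear norm
* Q ← (μW − Y2)(β(L + Lᵀ) + μI)⁻¹
* U ← (μX̃Xᵀ + Y3Xᵀ)(2γI + μXXᵀ)⁻¹
* X̃ ← (μUX − Y3)(2(I − W)(I − W)ᵀ + μI)⁻¹
* Y1 += μ(P − W); Y2 += μ(Q − W); Y3 += μ(X̃ − UX); μ ← min(ρμ, μ_max)

Each update is the exact minimizer of its subproblem; the test suite checks
all five against generic numerical minimizers on random instances (≤1e-6).
Initialization is deterministic: W = P = Q = 0, U the first-M-rows selector,
X̃ = UX, zero multipliers. Convergence is declared when all of
‖P − W‖∞, ‖Q − W‖∞, ‖X̃ − UX‖∞ fall below ε. Defaults follow the printed
algorithm: μ0 = 0.1, ρ = 1.01, ε = 1e-7, μ_max = 1e7 (the cap must exceed
μ0 for the schedule to be meaningful), max_iter = 2000 with a `converged`
flag rather than an error on exhaustion. The diagonal of W is not
constrained during solving; thresholding and feature extraction zero it.

### Degeneracy of the joint objective, and the operating point

The joint objective has only the trivial KKT point when γ > 0: stationarity
in U and X̃ forces U(γI + X(I − W)(I − W)ᵀXᵀ) = 0, hence U = 0, X̃ = 0, and
then W = 0. Whether the ADMM iterates reach an informative network before
drifting to that point is governed by the initial penalty relative to the
data Gram. With column-standardized data the aligned Gram diagonal is ≈ M
(or K without reduction); if μ0 is far below that scale, the X̃ update
multiplies the data by μ/(2 + μ) ≈ 0 in the very first iterations, the
solver effectively never sees the data, and the returned W is numerically
zero. With μ0 of the order of the Gram diagonal or above, the constraint
X̃ = UX stays anchored, the γ-driven drift of U is frozen out by the growing
penalty, and the solver converges (residuals < 1e-7) to a structured W long
before any collapse.

Practical rule used throughout the examples and tests: **μ0 ≈ 2K for
standardized data** (2M when aligning to M < K dimensions). At N=90, K=240
this converges in ≈ 500–570 iterations and recovers planted edges with
AUROC ≈ 0.96–0.98; μ0 = 0.1 on the same input converges (to the trivial
point) in ≈ 760 iterations with AUROC ≈ 0.55. The package keeps the printed
μ0 = 0.1 as the `HyperParams` default for fidelity to the published
schedule, and documents the scale rule here; the ablation `align=False`
(U pinned to the identity, X̃ = X) has no degeneracy at all and is the
most robust configuration for pure edge recovery.

## Thresholding and node importance

The solver's W is neither symmetric nor sign-constrained, so edge strength
is max(|W|, |Wᵀ|) and the thresholded graph is undirected. The threshold r
may be applied to raw strengths (default, r ∈ [0, 1]) or — as the pipeline
does — relative to the largest off-diagonal strength (`relative=True`),
which makes the sparsity controlled by r independent of the overall scale
of W (the scale varies with α, β and the data; raw thresholds in the
0.1–0.8 range assume correlation-scaled networks).

Simplified PageRank is the fixed point of s = T·s with T_vu = 1/deg(u) for
each link u→v (column-stochastic on linked nodes). Two conventions make the
iteration well-posed on arbitrary graphs, neither changing the fixed point:

* dangling nodes: their score mass is redistributed uniformly each step,
  so Σs = 1 always holds (asserted every iteration);
* the lazy half-step s ← (s + Ts)/2 is used instead of s ← Ts; it has the
  same fixed points but also converges on periodic (e.g. bipartite) graphs,
  where the plain power iteration oscillates forever. On a connected
  undirected graph the fixed point is degree/Σdegree.

Convergence: fixed-point residual ‖Ts − s‖₁ < 1e-10, max 10 000 iterations,
error on failure. No damping factor (exposed nowhere; the simplified variant
is the method). Comparator scores (local clustering coefficient, degree,
closeness, radiality) use standard definitions via networkx; disconnected
graphs are scored per connected component with unreachable pairs excluded,
isolated nodes score 0; radiality of u is the mean of
(component diameter + 1 − d(u, v)) over reachable peers v.

## Kernels and evaluation

Per subject, modality 1 is the strict upper triangle (row-major) of the
symmetrized (W + Wᵀ)/2 with zeroed diagonal (length N(N−1)/2); modality 2
is the node-score vector (length N). Kernels are linear after per-feature
z-scoring fit on training subjects only; test rows reuse training
statistics. The mixed kernel is c₁K⁽¹⁾ + c₂K⁽²⁾ with c ≥ 0, Σc = 1; c₁ runs
on a 0.1-step grid (11 candidates) crossed with SVM costs
{0.01, 0.1, 1, 10, 100}, selected by 3-fold stratified CV nested inside
each outer training fold; ties break toward larger connectivity weight,
then smaller cost. The outer protocol is stratified 5-fold CV repeated 5
times with per-repeat seeds; the reported statistic is the mean accuracy
over all 25 folds. Held-out subjects never enter standardization, weight
selection, or training — the nested reading is the minimal leak-free one.

## Synthetic data

The generator emulates exactly what the downstream stages consume, not the
physics that produces it. Per class: regions are partitioned into
communities; each community's signals are a random factor model
X0[:, b] = F_b A_b (factors i.i.d. standard normal, factor dimension
allotted from the `rank` parameter in proportion to community size). The
planted matrix W_true is obtained per column by constrained least squares
(express each region's loading through the other loadings of its community
with weights summing to one, minimum-norm), which simultaneously gives a
zero diagonal, unit column sums, community-confined support, and the exact
identity X0 = X0·W_true. Subjects get a ±10% multiplicative jitter of
W_true plus i.i.d. Gaussian noise (default sd 0.1; series signal sd ≈ 2);
fiber counts are Poisson with mean `fiber_scale` (default 50) on
within-community pairs and mean 1 elsewhere, symmetrized by averaging and
rounding. Everything is reproducible from integer seeds.

Not emulated: hemodynamics, autocorrelated noise, scanner artifacts,
tractography biases, negative or long-range correlations, inter-subject
registration error. Passing tests therefore show that the estimator
recovers the dependence structure it assumes when that structure is
present — not that real epilepsy cohorts are classifiable at these rates.
Cohort tests use noise sd 0.3 so that within-class subjects are similar but
not near-duplicates; near-duplicate cohorts make label-permutation nulls
dip systematically below chance (the classifier anti-learns the cluster
structure), which is an artifact of unrealistically clean data.

## Problem sizes and numerics

The test suite runs the solver at N=90/K=240 (full scale, for the
convergence bound and edge recovery) and at N=12–20 for cohort-level
checks (20 subjects, 25 CV folds), keeping the default run in minutes on
one CPU. Oracle comparisons use N=6, M=4, K=10 instances. The nuclear-prox
oracle avoids singular-value shrinkage entirely by minimizing over a
factorization (‖P‖_* = min_{P=AB} (‖A‖² + ‖B‖²)/2) with L-BFGS and random
restarts. Matrix equations are solved with dense `numpy.linalg.solve`
(all systems are regularized by μI or 2μI and cannot be singular for
μ > 0); right-inverses exploit symmetry of the bracketed matrices.

## Known limitations

* The published objective is degenerate as stated (see above); the package
  documents an operating regime rather than modifying the model (e.g. an
  orthonormality constraint on U would remove the degeneracy but would be a
  different method).
* With the printed schedule (μ0 = 0.1, ρ = 1.01) the residual tolerance
  1e-7 is reached only after ≈ 760 iterations at full scale; the objective
  value plateaus much earlier (≈ 400).
* Classification supports binary labels via the one-vs-one SVM default;
  the protocol reports accuracy only.
* No weighted PageRank; no centralities beyond the four comparators.
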