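# Methods

## Scope and model

`rankprune` implements a two-stage pipeline for class-labelled tabular
data: a wrapper feature selector (rank-based relevance scoring followed by
SVM recursive feature elimination under a joint objective) and a
composite-kernel hinge classifier trained by consensus ADMM over simulated
compute partitions. Distribution is simulated in-process: the contract is
only that each node update reads the consensus vector and its own data
partition and writes back its coefficient vector; no network transport is
implemented or emulated.

## Relevance scoring

For feature *i*, the variance contribution V_i is the population
(divide-by-N) variance; the same convention is used by the z-score scaler
and the high-dimensional variance filter so a single variance definition
runs through the package. The rank metric ranks each feature's values
1..N (ties averaged) and measures the class-size-weighted squared
deviation of within-class mean ranks from the overall mean rank. With no
ties this equals H·(N+1)/12 for the Kruskal–Wallis H statistic — the test
suite verifies both the identity and the induced feature ordering against
`scipy.stats.kruskal`, tie-aware because two features can realize exactly
the same rank-class pattern.

V and R live on incomparable scales, so both are min–max rescaled to
[0, 1] across features before the weighted combination S = α·V̂ + β·R̂
(defaults α = β = 0.5; the literal unnormalized sum is available via a
flag). A consequence worth knowing: after z-score preprocessing every
variance is 1, V̂ collapses to zero, and the ranking is carried entirely
by the rank metric — the variance term matters for min–max or unscaled
pipelines and for the high-dimensional variance filter.

## Recursive elimination and the joint objective

Each iteration fits a linear soft-margin SVM (hinge loss, parameter C,
libsvm backend) on the retained columns and removes the γ features with
the smallest |w_i| — the standard SVM-RFE criterion; a per-feature weight
must distinguish features, so the primal component magnitude is the only
workable reading of an importance weight derived from w. Ties are broken
by lower relevance S, then lower column index, making the elimination
path fully deterministic. Multiclass data is handled one-vs-rest with
per-feature maxima over the binary problems.

Defaults: γ = max(1, ⌊0.1·M⌋), T_min = max(2, ⌈0.05·M⌉), t_max = 50,
C = 1 — all config-overridable. The loop halts when the next removal
would drop below T_min or at t_max.

Every visited subset is scored by L = λ₁·relevance + λ₂·accuracy +
λ₃·efficiency. In the default normalized form the three terms are the
mean S over retained features, a stratified 3-fold cross-validated linear
SVM accuracy (fixed seed; resubstitution accuracy would degenerate the
objective), and 1 − T/T_total. The literal form uses the sum of S, the
accuracy, and 1/T, with the retained-feature count standing in for
evaluation time so that L is reproducible across machines; wall-clock
timing lives only in the instrumentation utilities. The returned subset
is the first L-maximizing iteration's.

## Composite kernel and its normalization

Base kernels: linear x'x, polynomial (x'x + c₀)^d, and Gaussian/RBF
exp(−‖x−x′‖²/2σ²) (one implementation for both names); the default trio
is linear, cubic polynomial (c₀ = 1), and RBF at the median pairwise
distance. The composite K = Σ β_m k_m with β_m ≥ 0, Σβ_m = 1 is PSD by
construction (property-tested over random data and simplex draws).

At training time each base kernel is trace-normalized: scaled so the mean
self-similarity of the landmark set is 1. Without this, a cubic
polynomial kernel can sit four orders of magnitude above the RBF, one
kernel silently dominates the composite regardless of β, and the node
subproblems become numerically intractable (duality gaps refuse to close
in float64). The scales are stored in the model and applied identically
at prediction. `base_kernel`/`composite_kernel_matrix` keep the literal
unnormalized definitions.

Kernel weights are re-estimated once per outer iteration by centered
kernel alignment between each base Gram matrix and the label target yy′
on a subsample of at most 500 points, negatives clipped, renormalized to
the simplex (uniform fallback when all alignments vanish). No update rule
is canonical here; alignment was chosen because it is scale-invariant,
cheap, and label-aware, and it is deliberately isolated behind one
function so it can be replaced. Alignment depends only on the data, so β
settles after the first update.

## Consensus training

The decision function is expressed on a shared landmark basis (default
min(100, N) uniformly subsampled training points, seeded): every node's
coefficient vector has length L+1 (bias last), which is what makes the
averaging step well defined for unequal partitions. The node objective is
½‖a‖² (bias excluded) + C Σ hinge over the node's samples + ρ‖c − a‖²
with proximal center c = z − u, where u is the node's scaled dual
variable; z is updated by averaging a_j + u_j and the duals by
u_j ← u_j + a_j − z. The scaled duals are what give the scheme an exact
consensus fixed point — plain proximal averaging without them leaves a
residual of order ‖z‖/(1+2ρ) between z and each a_j, which would defeat
any consensus tolerance. With P = 1 the sweep reduces to the proximal-
point iteration and converges to the exact centralized minimizer; the
test suite checks a relative objective gap ≤ 1e−3 against an independent
direct solve (the centralized problem is precisely a linear SVM over the
empirical kernel map, so libsvm serves as the oracle).

Each node carries the full ridge ½‖a_j‖², so the aggregate regularization
grows with P; observed accuracy effects on separable data are nil, and
the 1-node vs 4-node accuracy gap is property-tested at ≤ 0.05.

The node subproblem is solved exactly through its dual: with diagonal
Q = diag(ridge) + 2ρI, the dual is a smooth concave box-constrained QP in
the hinge multipliers λ ∈ [0, C]^n. An L-BFGS-B warm start is polished by
exact cyclic coordinate ascent, stopping on a relative duality gap below
1e−9 (the gap bounds primal suboptimality directly and is scale-free); a
gap above 1e−4 after the sweep budget raises a numeric error rather than
returning a silently bad update.

Convergence is declared only when both ‖z_{t+1} − z_t‖ < ε and the
consensus residual max_j ‖z − a_j‖ ≤ ε hold; a model that exhausts
max_iter is returned with the converged flag unset and a logged warning.
Defaults: C = 1, ρ = 1, ε = 1e−4, max_iter = 100. The dominant error mode
decays linearly at roughly 0.97 per iteration on small dense problems
(the unregularized bias direction is the slow mode), so tight tolerances
want a few hundred iterations; the test fixtures use max_iter = 800.

Fits are made invariant to input row order by internally reordering
samples to a canonical (lexicographic) order before landmark selection
and partitioning; without this, exact order invariance is impossible for
any subsampling scheme. One seed (`landmark_seed`) governs landmarks,
partitioning and the alignment subsample. Stratified partitioning deals
each class out contiguously while rotating which nodes absorb remainders,
keeping node sizes and per-node class counts within one sample of
proportional.

## Metrics

Classification metrics follow the confusion-count definitions; zero
denominators report 0 with a warning flag instead of raising, so batch
evaluation survives degenerate predictors. The feature reduction ratio is
stored as the retained fraction in [0, 1] and rendered as a percentage
only at the reporting layer, matching how per-dataset values are usually
tabulated while headlines quote percentages. The relevance score
operationalizes "weight × performance gain" as (selector score in [0,1])
× (add-one-in cross-validated accuracy delta), averaged over the
selection with fixed folds; no numeric correspondence to any externally
published relevance-score scale is claimed. Wall-clock time, speedup
(against a mandatory single-partition reference) and normalized memory
figures are instrumentation only — hardware dependent, never asserted on.

## Synthetic data

The generator is Gaussian class-conditional: informative features have
unit within-class standard deviation and a between-class mean gap equal
to `effect`, so the standardized separation is the parameter itself and
analytic expectations are available for tests (e.g. the empirical gap of
an informative feature at n = 2000 lies in [1.3, 1.7] for effect 1.5).
Noise features are class-independent N(0,1); redundant features add
N(0, noise_sd) to a parent, giving correlation 1/√(1+σ²) ≥ 0.8 for
σ ≤ 0.75 (default 0.5). The mixed archetype quantile-bins a subset of
columns into 3-level codes; the signal archetype passes features through
sin(x) + 0.3x, a bounded nonlinearity with a monotone component, so
linear methods are handicapped but not blinded; the high-dimensional
archetype requires p ≥ 5n. Labels hit the requested minority fraction
exactly up to integer rounding, and everything is bitwise-reproducible
by seed.

What the generator does **not** emulate: missing data, measurement
batch effects, heavy-tailed or discrete clinical distributions, label
noise, and feature correlation structure beyond the explicit redundant
blocks. Passing tests therefore demonstrate correctness of the algorithms
under a clean Gaussian design, not performance on any real cohort. The
fixture suite mirrors familiar public-benchmark shapes (768×8, 300×13,
195×22, 100×2000) purely as recognizable scales.

## Problem sizes

The default verification runs use 300×50 selection problems over 20
seeds, 200-sample two-blob classification fixtures, and ≤ 60-sample
random Gram matrices — sizes at which every check is exact or
well-powered while the full suite stays in the low minutes on one CPU.

## Known limitations

- The joint-objective accuracy term refits a CV'd SVM at every
  elimination step; cost grows as (M/γ)·folds SVM fits.
- The consensus scheme inherits ADMM's linear convergence; ε below 1e−5
  is slow without acceleration (over-relaxation is an obvious extension).
- Kernel-weight alignment uses a single global subsample rather than
  per-node statistics; a truly decentralized β update is future work.
- Multiclass support is one-vs-rest wrappers at both stages, not a native
  multiclass objective.
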