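# Methods

## Outcome model and covariance of cluster-period means

`swdreduce` evaluates designs for continuous outcomes analysed with a
linear mixed model under repeated cross-sectional sampling: outcome
Y\_kji = μ + β\_j + X\_kj θ + (cluster terms) + ε\_kji for participant i in
cluster k at period j, with β₁ = 0 for identifiability and iid individual
error ε ~ N(0, σ²ε). The cluster terms are either a shared random
intercept α\_k ~ N(0, τ²) (exchangeable structure) or a vector of
cluster-period effects γ\_k ~ N\_T(0, τ²R) with corr(γ\_kj, γ\_ks) =
r^|j−s| (discrete-time decay) or a flat r (block-exchangeable). The
exchangeable model is the r = 1 special case of the other two, and all
three share every downstream code path.

The analysis operates on cluster-period means, whose within-cluster
covariance is V = (σ²ε/m) I + τ²R. The identity shift bounds V's
eigenvalues below by σ²ε/m, so V is always positive definite and Cholesky
factorisations cannot fail for valid parameters.

**Standardisation.** Absolute variance components never enter any reported
quantity; only ρ = τ²/(τ²+σ²ε) and r do. The package fixes
τ² + σ²ε = 1, hence τ² = ρ, σ²ε = 1 − ρ, which puts the effect size θ on
the total-SD scale. All powers and precision losses are invariant to this
choice; it only fixes the meaning of "standardised effect size".

## Design variance, estimability and numerics

For an incomplete design, cluster k contributes its observed periods
through the selection matrix Z_k, covariance V_k = Z_k V Z_k' and
treatment vector X_k. The GLS variance is

    var(θ̂) = { Σ X_k'V_k⁻¹X_k − c'B⁻¹c }⁻¹,  c = Σ Z_k'V_k⁻¹X_k,
    B = Σ Z_k'V_k⁻¹Z_k,

restricted to periods observed in at least one cluster (a period nobody
measures has no period effect to estimate). On complete designs this
reduces to the familiar closed form with B = K V⁻¹; the test suite checks
agreement to 1e-10 relative and, for the exchangeable structure, agreement
with the independent scalar closed form for complete stepped wedges.

Estimability is a *value*, not an exception, because the removal algorithm
probes many non-estimable candidates. Three guards classify a design as
non-estimable:

1. a cheap necessary condition — some period must contain both an observed
   control and an observed intervention cell — short-circuits before any
   linear algebra;
2. the period-effect information matrix B is declared singular when its
   smallest eigenvalue falls below 1e-12 of its largest;
3. the bracketed scalar must exceed 1e-9 of its leading term Σ X'V⁻¹X (in
   every case examined the scalar of a truly non-estimable design is
   exactly 0.0 in floating point, so the threshold has wide margin).

All solves are Cholesky-based; no explicit inverse of V is formed for the
quadratic forms. The per-cluster precision blocks accumulated into B
require V_k⁻¹ itself and are obtained by solving against the identity
through the same factorisation.

A consequence worth noting: the smallest stepped wedge, T = 2, is *never*
estimable under this model — its two cell means cannot separate μ, β₂ and
θ — so the removal algorithm raises a configuration error there. The
smallest reducible design is T = 3.

## Information content and the removal algorithm

The information content of a centrosymmetric pair is the variance ratio
IC\_D(A) = var\_{D[A]}(θ̂)/var\_D(θ̂), computed by direct re-evaluation of
the incomplete-design variance on each candidate reduced design. A
rank-update shortcut exists (the precision of a reduced design is the
precision of its parent plus a constant) but is deliberately not used: at
T ≤ ~30 the direct route costs milliseconds per iteration and eliminates a
whole class of incremental-update bugs. The additivity property is instead
exercised as a consistency check in the tests (precision never increases
under removal), and each greedy choice is verified in the suite against a
brute-force recomputation through an independently assembled full
fixed-effects information matrix.

The algorithm removes the pair with the lowest finite IC at each
iteration. ICs within relative 1e-9 are treated as tied — the exchangeable
structure produces exact mathematical ties that differ only in the last
floating-point bits — and ties break toward the pair whose
lexicographically smaller member has the smallest (cluster, period) index,
cluster-major. "Smallest cluster and period index" admits a period-major
reading too; cluster-major was adopted and is consistent with every
reproduced result. Termination is reached when every remaining pair has
infinite IC, which subsumes the necessary condition above. For the 4×5
exchangeable example the first pair removed is {(1,4),(4,2)} — the unique
strict minimum, a cell distant from cluster 1's switch — and the path ends
at a 4-cell minimally viable design after 8 removals.

Because removal only ever deletes centrosymmetric pairs, every design on
the path keeps a centrosymmetric observation mask and skew-symmetric
treatment labels; both invariants are asserted after every removal, along
with monotone non-decreasing variance.

## Checkpoint sweep

The default sweep crosses T ∈ {5, 10}, m ∈ {10, 100}, ρ ∈ {0.01, 0.05,
0.15} and r ∈ {1, 0.95, 0.8} (36 configurations) and reads precision loss
off each removal path at 20%, 50% and 80% of cells removed. Cells leave in
pairs, so a checkpoint is realised as ⌈pct/100 · KT/2⌉ pair removals:
exact for T = 5 (2, 5, 8 pairs of 20 cells); for T = 10 the 50% checkpoint
is 23 pairs = 46 of 90 cells (51.11% removed, 48.89% remaining), the
nearest attainable design past the midway point. A checkpoint beyond the
minimally viable design is flagged `reached = False` rather than treated
as an error. The full sweep is single-threaded and completes in seconds.

## Simulator

`simulate.py` draws replicate cluster-period means directly from the mean
model plus the random terms: γ\_k from τ²R via Cholesky and the averaged
individual error at variance σ²ε/m. It emulates exactly the distributional
assumptions of the design calculations — Gaussian outcomes, equal cell
sizes, known correlation parameters, no treatment-effect heterogeneity —
so Monte-Carlo agreement (the empirical covariance of simulated means, and
the empirical variance of per-replicate GLS estimates at 20,000
replicates within three Monte-Carlo standard errors) validates the
algebra, not the model's fit to any real trial. Real stepped wedge data
with unequal cluster sizes, non-Gaussian outcomes, cohort sampling or
effect heterogeneity lie outside what these checks can establish; for
heterogeneous treatment effects even the centrosymmetry of IC values
breaks down.

## Parameters at a glance

| parameter | meaning | default / range |
|---|---|---|
| T | periods (clusters K = T−1) | ≥ 2; reducible from 3 |
| m | participants per observed cell | ≥ 1 |
| ρ | within-period ICC | [0, 1) |
| r | cluster autocorrelation | (0, 1]; 1 = exchangeable |
| effect_size | standardised effect θ (total-SD units) | 0.25 |
| alpha | two-sided significance level | 0.05 |

Power uses the normal approximation without degrees-of-freedom correction
and omits the opposite-tail term (negligible for any power above ~10%);
outputs print percentages to two decimals.

## Known limitations

Single cluster per sequence only; equal cluster-period sizes; continuous
outcomes with categorical time effects; no transition periods, no cohort
sampling, no cost-weighted removal, no global search over incomplete
designs (the algorithm is greedy and can in principle miss a better
non-nested design of the same size).
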