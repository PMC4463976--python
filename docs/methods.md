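# Methods

## Model

For N related subjects, the phenotype follows the additive polygenic model

    Y = Xβ + g + ε,  g ~ N(0, σ²_A · 2Φ),  ε ~ N(0, σ²_E · I),

with Φ the kinship matrix (entry (i,j) is half the expected fraction of
genome shared identically by descent; 0.5 on the diagonal for non-inbred
subjects). Narrow-sense heritability is h² = σ²_A / (σ²_A + σ²_E).
Assumptions: additive and unique-environment components only (no
dominance, household, or linkage terms), multivariate Gaussian errors,
non-inbred kinship in the synthetic generator (the kinship recursion
itself supports inbreeding).

Let `2Φ = S D_g S'` with orthonormal S and `D_g = diag(λ)`. Rotating by S'
gives `Y* = X*β + ε*` with diagonal covariance `Σ* = σ²_A D_g + σ²_E I`.
The rotation is a reparametrization, so the transformed likelihood equals
the dense one at the same parameters (tested against a dense-likelihood
oracle on small pedigrees). Because families are independent, Φ is
block-diagonal and the eigendecomposition is done per connected block
(blocks are recovered from the sparsity pattern, so a pre-computed kinship
matrix works as well as a pedigree). `trace(2Φ)/N = 1` for non-inbred
pedigrees, hence `mean(λ) = 1`; this is asserted to 1e-10 on every
generated pedigree.

Eigen-order convention: within each family block eigenvalues are sorted
descending and each eigenvector's sign is fixed by making its
largest-magnitude entry positive. All estimates and statistics are
invariant to this choice (tested by refitting under random sign flips and
reorderings); the convention only pins down a reproducible S. Eigenvalues
in [-1e-10, 0) are clipped to zero; anything more negative raises.

## Estimation

Newton's method on the transformed likelihood gives, at each iteration, a
weighted least-squares update for β and a weighted regression of the
squared residuals f* = ε̂*² on U = [1, λ] (weights Σ*⁻²) for
θ = (σ²_A, σ²_E), with a non-negativity projection max(0, ·).

* **OLS** — unweighted starting values (not recommended as final
  estimates).
* **WLS (one-step)** — exactly one weighted step from the OLS start;
  verified equal to the generic Newton iterate built from the score and
  expected information.
* **ML** — the updates iterated until |Δ log-likelihood| < 1e-8, at most
  200 iterations (the reference text states no tolerance; these are
  package choices). Non-convergence sets a flag instead of raising, so
  voxel-wise batch fitting never aborts.

Boundary handling (a deliberate refinement): the literal projected update
has spurious fixed points on the boundary — when the joint update clips
σ²_A to 0, the clipped GLS intercept is not the constrained maximum. The
ML loop therefore re-solves the free component on the active face
(σ²_E = mean(f*) when σ²_A = 0, and the one-column weighted regression for
σ²_A when σ²_E = 0). The result matches a dense-likelihood Nelder–Mead
optimizer to < 1e-6 in log-likelihood on test problems. The one-step WLS
estimator keeps the plain clipped update, since its definition is "one
literal Newton step". σ²_E is floored at 1e-12 × var(Y) whenever an update
would zero it, keeping Σ* invertible.

ML carries a genuine O(1/N) downward bias in ĥ² (about −0.006 at
N = 1500 with three covariates); WLS is slightly more biased but has MSE
within ~10% of ML at that scale. This is a property of the estimators, not
an implementation defect.

## Tests of H0: h² = 0

* **Score** — needs only the null (OLS) fit:
  `T_S = ½ (σ̂²_A,OLS / σ̂²_OLS)² · Σᵢ(λᵢ − λ̄)²` with σ̂²_OLS = ε̂'ε̂/N,
  equal to half the explained SS of the unweighted regression of
  f*/σ̂²_OLS on λ (the denominator must be the naive residual variance for
  this identity to hold).
* **Wald** — `T_W = ½ σ̂⁴_A [C(U'Σ̂*⁻²U)⁻¹C']⁻¹`, C = [0 1]. For the ML
  flavor Σ̂* is the ML fit and the statistic obeys the closed identity
  `½(N − (1'Σ̂*⁻¹1)²/(1'Σ̂*⁻²1))` (frozen in a test). For the WLS flavor
  the information uses the OLS weights that define the one-step estimator,
  so the statistic is half the generalized explained SS of the weighted
  auxiliary regression of f*_OLS on λ.
* **LRT** — 2(ℓ_alt − ℓ_null) clipped at 0; the null model is the trivial
  iid/OLS fit. The WLS flavor evaluates ℓ_alt at the one-step point (and
  uses the WLS β̂, a choice the source text leaves open).
* **Goldfeld–Quandt** — split subjects into group A (λ > 1, high variance
  under H1) and group B (λ ≤ 1, ties to B), fit OLS separately per group,
  and form the ratio of residual mean squares with A in the numerator.
  With denominators n − p the statistic is exactly F(n_A − p, n_B − p)
  under the Gaussian null (verified by a Kolmogorov–Smirnov test at 10,000
  null replicates); the printed n − 1 denominators are available behind a
  `ddof` switch and only rescale the statistic. The test is one-sided
  (upper tail): heritability can only inflate variance with λ.

The likelihood-based statistics sit on the boundary of the parameter space
under H0; their parametric reference is the 50:50 mixture of a point mass
at 0 and χ²₁ (p = 1 exactly when T = 0). For dependent family data zeros
occur at a rate above 50% (≈78% on the package's default synthetic
pedigree), which makes these parametric p-values conservative — the
motivation for permutation inference. Wald and score statistics are set to
0 exactly when the corresponding constrained σ̂²_A is 0, implementing the
boundary-adjusted test.

## Permutation inference

Under H0 the transformed data are iid after covariate removal, so subjects
are freely exchangeable (no within-family restriction is needed).
Schemes: P1 permutes λ only; P2 permutes OLS residuals and adds back
X*β̂_OLS; P3 does the same with full-model residuals; P4 permutes
whitened full-model residuals `Σ̂*^(-1/2) ε̂*` with **no** mean add-back —
implemented exactly as stated, with an `add_mean_p4` option since the
omission may be unintended. Permutations are sampled uniformly with
replacement from the symmetric group; the identity is included among the m
draws, ties count toward rejection, and p = #{T_perm ≥ T_obs}/m, giving a
floor of exactly 1/m (0.002 at m = 500). A surrogate whose refit fails
contributes statistic 0 (conservative) and is counted, never raised.

The batch engine exploits the fact that for every scheme the surrogate
statistic depends on the data only through a row-permuted base residual
matrix (the mean add-back is annihilated by the refit), so one gather plus
one projection per permutation serves all voxels/replicates. The engine is
asserted equal, column by column, to a naive loop over the univariate
pipeline. For the score statistic under P1 the OLS residuals never change
and only λ moves; the fast path skips the refit (asserted identical to
naive recomputation).

## Image-wise analysis

All in-mask voxels are fit and tested with one shared permutation
sequence — required for the max-statistic and max-cluster-size null
distributions. Voxel-wise FWE p at v is the fraction of permutations whose
image-wide maximum reaches T_v. Cluster inference thresholds the observed
and each permuted map at the parametric quantile matching the chosen
forming p (mixture or F quantile — deliberately parametric even though
those quantiles are miscalibrated, which reproduces the known
anticonservativeness of the Wald-WLS flavor at strict forming thresholds);
connected components use 26-connectivity by default (6/18 available). FDR
is Benjamini–Hochberg on uncorrected p-values (permutation p when
available). Phenotype normalization uses rank-based inverse-normal scores
with the Blom offset (r − 3/8)/(N + 1/4), average ranks for ties.

## Synthetic data

The stated simulation world: a 2-family, 138-subject pedigree; design of
intercept, a linear trend from 1 to −1, and the squared linear grid
rescaled to [−1, 1] (the source says only "a quadratic vector between 1
and −1"; the rescaling is this package's convention); β = (0, 0, 10);
ε ~ N(0, h²·2Φ + (1 − h²)I) for h² ∈ {0, 0.2, 0.4, 0.6, 0.8}. Phenotypes
are drawn in the eigenbasis (diagonal covariance) and rotated back when
original-basis data are wanted — distributionally identical to a dense
Cholesky draw (checked elementwise on a small pedigree over 50k draws) and
O(N) instead of O(N³).

The pedigree generator grows each family from a founder couple through
1 + Poisson(1.8) children per couple and marry-in spouses (new founders)
who immediately reproduce, until the family quota is met exactly; all
matings are between non-relatives. Only family counts and sizes of the
reference configurations are matched — the true topologies of the
workshop/study pedigrees are not public, so pedigree-sensitive quantities
(power values, mixture-test sizes) can only be checked qualitatively.

Null images: subject-wise white noise on a grid padded by 2 × FWHM per
side, Gaussian-smoothed with σ = FWHM/√(8 ln 2) (default voxel size
2 mm), renormalized to unit marginal variance by the L2 norm of the
realized kernel (the source does not state whether it renormalized; doing
so keeps per-voxel effect sizes on the stated scale), truncated to the
target grid, then given genetic structure through the same eigenbasis
scaling. What a green image test establishes: FWE calibration under
stationary Gaussian smoothness with exchangeable subjects — not
performance under real-data nonstationarity, registration error, or
non-Gaussian phenotypes.

## Numerical notes and limitations

* Identifiability requires dispersion in λ: an all-founders (unrelated)
  sample has U rank-deficient and raises rather than returning noise.
* Degenerate constant phenotypes report ĥ² = 0 with a flag.
* The GQ groups must each exceed the covariate count; tiny pedigrees can
  fail this precondition.
* Asymptotic equivalence of score/Wald/LRT holds under local alternatives;
  at fixed large effects the statistics rank realizations differently.
* Out of scope: REML, dominance/household components, multivariate genetic
  models, genotype-derived relatedness, X-linked kinship, random-field
  thresholds, TBSS/registration preprocessing (only the inverse-normal
  transform of already-extracted phenotypes is provided).
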