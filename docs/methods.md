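# Methods

## Model

`mmreml` fits Gaussian variance-component mixed models

y ~ N(Xβ, Σ_γ),  Σ_γ = Σ_{k=1..K} σ_k² V_k,

where each V_k is a known correlation structure, possibly factored as
V_k = Z_k R_k Z_kᵀ with an incidence matrix Z_k (n × n_k) mapping
observations to the n_k levels of the k-th random effect and a level
correlation R_k (a kinship, a double-relatedness matrix, or the identity).
Variance parameters are estimated by restricted maximum likelihood: with

P_γ = Σ_γ⁻¹ − Σ_γ⁻¹X(XᵀΣ_γ⁻¹X)⁻¹XᵀΣ_γ⁻¹,

the restricted log-likelihood (up to an additive constant) is

L_R(γ) = −½ [ log|XᵀΣ_γ⁻¹X| + log|Σ_γ| + yᵀP_γy ].

No error-contrast basis M with MX = 0 is ever materialized; L_R does not
depend on its choice, and m = n − p (p = rank(X)) plays the role of its rank
throughout.  Fixed effects are recovered afterwards by GLS at γ̂, with
covariance (XᵀΣ_γ̂⁻¹X)⁻¹.

## The Min-Max solver

At the current iterate γ⁽ᵗ⁾ the objective f = −L_R is dominated by the
separable surrogate

g(γ) = ½ Σ_k [ σ_k² tr(P⁽ᵗ⁾V_k) + (σ_k⁴(t)/σ_k²) yᵀP⁽ᵗ⁾V_kP⁽ᵗ⁾y ]
       + ½ ( log|XᵀΣ_t⁻¹X| + log|Σ_t| ) − m/2,

with equality at γ⁽ᵗ⁾ (the linear term majorizes the concave log-determinant,
the 1/σ_k² term majorizes the convex quadratic form).  Minimizing g
coordinate-wise gives the multiplicative update

σ_k²(t+1) = σ_k²(t) · sqrt( yᵀP⁽ᵗ⁾V_kP⁽ᵗ⁾y / tr(P⁽ᵗ⁾V_k) ),

whose fixed points are exactly the stationary points of L_R and which can
never leave the positive cone.  Ascent is monotone by the MM argument and is
asserted (slack 1e-10) on every logged iteration in the test suite.

The square root in the update is forced by differentiating the surrogate;
the stationarity condition σ_k⁴ = σ_k⁴(t)·yᵀPV_kPy / tr(PV_k) has a unique
positive root.  A component entirely confounded with the fixed effects
(tr(PV_k) = 0) is frozen at zero.

Tunables (units are those of the trait, squared, for all variances):

* `tol` (default 1e-5): both convergence criteria must hold — the ∞-norm of
  the variance step and the objective gain below `tol`.
* `max_iter` (default 1000).
* `init="auto"`: OLS residual variance split equally across components;
  strictly positive and scale-aware.
* Boundary floor: a variance below 1e-10 × (initial total variance) for 3
  consecutive iterations is frozen there and leaves the convergence norm —
  the multiplicative update decays geometrically but never reaches zero.

### SQUAREM acceleration

Every third iteration a squared-extrapolation proposal is formed from the
last three iterates: r = θ⁽ᵗ⁻¹⁾−θ⁽ᵗ⁻²⁾, v = θ⁽ᵗ⁾−2θ⁽ᵗ⁻¹⁾+θ⁽ᵗ⁻²⁾ (the second
difference), α = −‖r‖₂/‖v‖₂, proposal θ⁽ᵗ⁻²⁾ − 2αr + α²v.  It is accepted
only when entrywise positive and strictly improving, so monotonicity is
preserved.  For a linearly contracting iteration this extrapolation jumps
toward the geometric-series limit; on the 4-component factorial fit it cuts
the iteration count by roughly a factor of twenty.

## Newton, Fisher scoring and Average Information

An independent solver works in the ratio parameterization
δ_k = σ_k²/σ_ref², σ_ref² (reference component PD, normally the residual),
with Σ_δ = Σ δ_kV_k + V_ref and P_δ = σ_ref²P_γ.  The reference variance is
profiled out in closed form, σ̂_ref²(δ) = yᵀP_δy/m, and Newton-type updates
are applied to δ alone.  The curvature is the Average-Information matrix

AI_kk' = yᵀP_δV_kP_δV_k'P_δy / (2σ_ref²),
AI_kR ≈ yᵀP_δV_kP_δy / (2σ_ref⁴),   AI_RR = yᵀP_δy / (2σ_ref⁶),

the negated average of the observed and expected Hessians (exact on the
ratio block; the reference row uses the trace-free approximation
tr(V_kP_δ) ≈ yᵀP_δV_kP_δy / σ_ref²).  Because σ_ref² is profiled, the δ-step
uses the Schur complement of the reference entry — using the raw δ-block
overestimates curvature and degrades the iteration to a slow linear crawl.

Stabilization, chosen here because no safeguard is canonical: step-halving
(max 20) against a strict non-decrease of L_R; negative ratio proposals are
clamped onto a geometric path to the boundary (×0.1 per iteration, zeroed
and removed from the Newton system once below 1e-12 or negligible relative
to the largest ratio); fallback directions (damped AI, Fisher scoring) with
a trust region of 5×max(1, ‖δ‖_∞) per step; convergence is never declared on
an iteration that moved a coordinate toward the boundary.

Profiling requires a positive-definite reference component.  Models with
only singular components — notably the trial-specific error-variance model,
whose per-trial error structures are 0/1 diagonal indicators — are refused
by `fit_ai` and handled by `fit_mm`, which needs no profiling.  When the
*estimated* reference variance collapses to zero the profiled AI iteration
can fail to converge (all ratios diverge jointly); this is a structural
weakness of AI-with-profiling, not of the model, and `fit_mm` remains the
robust path.

### Standard errors

Variance standard errors come from the inverse AI matrix at the optimum,
mapped from (δ, σ_ref²) to the variance scale by the delta method
(γ_k = δ_kσ_ref²).  For K = 1 this reduces to the closed form
SE(σ̂²) = σ̂²√(2/m).  A 200-replicate simulation at n = 300 checks the mean
reported SE against the empirical sampling SD within 25%.  At boundary
optima the AI matrix is not invertible as a covariance and SEs are reported
as unavailable rather than fabricated.

## Two-component fast path

For K = 2 with V₂ PD, one simultaneous orthogonalization Λ (from the
Cholesky of V₂ and an eigendecomposition) gives ΛV₁Λᵀ = diag(D),
ΛV₂Λᵀ = I.  On transformed data the profiled restricted likelihood is a
function of the single ratio δ:

L_R(δ) = −½ [ m log(σ̂₂²(δ)) + log|Dδ+I| + log|X̃ᵀ(Dδ+I)⁻¹X̃| + m ],

evaluable in O(np²).  The MM step for δ minimizes the profiled surrogate,
which reduces to the quadratic

tr(P_δD)·b·δ² + tr(P_δD)·a·δ_t²·δ − m·a·δ_t² = 0,
a = ỹᵀP_δDP_δỹ,  b = ‖P_δỹ‖²  (all at δ_t),

with a unique positive root (the constant term is negative).  A scalar
squared-extrapolation accelerates the iteration — essential near either
boundary, where the plain update crawls geometrically (measured: 500
iterations reach δ ≈ 272 on a divergent-ratio instance that the accelerated
iteration finishes in a handful) — and a safeguarded bounded search on
log(1+δ) finishes any run that has not met both convergence criteria.
Degenerate quadratic coefficients fall back to the same bounded search.

The quadratic-root update and the generic two-component MM update are
*different* iterations (the former minimizes the profiled surrogate, the
latter the separable one); they share fixed points and are tested to agree
at convergence (1e-5 on the variances, 1e-6 on δ against a 1-D oracle), not
along the trajectory.

For genome scans Λ is computed once; each marker only appends one
transformed column to X̃ and refits δ from the base-model warm start.  Exact
per-marker p-values match independently rebuilt models to 1e-8, and warm
starting changes no estimate beyond solver tolerance.

## Henderson mixed-model-equation shortcut

When every R_k and the reference V are invertible and the total latent
dimension Σn_k + p is small against n, the quantities of the MM update are
taken from the MME coefficient matrix C instead of the n × n projection:

ZᵀP_δy = G_δ⁻¹û,  ZᵀP_δZ = G_δ⁻¹ − G_δ⁻¹[C⁻¹]_uuG_δ⁻¹,  P_δy = V_ref⁻¹ê,
tr(P_δV_ref) = m − tr(ZᵀSZ·[C⁻¹]_uu),

with S = V_ref⁻¹ − V_ref⁻¹X(XᵀV_ref⁻¹X)⁻¹XᵀV_ref⁻¹ computed once per model.
The restricted likelihood is evaluated on the same factorization through
|C| = |Q|·|XᵀΣ_δ⁻¹X| and |Σ_δ| = |V_ref|·|G_δ|·|Q| (Q the lower-right block
of C), so the shortcut never forms an n × n inverse.  The direct and MME
update paths are algebraically identical and tested to agree to 1e-8 over
20-iteration trajectories.

Strategy selection uses a pure flop proxy with threshold 1:
(Σn_k + p)³ + Σn_k²·n < n³ + K·n², plus the invertibility requirement;
`use_mme` ∈ {auto, on, off} overrides it.  C is rebuilt each iteration
(correctness over speed; low-rank updating is a possible future
optimization).

## GWAS

Each polymorphic marker's dosage (allele-1 copy count in {0,1,2}, real
dosages accepted) enters the fixed part; dominance adds a heterozygote
indicator and a 2-df test.  The Wald statistic is W = β̂_Tᵀ[cov_TT]⁻¹β̂_T
against χ²(|T|).  Modes:

* exact — variances refitted per marker (warm-started);
* approximate — variances fixed at the base fit, GLS per marker only; close
  to exact (rank correlation ≥ 0.99 on test panels) but not identical;
* LOCO — per chromosome, the kinship is rebuilt from all other chromosomes'
  markers.

Missing dosages are mean-imputed per marker with a warning; monomorphic
markers are skipped and counted.  Multiple testing uses Bonferroni at the
effective number of tests: per chromosome, the smallest number of leading
eigenvalues of the marker correlation matrix reaching 99.5% of the total,
summed (the simpleM recipe).  Model comparison uses
BIC = −2L_R(γ̂) + q·log(m) with q free variance parameters and m = n − p;
because L_R carries an arbitrary additive constant, only BIC differences
between models fitted to the same data are meaningful, and the m-based
sample size is recorded in the output metadata.

## Synthetic designs

The generator reproduces the three study layouts structurally:

* line panel — n lines, i.i.d. biallelic dosages with per-marker MAF uniform
  in (0.05, 0.5], VanRaden kinship W Wᵀ / Σ2f(1−f);
* incomplete factorial — n_F flint × n_D dent parents, hybrids sampled
  without replacement from the cross grid, components flint/dent/interaction
  (double-relatedness Φ_{hh'} = (K_F)_{ff'}(K_D)_{dd'})/error;
* multi-trial — per-trial flint/dent/hybrid interaction components sharing
  the parental correlations, row and column effects with identity
  correlations, and a common or trial-specific error.  The inventory is
  3 + 5·N_T + 1 components (common error) or 3 + 5·N_T + N_T (trial-specific):
  44 vs 51 at N_T = 8, asserted structurally.

What it deliberately does not emulate: linkage disequilibrium (markers are
i.i.d.; no computation here depends on LD beyond what kinship induces),
spatial autocorrelation of field rows/columns, pedigree structure, and the
original studies' actual kinship matrices.  Passing recovery tests therefore
demonstrates correct inference under the stated model, not robustness to
real-data violations of it.

## Problem sizes and study conditions

Simulation sizes are the package's own scaled study conditions: oracle and
cross-solver checks on 20 instances with n ≤ 60 and K ∈ {2,3,4}; factorial
recovery at n = 400 hybrids (30 × 40 parents), 100 replicates, true
variances (1, 1, 0.5, 1); multi-trial recovery at N_T = 3, n = 600
(19 components), 50 replicates; GWAS calibration at n = 300 with 2,000 null
markers drawn independently of the phenotype.  Recovery is judged by the
mean estimate across replicates lying within 3 Monte-Carlo standard errors
of truth per component; the type-I error at α = 0.05 must fall in the
binomial band [0.040, 0.060].

Two measurement conventions: variance comparisons are relative per
component, with components that *both* routes place below 1e-6 of the
phenotypic variance counted as agreeing (a converged multiplicative iterate
stops a few multiples of its step tolerance above an exact zero); and
high-precision cross-checks run the solvers at tol = 1e-9 rather than the
1e-5 default, since the comparisons are at 1e-4/1e-5.

## Numerical choices and degenerate inputs

* All Σ solves via Cholesky; log-determinants from Cholesky diagonals; a
  non-positive pivot reports the offending γ.
* Dense P is materialized once per iteration (one extra n² backsolve) for
  the K trace terms; quadratic forms reuse P y.
* Eigenvalues of PSD structures are clipped at zero when within −1e-8
  (round-off); component V_k must be PSD within −1e-8·‖V_k‖, R_k symmetric
  within 1e-10.
* Singular individual V_k are permitted (required by the trial-specific
  error model); only Σ_γ must be PD at evaluated points.
* Correlation scaling of R_k (unit-ish diagonal) is warned about but not
  enforced — Φ need not have a unit diagonal.
* Rank-deficient X is rejected with the indices of the collinear columns
  (QR with pivoting).

## Known limitations

* No sparse-matrix or pedigree-scale specializations; dense algebra caps
  practical n at a few thousands.
* No factor-analytic or autoregressive covariance structures; the MM
  surrogate is specific to the nonnegative-combination covariance.
* No multi-trait (genetic correlation) models, permutation thresholds, or
  score tests.
* AI-with-profiling can fail when the reference variance estimate collapses
  to zero (see above); use the MM solver there.
* The reported effective number of tests depends on the eigenvalue cutoff
  (99.5%) and chromosome blocking of the simpleM dialect.
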