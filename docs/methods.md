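# Methods

This note records the statistical model, the numerical choices, and the
limits of what the test suite establishes.

## Two-stage analysis

Stage 1 estimates genotype means per environment as fixed effects. BLUEs
are reported as full genotype means on the observation scale: other factors
use sum-to-zero coding and numeric covariates are centered, so each BLUE is
the genotype mean at the average covariate level and Stage 2 can carry
environment main effects. With i.i.d. random covariates (single trait
only), variance components come from REML and BLUEs from GLS; the BLUE
covariance is then conditioned on the estimated variance components
(standard empirical-BLUE practice — the uncertainty of the Stage-1 variance
estimates is *not* propagated). Multi-trait Stage 1 assumes a separable
residual covariance: with an identical design matrix across traits the GLS
refit equals OLS, so the estimator is OLS per trait plus the residual
cross-product matrix, and vcov(BLUE) = (X′X)⁻¹ ⊗ Σ̂. Spatial models are out
of scope; externally produced BLUE + vcov tables can be loaded through
`Stage1Fit.from_csv` so spatial adjustment can happen upstream.

Stage 2 fits, by REML, the mixed model on the stacked BLUEs with (i)
environment fixed effects (trait-specific in multi-trait mode), (ii)
optional fixed marker covariates and the heterosis covariate, (iii) random
genetic terms, (iv) an i.i.d. (or per-location, or per-cell unstructured)
G×E residual, and (v) the Stage-1 error term with *fixed known* covariance
⊕ⱼVⱼ entering V with coefficient exactly 1.

## Relationship matrices and dominance

Allele frequencies are always the observed frequencies of the supplied
population; markers that are monomorphic (or fail the MAF/missingness
filters) are dropped before any matrix is built, and missing dosages are
imputed with the marker mean so the centered matrix W is well defined.
Because W is column-centered, G·1 = 0: G is rank-deficient by construction.
Code paths that need an inverse either avoid it (the BLUP V-inversion
route) or use the pseudo-inverse (marker-effect backsolve, where predicted
values lie in the range of G, making the pseudo-inverse exact).

The dominance coefficient Q, relationship D, and inbreeding vector F follow
the digenic framework extended to arbitrary even ploidy. The heterosis
covariate entered in the fixed design is −(F − F̄); centering moves a
constant into the environment means and leaves b and its SE unchanged. The
F used as covariate is the dominance-based definition (the theoretically
correct regressor); the diag(G)-based definition is available for
comparison via `inbreeding_from_diag`.

Pedigree A supports ploidy 2 and 4 by the tabular kinship recursion; the
tetraploid case assumes random bivalent pairing and no double reduction
(F_offspring = (F_s + F_d)/6 + (2/3)·f(s,d)). This is a documented
simplification — quadrivalent pairing would inflate inbreeding slightly.

## REML engine

The restricted log-likelihood includes the −½log|X′V⁻¹X| term and the
(n−p)log 2π constant, so ℓ_R values are comparable across implementations
using the same convention. AIC = −2ℓ_R + 2k counts only free (co)variance
parameters; fixed-known terms add zero, which is what makes
with/without-Stage-1-error comparisons meaningful.

Free parameters are transformed to an unconstrained scale (log variances;
log-Cholesky for unstructured; loadings free with Λ[0,2nd] pinned to zero
for FA2; log per-trait scales for the correlation-fixed-at-1 structure) and
optimized by L-BFGS-B with analytic gradients
(∂ℓ/∂θ = −½[tr(P ∂V) − y′P ∂V P y]); Nelder–Mead is the fallback when the
gradient path fails or regresses below the deterministic start (variances
initialized at half the phenotypic variance split equally). Variance
estimates below 1e−8 × phenotypic variance are flagged as boundary ("B").
FA2 needs at least 3 levels; with fewer, an unstructured covariance is
substituted silently (logged). FA2 loadings are reported after varimax
rotation (statsmodels) with a non-negative-column-mean sign convention;
per-location uniplot coordinates are Λᵢ/√Γᵢᵢ so the squared radius is the
proportion of genetic variance captured by the two factors.

Multi-location models fix the non-additive correlation across locations at
1 (equivalently a single genotype-level term), following the observation
that a free correlation always ends on that boundary; multi-trait models
estimate separate unstructured covariances for additive and non-additive
effects, and the per-cell G×E residual covariance across traits is
unstructured (the structure is otherwise unspecified; this is our choice).

## PVE accounting

Each effect's contribution is its expected variance on the G×E basis:
E[V] = [w-mean diag(K) − w-mean K] + [w-mean μ² − (w-mean μ)²] with weights
equal to the number of observations per genotype. Heterosis is the μ-part
of the fitted −bF term; fixed markers likewise contribute through μ = Wδ.
For multi-location fits the additive G ⊗ Γ term is split into a main effect
(off-diagonal mean of Γ, Rogers-style) and a G×location remainder.
Environment main effects are excluded and rows normalized to sum to 1. The
split is not an orthogonal decomposition — effects share variance when
their covariance structures overlap (visible as transfer between additive
and dominance PVE in single realizations).

## BLUP, merit, and reliability

The standard-form rewrite stacks additive and non-additive values
(trait-within-individual); the residual covariance is the G×E term plus the
Stage-1 blocks, block-diagonal per environment. The solver inverts the MME
coefficient matrix when records outnumber effects *and* var(u) is
numerically nonsingular (VanRaden G is not, see above); otherwise it
inverts V — both routes agree to machine precision where both apply, and
var(û) = var(u) − C₂₂ or var(u)Z′PZ var(u) respectively. Masking removes
records before solving; fixed-effect columns emptied or aliased by masking
are dropped with a warning.

Merit uses the index formulation: user weights are divided by per-trait
breeding-value SDs √(σ²_A + γ²σ²_D), rescaled to unit norm; γ is 0 / 1 /
(φ/2−1)/(φ−1) for additive / total / breeding value. Environment effects
are excluded from merit; marker effects enter with weight 1 and heterosis
with weight γ. Reliability is λ′var(ûᵢ)λ / λ′var(uᵢ)λ with
λ = [1 γ]′ ⊗ c, clipped to [0, 1].

## Selection response and restricted indices

B = varₙ(b̂) over the candidate population (unweighted means over the n
individuals), combining the var(û) dispersion and the spread of the fixed
marker/heterosis means. The gain program max c′x subject to x′B⁻¹x ≤ 1 plus
per-trait constraints is solved exactly: whitening with B = LL′ turns the
constraint into the unit ball, and active sets over the (few) linear trait
constraints are enumerated, each subproblem having a closed form. This
avoids iterative-solver failures entirely and reproduces the
Kempthorne–Nordskog solution for one equality constraint. Singular B is
handled by pseudo-inverse with a rank warning. Ellipse slices fix
non-displayed traits at a supplied (e.g. optimal) response; reported
responses can be standardized by Δ = diag(σ_b).

## GWAS

Additive effects are backsolved per marker from â (dominance from
d̂₀ − b̂(F−F̄), so the fixed heterosis part is represented); standard errors
use var(â) as written in the defining formula, and the null-simulation
calibration test guards that choice. Two-sided normal p-values; no
genomic-control adjustment. The effective marker count is computed per
chromosome from the dosage correlation matrix by an adjacency bound
(1 + Σⱼ √(1 − max r²) over preceding markers), with the Li–Ji eigenvalue
method as an alternative (`method="liji"`); eigenvalues are rounded before
the floor to avoid the discontinuity at exact integers. Backsolving
requires the pure genomic G (ω = 0); blended H breaks the WW′ ∝ G identity
and is rejected.

## Synthetic data: the stated world

`sim_population` draws dosages Binomial(φ, pₖ) at independent loci —
panmixia, no LD, no population structure. `sim_genetic_values` scales
effect variances so expected population variances hit the targets exactly:
σ²_α = σ²_A/(φΣpq), σ²_β = σ²_D/(C(φ,2)Σ4p²q²), and b = μ_β·C(φ,2)Σ2pq.
`sim_phenotypes` adds environment effects, i.i.d. G×E, and either
plot-level errors (2 reps, randomized blocks) or exact Stage-1-style BLUEs
with known heterogeneous error variances spanning a 0.5–2.0 scale range
across environments (the spread used in recovery tests). The reference
scenario is n = 300 tetraploids, m = 1000 markers, 4 environments,
σ²_A = 1, σ²_D = 0.3, b = 5, σ²_gE = 0.5 — sized so the whole acceptance
suite runs in minutes on one CPU.

What a green test does **not** establish: behavior under linkage
disequilibrium, selection, population structure, genotyping error, or
spatial field trends — none of which the generator emulates. The GWAS
null-calibration result in particular is for unstructured populations; with
structure, the polygenic term absorbs less confounding than claimed.

## Known limitations

* Multi-trait models assume homogeneous G×E (one genetic correlation across
  environments) and complete trait records per genotype-environment cell.
* No spatial Stage-1 models, no environmental covariates, no
  optimal-contribution selection, no >digenic dominance.
* Tetraploid pedigree A ignores double reduction.
* Stage-1 variance-estimate uncertainty is conditioned on, not propagated.
* Dense linear algebra throughout: comfortable to a few thousand records,
  not designed for tens of thousands.
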