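# Methods

## Model family

All models are linear mixed models for a single standardized trait y
(n animals) with fixed test-day effects Xb and independent residuals
e ~ N(0, Iσ²_e). The random animal effects differ:

- **GBLUP**: g ~ N(0, Gσ²_g) with G = ZZᵀ/m̃, Z the column-centered dosage
  matrix (dosage − 2pⱼ), m̃ = Σⱼ2pⱼ(1−pⱼ). Allele frequencies pⱼ are
  estimated from the sample unless supplied; monomorphic SNPs are excluded
  from both Z and m̃ (they carry no relationship information and would
  only perturb the scaling).
- **TBLUP**: t ~ N(0, Tσ²_t) with T = WWᵀ/k; W holds k transcript columns
  that are Box-Cox transformed, standardized, and pre-corrected for
  technical fixed effects.
- **GTBLUP**: both terms, assumed independent.
- **GTCBLUP / GTCBLUPi**: g plus t_c ~ N(0, T_cσ²_tc), where
  T_c = W_cW_cᵀ/k and W_c = (I − S_λ)W removes the genotype-predictable
  part of each transcript through the ridge smoother
  S_λ = Z(ZᵀZ + λI)⁻¹Zᵀ. The smoother is the BLUP operator of a SNP-effect
  model for the transcript-level effects, which fixes the ridge at
  λ = m̃(1/h̃²_t − 1), h̃²_t being the heritability of transcript-level
  effects. Centered Z (the same matrix as in G) is used in S_λ.

Because h̃²_t enters W_c nonlinearly, it cannot be estimated jointly with
the variance components; GTCBLUPi profiles it on a grid over (0, 1)
(default step 0.01, bounds one step in from 0 and 1 since λ is undefined
at the endpoints) and keeps the grid value with the highest REML
log-likelihood, ties going to the smaller h̃²_t (the more conservative,
lesser removal of genetic signal). Consecutive grid fits are warm-started
from the previous optimum. GTCBLUP instead derives λ from the trait's own
GBLUP heritability, λ = m(1/h² − 1) with m the SNP count (a flag switches
m to m̃); it refuses to run when the GBLUP heritability sits on the zero
boundary, where λ is undefined.

Two conditioning routes are implemented and tested against each other: the
direct form inverts the m×m matrix (ZᵀZ + λI); the Woodbury form
W_c = (I − G* + G*(I + G*)⁻¹G*)W with G* = G·m̃/λ inverts only n×n
matrices. The route is chosen by comparing n and m (ties to direct).

## REML

Variance components maximize the restricted likelihood
−½[log|V| + log|XᵀV⁻¹X| + yᵀPy + (n−p)log2π], V = ΣKᵢσ²ᵢ + Iσ²_e. The
optimizer is average-information REML: AI steps with step-halving,
falling back to an EM step whenever the damped AI step fails to improve
the objective. Components are floored at 1e-8·Var(y) (nonnegativity);
estimates finishing on the floor are flagged as boundary values.
Convergence requires |ΔlogL| < 1e-8 and a maximum relative parameter
change < 1e-6 within 200 iterations. Standard errors come from the
inverse AI matrix at the optimum; BLUPs are û_i = σ²ᵢKᵢPy and fixed
effects b̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, which jointly solve the mixed-model
equations (verified in the tests to 1e-6 relative).

Models with a single random term use a fast path that diagonalizes K once
and evaluates every iteration against the rotated data in O(np²); it
agrees with the dense path to well below test tolerances and makes
repeated fits (cross-validation, grid search, null simulations) cheap.

AIC = −2·logL_REML + 2·(number of variance parameters); fixed effects are
excluded from the count because compared models share X. Likelihood-ratio
tests report D = 2ΔlogL against χ² with df equal to the difference in
variance-parameter count; for a component tested on its boundary this is
conservative, and the 50:50 mixture p-value is available separately.

Variance proportions divide each σ̃²ᵢ = σ²ᵢ·mean(diag(Kᵢ)) by the total
σ̃²_g + σ̃²_tc + σ²_e. The mean-diagonal scaling matters for T_c, whose
diagonal is shrunk below one by conditioning; for G it is ≈1 by
construction, so applying it uniformly is essentially a no-op there.

## Preprocessing

Traits and transcript columns are Box-Cox transformed,
f(y) = (y^λ−1)/λ for λ≠0 and log y at λ=0, with λ chosen per column by
grid search over the normal-theory profile log-likelihood (including the
Jacobian term (λ−1)Σlog y). The default grid spans −4 to 6 — wide enough
for strongly skewed traits in either direction — with a coarse pass at
10× the step followed by a refinement at the step (default 0.001) around
the coarse optimum; exact ties break toward the value nearest 1 (no
transformation). Standardization uses the sample SD (n−1), matching
common statistical software. Transcript pre-correction then replaces each
column by its OLS residuals on the technical covariates (test day, plate,
sex, housekeeping-gene abundances as continuous covariates) and
re-centers; aliased covariate columns are dropped with a warning. The
order is fixed: transform → standardize → pre-correct → re-center. OLS is
used because the correction model contains only fixed effects.

## Cross-validation and accuracy

Random CV repeats an 80/20 reference/validation split (validation size
round(0.2·n)); family-based CV enumerates all C(g, v) combinations of
v = round(0.2·g) validation half-sib groups, keeping families intact so
reference and validation animals are less related (10 groups with 2 held
out gives exactly 45 folds). Variance components are re-estimated on each
reference set. Validation animal effects are predicted by conditional
expectation, û_val = K_val,ref(K_ref,ref + εI)⁻¹û_ref summed over random
terms; this matches re-solving the mixed-model equations with validation
records masked (tested to 0.005 in accuracy). Accuracy is the Pearson
correlation between predictions and phenotypes corrected for test-day
effects, with the correction b̂ estimated on the full data by least
squares (stable across folds; a per-fold option exists). Accuracies are
summarized on Fisher's z scale, z = ½ln((1+r)/(1−r)), as the
back-transformed mean and mean ± 1.96·SD(z). Paired model comparisons use
the per-fold accuracy differences with a mean ± 1.96·SD interval on the
raw differences — the z transform is not defined for differences in
general — and significance means the interval excludes zero.

By default GTCBLUPi's h̃²_t would be re-estimated per reference set like
every other parameter; since the grid search uses phenotypes, estimating
it once on the full data before CV would leak validation information and
is therefore not the default.

## Transcript-effect back-solving

From a TBLUP fit, per-transcript effects are recovered as
û = (1/k)WᵀT⁻¹t̂. Their sampling variance uses the prediction error
variance of t̂ via the animal-effect block of the inverse mixed-model
equations, Cᵗᵗ = σ²_e(I − X(XᵀX)⁻¹Xᵀ + T⁻¹λ)⁻¹ with λ = σ²_e/σ²_t
(valid when each animal has one record, which is asserted), giving
Var(û) = (1/k²)WᵀT⁻¹(Tσ²_t − Cᵗᵗ)T⁻¹W. The standardized effect
RNA_j = ûⱼ/√Var(ûⱼ) is tested two-sided against N(0,1); results report
both the nominal 0.05 and the Bonferroni 0.05/k thresholds, and a
Manhattan-style plot and TSV are available.

T (k < n) is singular, so all inversions of relationship matrices add a
relative ridge ε·mean(diag)·I with ε = 1e-6 by default (recorded in the
result); diagonal entries of Var(û) below −1e-10 raise an error, smaller
negatives are clipped to zero. The test statistic is undefined when
σ̂²_t = 0; fits with the transcript component on the boundary are
excluded from calibration experiments for that reason.

## Bivariate TBLUP

Two traits on the same animals share the covariance
Σ_t ⊗ T + Σ_e ⊗ I with 2×2 trait covariance matrices for the
transcriptomic and residual effects. Diagonalizing T once reduces the
REML log-likelihood to n independent 2×2 blocks, so each evaluation costs
O(np²) and the six parameters (Cholesky factors of Σ_t and Σ_e, PSD by
construction, log-scale diagonals floored at e⁻⁸) are maximized directly
by L-BFGS-B with a Nelder-Mead polish, multi-starting from the univariate
fits at transcriptomic correlations {0, ±0.8}. The residual covariance is
estimated (the traits are measured on the same animals, so omitting it
would confound r_t); a flag fixes r_e = 0. The transcriptomic correlation
r_t = Σ_t[1,2]/√(Σ_t[1,1]Σ_t[2,2]) gets a delta-method SE from the
numerical observed information, and H₀: r_t = 0 is tested by refitting
with Σ_t diagonal, D = 2ΔlogL against χ²₁. With both Σ matrices diagonal
the bivariate log-likelihood equals the sum of the two univariate TBLUP
log-likelihoods exactly — the module's primary correctness oracle.

## Synthetic data

The generator emulates the F2-cross design the models target: two founder
lines (default 12 animals each), an F1 of 10 sires and 20 dams mated 1:2
without rotation, and 24 F2 offspring per mating — 480 F2 animals in 10
paternal half-sib groups with full-sib pairs nested inside, hatched and
slaughtered across 11 test days with balanced assignment. Biallelic SNPs
(default 4000 at the full design; tests use fewer) are gene-dropped
through the pedigree at independent loci with line-specific founder
frequencies drawn uniformly from (0.05, 0.95). Transcript columns are
Zγ + ε with γ supported on a random 10% of SNPs, the genetic part scaled
so its realized variance fraction equals the target heritability (default
0.25), then standardized. Phenotypes compose test-day effects (SD 0.3 on
the standardized scale), a polygenic part g = Zα, a transcript-mediated
part t = Wτ, and noise, each centered and rescaled so realized sample
variances hit the targets (default 0.25/0.35/0.40) exactly. All
randomness derives from one integer seed through named generators, so
every output is bit-reproducible.

Two generative modes exist for the phenotype. The default composes g and
t independently — the joint (GTBLUP-type) truth. Under that truth, no
conditioning is ever optimal: the profile log-likelihood of the
conditioned model is maximized as h̃²_t → 0, because T itself is the
correct covariance. The `condition_transcripts` option instead uses
t = W_c(λ(h̃²_t*))τ, the generative counterpart of the conditioned model,
in which the heritable share of the transcript effect belongs to the
genetic term rather than being double-counted; only under this mode does
the grid search have a well-defined target, and the recovery experiments
use it.

What the simulations do not emulate: linkage and recombination (loci are
independent, so the LD structure of a real F2 map is absent — this
affects LD patterns, not the correctness of the estimators), selection of
phenotypically discordant sib pairs for expression profiling (the
simulator samples at random), technical batch structure in the transcript
data beyond what pre-correction handles, and miRNA-vs-mRNA biology.
Passing tests therefore demonstrate correct statistical machinery under
the stated covariance structures, not robustness to map-level LD or
selection bias.

## Problem sizes in the checks

The verification experiments use deliberately chosen scales: route
equivalence on 30 randomized shapes spanning n>m, n<m, n=m;
REML-vs-oracle at n=50; GTBLUP variance recovery at the study size
(n=480, 20 replicates, 2-SE coverage ≥ 80%); transcript-heritability
recovery at n=1000, m=500, k=80 with a 0.05 grid (5 replicates, median
within 0.10 of 0.25); RNA-test and bivariate-LRT calibration at 200 null
replicates each. The GTBLUP↔GTCBLUPi limit check (grid point h̃²_t=0.01)
sits deep in the m≫n regime (n=30, m=20000): the smoother at that grid
point still shrinks about 1% of every genotype-space direction, a uniform
shrink is absorbed exactly by the variance component, and the residual
log-likelihood gap is first-order in the smoother's spectral
non-uniformity, which scales like √(n/m) — family-structured data at
study shapes therefore reduce only to within ~0.05–0.4 log-likelihood
units, while the m≫n design reduces below 1e-3.

## Known limitations

- REML enforces nonnegative variance components; software that permits
  slightly negative components can differ at boundaries.
- The singular T is handled by an explicit documented ridge; results near
  machine precision depend mildly on ε.
- The bivariate optimizer is a direct 6-parameter search; with nearly
  degenerate data (e.g. duplicated traits) the likelihood is unbounded on
  the PSD boundary and estimates saturate at the parameterization floor.
- Family-based CV assumes group labels partition the animals; overlapping
  family structures are not supported.
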