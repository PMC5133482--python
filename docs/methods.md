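# Methods

## 1. Data model

Each individual *i* in family *f* contributes up to *T* clinic visits,
each with systolic and diastolic blood pressure (SBP, DBP), age, sex,
smoking status, and an antihypertensive-treatment indicator.  The SEM
operates on medication-adjusted, covariate-residualized traits
(rSBP, rDBP), stacked per person as the length-2*T* vector
(rSBP₁, rDBP₁, …, rSBP_T, rDBP_T).

## 2. Structural equation models

Both models share a measurement layer: at visit *t* a latent
blood-pressure factor η_t drives the two observed traits,

    rSBP_t = η_t + ε_St,      ε_St ~ N(0, θ_S)
    rDBP_t = λ η_t + ε_Dt,    ε_Dt ~ N(0, θ_D)

with a single loading λ (`lambda_dbp`) and measurement-error variances
θ_S, θ_D shared across visits.  SBP anchors the latent scale (loading
fixed at 1), so η is in mmHg.

**AR model.**  The latent factors form a first-order chain,

    η_1 = μ₁ + γ g + ζ_1
    η_t = β η_{t−1} + ζ_t          (t ≥ 2)

where g is the minor-allele dosage of the tested SNP and γ the SNP
effect (0 under the null).  Each disturbance ζ_t splits into an
additive-genetic and an environmental part, ζ_t = a_t + e_t with
a_t ~ N(0, σ²_{a,t}) and e_t ~ N(0, σ²_{z,t}); the first visit's
variances are free, visits ≥ 2 share one pair.  Free parameters (9):
μ₁, λ, β, σ²_{a1}, σ²_a, σ²_{z1}, σ²_z, θ_S, θ_D.

**LG model.**  Latent intercept I and slope S with fixed time loadings
l_t = t − 1 generate the visit factors,

    η_t = I + l_t S + v_t,   v_t ~ N(0, σ²_v)
    I = μ_I + γ g + (a_I + e_I),   S = μ_S + (a_S + e_S)

with (a_I, a_S) ~ N(0, Σ_a) and (e_I, e_S) ~ N(0, Σ_e), both full 2×2.
Free parameters (12): μ_I, μ_S, λ, the three entries of each of Σ_a
and Σ_e, σ²_v, θ_S, θ_D.

Both models are instances of the reduced form
Σ = Λ(I − B)⁻¹Ψ(I − B)⁻ᵀΛᵀ + Θ; splitting Ψ into its genetic and
environmental parts yields per-person genetic and environmental trait
covariances Σ_A and Σ_E (2T × 2T), and the SNP shifts the mean along
the direction c = Λ(I − B)⁻¹Γ, per allele scaled by γ.

## 3. Family likelihood

Relatives share genes: for family members i, j the additive-genetic
covariance is 2φ_ij Σ_A, with φ the kinship coefficient from the
standard tabular recursion (φ_ii = ½(1 + φ_fm), φ_ij = ½(φ_jf + φ_jm)
over parents f, m in topological order).  Stacking a family of n
members row-major gives

    V_f = 2Φ_f ⊗ Σ_A + I_n ⊗ Σ_E

and the log-likelihood is the multivariate-normal log density of the
observed entries (missing visits are marginalized by row/column
deletion — valid because the joint is Gaussian).

For complete families the likelihood avoids the dense Kronecker build:
with 2Φ = U diag(d) Uᵀ, rotating the family's phenotype block by Uᵀ
makes rows independent with covariance d_i Σ_A + Σ_E, and the
generalized eigendecomposition Σ_A = Σ_E^{1/2} Q diag(w) Qᵀ Σ_E^{1/2}
reduces each evaluation to elementwise operations on an
(n_total × 2T) array.  All complete families are pre-rotated once per
fit, so one likelihood evaluation over ~1000 individuals costs well
under a millisecond; incomplete families fall back to the dense path.
Both paths agree to machine precision (tested).

**Fitting.**  L-BFGS-B on an unconstrained scale: log variances,
atanh(β), log-diagonal Cholesky factors for the LG 2×2 blocks.
Multi-start (a pooled method-of-moments start plus jittered copies)
guards against local optima.  Standard errors come from the numerical
observed information with a delta-method map back to the natural scale.

## 4. Medication adjustment (censored regression)

Treated blood-pressure readings understate the underlying trait.  Each
visit/trait is modeled as right-censored: for untreated observations
the usual normal density applies; for treated ones only
Pr(Y* > y_obs) enters the likelihood,

    ℓ(β, σ) = Σ_untreated log φ((y − xβ)/σ)/σ
            + Σ_treated  log Φ̄((y − xβ)/σ)

maximized by quasi-Newton with an analytic gradient (the inverse Mills
ratio uses its asymptotic expansion for extreme arguments).  Treated
values are replaced by the conditional mean

    E[Y* | Y* > y_obs] = xβ̂ + σ̂ λ((y_obs − xβ̂)/σ̂)

and all values residualized on intercept, age, sex and smoking,
producing the rSBP/rDBP inputs per visit.  With no treated
observations the procedure reduces exactly to OLS residualization.

*Design note.*  The estimator is the exact MLE when treatment
right-censors at an (approximately) independent level.  When treatment
instead subtracts a fixed effect (observed = true − effect), the
pseudo-likelihood is misspecified: the truncated-normal imputation
E[Y*|Y* > y_obs] exceeds a fixed 12 mmHg shift by roughly 4–5 mmHg at
BP-like noise levels, so the adjustment removes most — not all — of the
treated-group gap.  Recovery studies therefore generate data under the
censoring mechanism (where unbiasedness is the correct expectation),
while the integration tests assert gap *reduction* under subtractive
treatment.  Estimating a common treatment-effect distribution would
remove the overshoot but requires pooling across visits and stronger
assumptions; it is deliberately out of scope.

## 5. Efficient-score association scan

Fitting both SEMs per SNP is infeasible genome-wide.  Instead one null
fit per model powers a score test for every SNP.  Writing ν for the
nuisance parameters and γ for the SNP path, γ enters only the mean
(∂V/∂γ = 0), so with per-family genotype vector g_f and the per-allele
direction c,

    U = Σ_f (g_f ⊗ c)ᵀ V_f⁻¹ r_f
    Var(U) = I_γγ − I_γν I_νν⁻¹ I_νγ

with expected information blocks; the statistic U²/Var(U) is χ²₁ under
the null.  Per family the SNP-independent pieces are cached once:
w = CᵀV⁻¹r, M = CᵀV⁻¹C and K = CᵀV⁻¹D (C places c per member, D holds
the nuisance mean derivatives), plus the full nuisance information
I_νν including the ½ tr(V⁻¹ ∂V V⁻¹ ∂V) covariance terms.  Moment
derivatives are central finite differences on the transformed scale.
Each SNP then costs three small quadratic forms.

Missing genotypes are mean-imputed (2 × allele frequency); SNPs that
are monomorphic or > 50% missing are skipped with explicit status
codes.  Genotypes are centered after imputation: the constant direction
coincides with the latent-mean derivative and carries zero efficient
information, so centering changes nothing statistically while making
allele-label flips (g → 2 − g) exact sign flips of U.

As a per-SNP oracle, `refit_chisq` re-fits the model with γ free
(warm-started at the null) and returns the likelihood-ratio χ²; the
acceptance suite requires correlation > 0.99 with the score statistic.

Scan summaries include the genomic inflation factor
λ_GC = median(χ²)/0.45494, Q-Q coordinates/plots, suggestive hits
(default P < 10⁻⁵), and a cross-model comparison (Spearman correlation
of P values, overlap of suggestive hits).

## 6. Synthetic cohorts

The generator produces three-generation pedigrees (founder couple,
their children with unrelated spouses, grandchildren), re-drawn until
the family size falls in a configured range; the full-scale preset
uses 20 families of 27–107 members.  Genotypes are gene-dropped:
founders draw Hardy-Weinberg genotypes at each SNP's allele frequency
and each child inherits one allele per parent (exact for unlinked
loci).  Latent trajectories follow the chosen SEM exactly, with
polygenic vectors drawn from N(0, 2Φ ⊗ Σ_a) per family.  Observed
phenotypes add covariate effects (age, sex, smoking; ages by
generation), treatment (individuals inclined to treat with some
probability are treated at visits where true SBP exceeds a threshold;
the effect, clipped at 0, subtracts from SBP and half of it from DBP),
and per-visit missingness.  Writers emit LINKAGE pedigrees, phenotype
CSV, dosage TSV and a minimal GT-only VCF; a truth file records every
latent quantity for verification.

Known simplifications: no assortative mating, inbreeding, dominance,
shared-household environment, linkage disequilibrium between SNPs, or
age-dependent treatment uptake.  These are acceptable because the
generator's role is verification against known truth, not demographic
realism.

## 7. Problem sizes and runtime (single CPU)

* Null SEM fit, 20 families / ~1000 individuals / 3 visits: ~1 s.
* Score-cache build (per model): a few seconds; per-SNP test ~0.5 ms
  (a 5000-SNP dual-model scan runs in ~30 s end to end).
* Parameter-recovery study (100 full-scale replicates per model):
  ~3 min.
* Full test suite ~4 min; verification script ~2 min.
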