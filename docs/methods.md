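# Methods

## Model and test

The data for one SNP are `n` subjects with allele counts `x_i ∈ {0,1,2}`
(additive coding) and an `n × m` matrix `Y` of continuous traits, modelled
as `Y = x β' + ε` with `ε_i` zero-mean and correlated across traits.  Each
trait is tested marginally with the OLS slope test of
`Y_j ~ intercept + x`; `z_j` is the slope over its standard error (residual
df `n − 2`) and the two-sided p-value uses the exact `t_{n−2}` tail by
default, so the null marginal p-values are uniform under Gaussian errors.
(A `reference="normal"` option gives `p_j = 2Φ(−|z_j|)` instead; at n = 100
the χ²-combination of normal-reference p-values is visibly anti-conservative
— rejection ≈ 0.056 instead of 0.05 at the 0.05 level in our null
simulations — which is why the t reference is the default.)

The Fisher statistic `T = Σ −2 log p_j` has `E[T] = 2m` always, and
`Var(T) = 4m` only under independence.  For correlated traits,

    Var(T) = 4m + Σ_{j≠k} δ(ρ_jk),
    δ(ρ)   = cov(−2 log p_j, −2 log p_k)
           = 4 ∬ log{2Φ(−|z_j|)} log{2Φ(−|z_k|)} dF_ρ(z_j, z_k) − 4,

with `F_ρ` the bivariate standard Gaussian.  The global p-value is the
survival function at `T` of the gamma distribution matching these two
moments (equivalently a scaled χ²: shape `μ²/σ²`, scale `σ²/μ`).  For
`m = 1` this reduces *exactly* to the marginal p-value; with all
correlations zero it reduces to the χ²_{2m} test.

## Calibration of δ(ρ)

`delta_numeric` evaluates the double integral by nested adaptive
(QUADPACK) quadrature: conditioning on `z_j`, the inner integral averages
over `z_k = ρ z_j + √(1−ρ²) u` with a breakpoint where the argument of
`|·|` changes sign; the outer integral uses the even symmetry in `z_j`.
The domain is truncated to `|z| ≤ 8.5`, where the Gaussian weight bounds
the tail contribution below 1e-13; inner/outer absolute tolerances are
`tol·1e-3` and `tol·0.05` (default `tol = 1e-6`).  The values are stable to
<1e-12 under tolerance tightening and domain widening, and agree with a
10⁷-draw Monte-Carlo estimate within its standard error.

`fit_delta_polynomial` fits `f(ρ) = c₁ρ² + … + c₅ρ¹⁰` by plain least
squares on the grid `ρ = −0.99(0.01)0.99` (199 points, zero intercept).
The refit leading coefficient is `c₁ = 3.9091`.  The shipped default
coefficients are the package's fixed reference calibration
`(3.9081, 0.0313, 0.1022, −0.1378, 0.0941)`, kept constant so results are
bit-stable across quadrature backends; `fc_test(..., poly=...)` and the
`calibrate` CLI switch to refit coefficients.

**Known limitation.** The five-term even polynomial cannot represent the
steep approach of δ(ρ) to its analytic limit 4 at |ρ| → 1 better than
≈ 3.9e-4 (the maximum fit residual, attained at ρ = ±0.99; about 1e-4 of
the local δ value).  Reaching a 1e-4 absolute residual would need two more
even terms.  The error is immaterial in practice: it enters σ² once per
trait pair and only for near-duplicate traits.

## Correlation estimation

Trait correlations are estimated from the raw phenotype columns — not from
per-SNP residuals — because under the null the correlation of `(z_j, z_k)`
for a shared regressor equals the trait correlation; this is also what
makes a scan cheap (one estimate per trait set, reused for every SNP).
Two estimators are offered: Pearson product-moment (`fc-pearson`), and
Kendall's tie-adjusted τ-b mapped through `ρ = sin(πτ/2)` (`fc-kendall`),
the robust choice for long-tailed traits.  Each pairwise estimate gets the
small-sample correction `ρ̂(1 + (1−ρ̂²)/(2(n−3)))`, clamped to [−1, 1]
(the raw correction can exceed 1 near |ρ̂| = 1 at small n — hence the
`n ≥ 4` requirement), and `f(r̂)` gets the leading-order plug-in bias
removal `−(c₁/n)(1−r̂²)²`.  `Var(T)` is floored at 1e-8: at tiny n with
near-zero correlations the bias terms can drive the sum slightly negative.
Missing phenotype values are rejected (complete-case filtering in the
reader), never imputed; Eq.-level `n` is the complete-case count.

## Comparison methods

All baselines share the signature `fn(Y, x, **options) -> p`:

* **MANOVA** — one-way, genotype as a categorical factor (observed levels
  only), Wilks' Λ with Rao's F approximation; exact for two groups or one
  trait.  Cross-checked against statsmodels to 1e-8.
* **PCA** — first principal component of the trait correlation matrix,
  scores regressed on `x` with the same marginal engine.
* **GEE** — stacked long format, identity link, trait-specific intercepts,
  one shared genotype slope, exchangeable working correlation clustered by
  subject, robust sandwich variance, normal-reference Wald test.
  Implemented directly in numpy for speed (the simulation calls it 10⁴+
  times); it reproduces statsmodels' GEE to 1e-14.  Note: this correctly
  specified GEE *controls* the type-I error (≈ 0.05–0.06 across ϱ in our
  simulations); claims of GEE type-I inflation in this setting arise from
  naive (non-sandwich) variance estimation under a working-independence
  fit, which this package deliberately does not reproduce.
* **TATES** — marginal p-values sorted ascending;
  `global p = min_j m_e p_(j) / j_e` with effective test counts from the
  Li–Ji eigenvalue rule `Σ [1{λ≥1} + (λ − ⌊λ⌋)]`.  The rule is applied to
  the correlation matrix of the *p-values*, obtained by mapping each trait
  correlation through `corr(p_j, p_k) = 12(E[p_j p_k] − 1/4)`, computed by
  the same quadrature machinery and approximated by an even polynomial
  (max residual ≈ 1.3e-3 on the grid).  Applying the rule to the trait
  correlations directly (available via a flag) is anti-conservative: null
  rejection ≈ 0.076 at ϱ = 0.75 versus ≈ 0.05 for the mapped version.
  On realistic inputs TATES is never less significant than plain Simes;
  adversarial rank-one correlation structures can break that dominance,
  which is inherent to the eigenvalue rule.
* **FC-χ²_{2m}** — Fisher statistic with the independence null; shipped as
  the cautionary baseline (rejection grows to ≈ 0.13 at ϱ = 0.75 under the
  null).
* **FC-permutation** — permutes `x` uniformly B times (vectorised closed-form
  OLS recomputation), add-one estimator `(1 + #{T_b ≥ T_obs})/(B + 1)`;
  granularity 1/(B+1).

## Synthetic data and the power study

`simulate_genotype` draws `x ~ Binomial(2, maf)` (Hardy–Weinberg);
`simulate_phenotypes` draws `ε ~ MVN(0, Σ)` with compound-symmetric Σ
(unit variance, common off-diagonal ϱ, valid for ϱ > −1/(m−1)) and sets
`Y = xβ + ε` with zero intercepts.  The contaminated model multiplies each
subject's error vector by √5 with probability 0.10 (marginal variance 1.4),
emulating the long-tailed symptom-count-like traits of real studies.  Not
emulated: linkage disequilibrium between SNPs, family structure, covariates,
discrete/zero-inflated traits — so passing tests demonstrate calibration
and power under the stated Gaussian and contaminated-Gaussian conditions,
not robustness to those real-data features.

Default study conditions: n = 100, m = 5, MAF 0.25,
ϱ ∈ {0, 0.25, 0.5, 0.75}, effect vectors `(0,…,0)`, `(0.3,…,0.3)` and
`(0.1, 0.2, 0.3, 0.4, 0.5)`, α = 0.05, B = 1000 permutations, R = 10,000
replicates.  Each replicate gets its own seed stream spawned from the root
seed (`SeedSequence.spawn`), so every method sees identical data, runs are
bit-reproducible, and scaled-down runs are prefixes of larger ones in
distribution.  Monomorphic genotype draws are redrawn and counted
(vanishingly rare at n = 100, MAF 0.25).  Cells report the rejection
proportion and its Monte-Carlo SD `√(p̂(1−p̂)/R)`; a cell with >1 %
per-replicate failures is flagged invalid.  The acceptance tests run the
full R = 10,000 per cell (seconds per configuration); the permutation
comparison uses R = 1,000 and the qualitative pattern checks R = 2,000 —
sizes chosen to keep the whole suite desk-scale while leaving every
comparison inside its Monte-Carlo tolerance.

## Numerical choices and degenerate inputs

* Marginal p-values are floored at 1e-300 before logging (perfect-fit
  underflow); global p-values are clamped to (1e-300, 1].
* Monomorphic SNPs raise a degenerate-genotype error in the library and are
  skipped with a recorded reason in scans; constant trait columns raise a
  degenerate-phenotype error naming the column.
* δ at |ρ| = 1 is defined as the analytic limit 4; quadrature is excluded
  there.
* Kendall's τ uses the tie-adjusted τ-b variant (phenotype data contain
  ties).
* GEE iterates parameter/α updates to 1e-8 with a 60-iteration budget and
  clamps α inside the invertibility region of the exchangeable structure.
* The phenotype reader treats the first column as subject IDs when its
  values are not all numeric; empty/NA/NaN cells drop the row (logged);
  any other non-numeric cell is a parse error with its line number.

## File formats

Plain TSV throughout: phenotypes (header + optional ID column), genotypes
(one SNP per row, optional identifier, codes 0/1/2, streamed), scan output
('#' metadata header recording version, method, correlation method,
coefficient provenance and seed; p-values at 6 significant digits,
exact 1 as "1.0", underflow as "1e-300" plus a flag column).  VCF/PLINK
parsing, dosages, covariates and multiple-testing machinery beyond a fixed
significance threshold are out of scope.
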