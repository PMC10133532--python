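# Methods

## Model

For n unrelated individuals, r quantitative traits and p predictors
(standardized SNP dosages plus non-genetic covariates), `miht` fits the
multivariate Gaussian regression

    Y_{r×n} = B_{r×p} X_{p×n} + E,    vec(E) ~ N(0, I_n ⊗ Γ⁻¹),

maximizing, up to an additive constant, the loglikelihood

    L(B, Γ) = (n/2) log det Γ − (1/2) tr[Γ (Y − BX)(Y − BX)ᵀ]

subject to ‖B‖₀ ≤ k on the genetic block of B. Γ is the unstructured r×r
residual precision matrix; its inverse, normalized to unit diagonal, is the
residual trait correlation matrix. All SNPs enter one joint regression, so
each estimated effect is conditioned on every other SNP — this is what keeps
false positives from secondary LD associations low relative to
marker-by-marker methods.

## Algorithm (block ascent)

Each outer iteration:

1. **Gradient step in B** at fixed Γ. The gradient is C = Γ(Y − BX)Xᵀ and the
   step length t = ‖C‖_F² / tr(XᵀCᵀΓCX) is the exact maximizer of the
   (exactly quadratic) loglikelihood along B + tC. The denominator is
   evaluated as tr(Γ·D Dᵀ) with D = CX, so no n×n product is ever formed.
2. **Projection.** B + tC is projected onto {‖B‖₀ ≤ k} by keeping the k
   largest-magnitude entries of the vectorized matrix — jointly across
   traits, not per trait. Standardizing predictors and traits beforehand is
   what makes cross-trait magnitude comparison meaningful. Covariate columns
   (intercept, sex, age, PCs, …) are exempt from projection and do not count
   toward k.
3. **Backtracking.** The step is exact for the unprojected update, but
   projection can undo part of the gain, so if the projected candidate
   lowers L (at the current Γ) the step is halved and re-projected, up to 10
   times; if all candidates fail, the best one is accepted and the iteration
   flagged. Accepted iterations therefore never decrease L.
4. **Exact Γ update.** Γ ← [(1/n)(Y − BX)(Y − BX)ᵀ]⁻¹, the closed-form
   stationary point of L in Γ, which can only increase L. A 1e-10·I jitter is
   added only if the Cholesky of the residual covariance fails (logged);
   a still-singular covariance is a hard error suggesting fewer traits.

Initialization is B = 0, Γ = I (deterministic, matches the sparse prior).
Iteration stops when |ΔL| < tol·(|L| + 1) with tol = 1e-6, or at
max_iter = 200 (both configurable). Ties in the top-k are broken by lowest
linear index so results are platform-independent.

Degenerate inputs: a monomorphic variant (sd = 0) is a hard error naming the
variant; a zero gradient is treated as convergence, not an error.

## Packed genotype linear algebra

Genotypes stay in the 2-bit PLINK encoding (00→0, 10→1, 11→2, 01→missing,
little-endian within each byte) and the .bed payload is memory-mapped. All
products with the standardized genotype matrix Z run tile-by-tile (default
256 variants × 1024 samples, any tile size gives identical results): a tile
of bytes is expanded through a 256×4 lookup table, standardized using cached
per-variant statistics, multiplied by BLAS, and accumulated. Missing
genotypes are imputed on the fly to the variant mean, i.e. exactly 0 after
centering. Standardization uses the empirical sd with the n−1 denominator
over non-missing entries; the HWE-based sd √(2·maf·(1−maf)) is a known
alternative and would only rescale the coefficients. When n·p ≤ 4·10⁷
entries the standardized matrix is additionally cached densely once — a pure
speed choice (the cached path computes the identical Z through the same
statistics) that keeps repeated cross-validation fits cheap at cohort sizes
where 8·n·p bytes fit comfortably in memory.

LD pruning is a greedy left-to-right scan: a variant is kept iff its
absolute Pearson correlation with every previously kept variant inside a
trailing window (default 50 SNPs) is at or below the threshold. Kept sets
may differ from PLINK's `--indep-pairwise`. A monomorphic variant has
undefined correlation; we treat it as 0 and keep the variant.

## Cross-validation of k

k is the only tuned hyperparameter. q-fold CV (default q = 5) scores each
candidate k by held-out mean squared prediction error averaged over all
(trait, sample) cells of the standardized trait matrix, then a two-stage
grid zooms in: coarse k ∈ {5, 10, …, 50}, refinement over
{k_best − 4, …, k_best + 4} clamped to k ≥ 1, same folds in both stages; the
reported k_best is the argmin over the merged grid (ties to the smaller k).
Genotype, covariate, and trait standardization are computed on the training
folds only and applied to the held-out samples; `global_standardize=True`
restores single-pass global standardization instead. Inner CV fits use a
relaxed tolerance (tol 1e-4, max 100 iterations): model selection only needs
the MSE ranking across k, and the final model is refit at full tolerance.
Folds are independent computations; results are identical for any execution
order or worker count.

## Trait simulator

`simulate_dataset` emulates a GWAS cohort with correlated traits:

* **Genotypes** — per-variant maf ~ Uniform(0.05, 0.5) by default; each
  genotype is the sum of two Bernoulli(maf) alleles obtained by thresholding
  latent standard Gaussians; with `ld_rho > 0` the latents follow an AR(1)
  across adjacent variants, giving a closed-form adjacent-allele correlation
  used as the test oracle. This produces blocky, stationary LD — not the
  irregular haplotype structure of real panels — and no missing genotypes.
* **Effects** — k_plei variants hit two distinct random traits, k_indep hit
  one, so ‖B‖₀ = k_true = 2·k_plei + k_indep; magnitudes are uniform on
  {0.05, 0.10, …, 0.50} with random sign (a positive-only flag exists for
  strict parity with magnitude-only designs). Effects multiply the
  *standardized* genotypes, the same predictor scale the model fits.
* **Trait covariance** — Σ has Haar-random eigenvectors and eigenvalues
  drawn Uniform(0.1, 10), affinely shifted whenever needed so that
  cond(Σ) ≤ 10 holds on every draw.
* **Traits** — Y ~ MatrixNormal(B Z, Σ, σ_g²Φ + σ_e²I) sampled via two
  Cholesky factors, with Φ the centered GRM, Φ = (1/p)WᵀW for the
  variant-centered genotype matrix W, computed from the simulated genotypes
  themselves. Defaults σ_g² = 0.1, σ_e² = 0.9 put a 10% exchangeable
  polygenic-background component into the sample covariance — a structure
  that favors mixed-model analysis, making it a conservative test bed for a
  sparse fixed-effect method.

Everything is reproducible bit-for-bit given (seed, parameters); sub-seeds
for the genotype/effect/covariance/trait draws are spawned from the one seed.

Because Σ's diagonal is not normalized, a nominal effect of size b on trait
i has effective standardized size b/√Σ_ii once traits are standardized for
fitting — down to ≈ 0.3·b when Σ_ii ≈ 10. Detection of such diluted effects
at n = 1000 against ~10⁴ competing coefficients is near the information
limit, which is worth keeping in mind when reading recovery rates from the
benchmark harness (power on independent variants sits in the 0.75–0.85 range
rather than near 1, mirroring published multivariate-GWAS simulation
studies). Passing tests on this simulator show correct algebra and sensible
statistical behavior under matrix-normal assumptions; they do not certify
performance on real cohorts with fine-scale LD, rare variants, non-Gaussian
traits, or cryptic relatedness.

## Evaluation conventions

Power is scored at entry level by default — each true (snp, trait) pair
counts separately, so a pleiotropic variant found on one of its two traits
contributes 0.5 — with a SNP-level alternative that grants full credit once
any entry of a variant is recovered. False positives are non-zero estimates
at positions with zero truth; nearby-in-LD selections are *not* forgiven
(pruning the input is the supported way to study LD effects). Variance
explained per trait is Var(b̂_i Z)/Var(y_i); trait correlations come from
normalizing Γ⁻¹ to unit diagonal.

## Benchmark harness sizes

The bundled recovery study runs the two-trait configuration (k_plei = 3,
k_indep = 4, k_true = 10) at n = 1000, p = 5000 with linkage-equilibrium
genotypes, effect magnitudes restricted to ≥ 0.3, over 20 seeded replicates,
with 5-fold two-stage CV — sizes chosen so the full suite runs on a single
CPU in minutes while keeping per-replicate behavior representative of the
cohort-scale setting.

## Known limitations

* No p-values or standard errors; support + effect sizes only.
* Polygenic background and relatedness are not modeled (exclude close
  relatives; supply principal components as covariates).
* Gaussian traits only; log-transform skewed traits first (the CLI exposes
  `--log-transform`).
* The Γ update inverts an r×r matrix; fine for r ≤ a few hundred traits.
* Biallelic, SNP-major PLINK input only; no BGEN/VCF/dosage paths.
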