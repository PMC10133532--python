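"""Synthetic genotypes and matrix-normal quantitative traits.

The generator emulates the structure of a population-cohort GWAS panel:

* genotypes are sums of two Bernoulli(maf) alleles per variant, with an
  optional AR(1) latent-Gaussian correlation between adjacent variants to
  mimic local LD;
* a sparse r x p effect matrix B with ``k_plei`` pleiotropic variants (each
  hitting two distinct traits) and ``k_indep`` variants hitting one trait, so
  ||B||_0 = k_true = 2*k_plei + k_indep; non-zero magnitudes are drawn
  uniformly from the grid {0.05, 0.10, ..., 0.50} with random sign;
* a random r x r trait covariance Sigma conditioned so cond(Sigma) <= 10;
* traits drawn from the matrix normal

      Y ~ MatrixNormal(B Z,  Sigma,  sigma_g2 * Phi + sigma_e2 * I),

  where Z is the standardized genotype matrix, Phi the centered genetic
  relationship matrix computed from the simulated genotypes, and the default
  variance components are sigma_g2 = 0.1, sigma_e2 = 0.9.

All outputs are bit-for-bit reproducible given (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import PackedGenotypeMatrix, write_plink

__all__ = [
    "SET_PRESETS",
    "SimulationTruth",
    "simulate_genotypes",
    "centered_grm",
    "simulate_effects",
    "simulate_trait_covariance",
    "simulate_traits",
    "simulate_dataset",
    "allele_correlation",
    "EFFECT_GRID",
]

#: The 10-point grid of admissible effect magnitudes.
EFFECT_GRID = np.round(np.arange(1, 11) * 0.05, 2)

#: Benchmark parameter bundles: (r traits, k_indep, k_plei).
SET_PRESETS = {
    1: dict(r=2, k_indep=4, k_plei=3),
    2: dict(r=3, k_indep=10, k_plei=5),
    3: dict(r=5, k_indep=16, k_plei=7),
    4: dict(r=10, k_indep=4, k_plei=3),
    5: dict(r=50, k_indep=10, k_plei=5),
    6: dict(r=100, k_indep=16, k_plei=7),
}


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    B_true: np.ndarray  # r x p
    pleiotropic_snps: np.ndarray  # each affects exactly 2 traits
    independent_snps: np.ndarray  # each affects exactly 1 trait
    Sigma: np.ndarray | None = None  # r x r trait covariance
    Phi: np.ndarray | None = None  # n x n GRM
    sigma_g2: float = 0.1
    sigma_e2: float = 0.9
    seed: int | None = None
    config: dict = field(default_factory=dict)

    @property
    def k_true(self) -> int:
        return int(np.count_nonzero(self.B_true))

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.B_true)
        plei = set(self.pleiotropic_snps.tolist())
        return pd.DataFrame(
            {
                "snp": cols,
                "trait": rows,
                "effect": self.B_true[rows, cols],
                "class": ["plei" if j in plei else "indep" for j in cols],
            }
        ).sort_values(["snp", "trait"], kind="stable").reset_index(drop=True)


def simulate_genotypes(
    n: int,
    p: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.0,
    seed: int | None = None,
    out_prefix=None,
) -> PackedGenotypeMatrix:
    """Biallelic genotypes as sums of two Bernoulli(maf) alleles.

    Per-variant minor allele frequencies are Uniform(maf_range). With
    ``ld_rho > 0`` the latent Gaussians behind each haplotype follow an AR(1)
    across adjacent variants, inducing LD whose allele-level correlation is
    given by :func:`allele_correlation`. ``out_prefix`` optionally writes a
    .bed/.bim/.fam triplet.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    if not (0 <= ld_rho < 1):
        raise ValueError("ld_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=p)
    thresh = stats.norm.ppf(maf)
    codes = np.zeros((n, p), dtype=np.int8)
    for _hap in range(2):
        e = rng.standard_normal((n, p))
        u = np.empty_like(e)
        u[:, 0] = e[:, 0]
        w = np.sqrt(1.0 - ld_rho**2)
        for j in range(1, p):
            u[:, j] = ld_rho * u[:, j - 1] + w * e[:, j]
        codes += (u < thresh).astype(np.int8)
    G = PackedGenotypeMatrix.from_dense(codes.T)
    if out_prefix is not None:
        write_plink(out_prefix, G)
    return G


def allele_correlation(rho: float, maf_a: float, maf_b: float) -> float:
    """Correlation between adjacent alleles under the latent AR(1) model.

    corr(1{U1 < a}, 1{U2 < b}) for (U1, U2) standard bivariate normal with
    correlation ``rho`` and thresholds a, b at the allele frequencies.
    """
    a, b = stats.norm.ppf(maf_a), stats.norm.ppf(maf_b)
    joint = stats.multivariate_normal(
        mean=[0, 0], cov=[[1, rho], [rho, 1]]
    ).cdf([a, b])
    num = joint - maf_a * maf_b
    den = np.sqrt(maf_a * (1 - maf_a) * maf_b * (1 - maf_b))
    return float(num / den)


def centered_grm(G: PackedGenotypeMatrix | np.ndarray) -> np.ndarray:
    """Centered genetic relationship matrix Phi = (1/p) W W^T in sample space.

    W is the dense genotype matrix with each variant centered (not scaled).
    Symmetric PSD; rows sum to zero.
    """
    if isinstance(G, PackedGenotypeMatrix):
        codes = G.densify().astype(np.float64)
    else:
        codes = np.asarray(G, dtype=np.float64)
    p = codes.shape[0]
    if p < 2:
        raise ValueError("need at least 2 variants")
    W = codes - codes.mean(axis=1, keepdims=True)  # p x n, variant-centered
    Phi = (W.T @ W) / p
    return 0.5 * (Phi + Phi.T)


def simulate_effects(
    p: int,
    r: int,
    k_indep: int,
    k_plei: int,
    seed: int | None = None,
    *,
    magnitude_grid: np.ndarray = EFFECT_GRID,
    signed: bool = True,
) -> SimulationTruth:
    """Sparse effect matrix with controlled pleiotropy.

    ``k_plei`` variants each receive non-zero effects on two distinct traits;
    ``k_indep`` further variants receive one effect each (disjoint variant
    sets). Magnitudes are uniform on ``magnitude_grid``; signs are uniform
    +/- unless ``signed=False``.
    """
    k_true = 2 * k_plei + k_indep
    if k_plei < 0 or k_indep < 0:
        raise ValueError("k_plei and k_indep must be non-negative")
    if k_plei > 0 and r < 2:
        raise ValueError("pleiotropic effects need at least 2 traits")
    if k_plei + k_indep > p or k_true > r * p:
        raise ValueError(
            f"cannot place {k_plei} pleiotropic + {k_indep} independent "
            f"effects in a {r} x {p} matrix"
        )
    rng = np.random.default_rng(seed)
    snps = rng.choice(p, size=k_plei + k_indep, replace=False)
    plei, indep = snps[:k_plei], snps[k_plei:]
    B = np.zeros((r, p))

    def draw(size):
        mag = rng.choice(magnitude_grid, size=size)
        if signed:
            mag = mag * rng.choice([-1.0, 1.0], size=size)
        return mag

    for j in plei:
        traits = rng.choice(r, size=2, replace=False)
        B[traits, j] = draw(2)
    for j in indep:
        B[rng.integers(r), j] = draw(1)[0]
    return SimulationTruth(
        B_true=B,
        pleiotropic_snps=np.sort(plei),
        independent_snps=np.sort(indep),
        seed=seed,
        config=dict(p=p, r=r, k_indep=k_indep, k_plei=k_plei, signed=signed),
    )


def simulate_trait_covariance(
    r: int, max_condition: float = 10.0, seed: int | None = None
) -> np.ndarray:
    """Random SPD trait covariance with condition number <= ``max_condition``.

    Eigenvectors are Haar-random orthogonal; raw eigenvalues are drawn
    Uniform(0.1, 10) then shifted (affine squeeze) whenever their ratio
    exceeds the bound, so lambda_max / lambda_min <= max_condition on every
    draw.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if max_condition < 1:
        raise ValueError("max_condition must be >= 1")
    rng = np.random.default_rng(seed)
    lam = rng.uniform(0.1, 10.0, size=r)
    lo, hi = lam.min(), lam.max()
    if hi / lo > max_condition:
        # shift so the ratio equals the bound exactly
        s = (hi - max_condition * lo) / (max_condition - 1.0)
        lam = lam + s
    if r == 1:
        return np.array([[lam[0]]])
    Q = stats.ortho_group.rvs(r, random_state=rng)
    Sigma = (Q * lam) @ Q.T
    return 0.5 * (Sigma + Sigma.T)


def simulate_traits(
    truth: SimulationTruth,
    G: PackedGenotypeMatrix | np.ndarray,
    seed: int | None = None,
) -> np.ndarray:
    """Matrix-normal traits Y (r x n) given truth and genotypes.

    Y = B Z + A N L^T with A A^T = Sigma (row/trait covariance),
    L L^T = sigma_g2 * Phi + sigma_e2 * I (column/sample covariance) and N an
    r x n matrix of iid standard normals; Z is the standardized genotype
    matrix, so effects act on the same predictor scale the model fits.
    """
    if isinstance(G, PackedGenotypeMatrix):
        Z = G.standardized_variants(np.arange(G.n_variants))
        n = G.n_samples
    else:
        Z = np.asarray(G, dtype=np.float64)
        n = Z.shape[1]
    r = truth.B_true.shape[0]
    Sigma = truth.Sigma if truth.Sigma is not None else np.eye(r)
    try:
        A = np.linalg.cholesky(Sigma)
        if truth.Phi is not None and truth.sigma_g2 != 0:
            L = np.linalg.cholesky(
                truth.sigma_g2 * truth.Phi + truth.sigma_e2 * np.eye(n)
            )
        else:
            L = None  # column covariance is sigma_e2 * I; skip the n x n factor
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "row or column covariance is not positive definite"
        ) from exc
    rng = np.random.default_rng(seed)
    N = rng.standard_normal((r, n))
    noise = A @ N @ L.T if L is not None else np.sqrt(truth.sigma_e2) * (A @ N)
    return truth.B_true @ Z + noise


def simulate_dataset(
    n: int,
    p: int,
    r: int,
    k_indep: int,
    k_plei: int,
    *,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.0,
    sigma_g2: float = 0.1,
    sigma_e2: float = 0.9,
    magnitude_grid: np.ndarray = EFFECT_GRID,
    signed: bool = True,
    max_condition: float = 10.0,
    use_grm: bool = True,
    seed: int | None = None,
):
    """Full study replicate: genotypes, truth, and traits.

    Returns ``(G, Y, truth)`` with Y of shape (r, n). Sub-seeds for the
    genotype, effect, covariance, and trait draws are spawned deterministically
    from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_geno, s_eff, s_cov, s_trait = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    G = simulate_genotypes(n, p, maf_range, ld_rho, seed=s_geno)
    truth = simulate_effects(
        p, r, k_indep, k_plei, seed=s_eff,
        magnitude_grid=magnitude_grid, signed=signed,
    )
    truth.Sigma = simulate_trait_covariance(r, max_condition, seed=s_cov)
    truth.Phi = centered_grm(G) if use_grm else None
    truth.sigma_g2 = float(sigma_g2) if use_grm else 0.0
    truth.sigma_e2 = float(sigma_e2)
    truth.seed = seed
    truth.config.update(
        n=n, maf_range=maf_range, ld_rho=ld_rho,
        sigma_g2=truth.sigma_g2, sigma_e2=sigma_e2, seed=seed,
    )
    Y = simulate_traits(truth, G, seed=s_trait)
    return G, Y, truth
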