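"""Sparsity-constrained multivariate Gaussian regression by iterative hard thresholding.

The model: r quantitative traits Y (r x n) regressed jointly on p predictors
X (p x n, standardized genotypes plus non-genetic covariates) with an r x p
coefficient matrix B constrained to at most k non-zero entries and an
unstructured r x r precision matrix Gamma. Up to an additive constant the
loglikelihood of n independent samples is

    L(B, Gamma) = (n/2) log det Gamma - (1/2) tr[Gamma (Y - BX)(Y - BX)^T].

Fitting alternates (block ascent):

1. a projected gradient ascent step in B at fixed Gamma — gradient
   C = Gamma (Y - BX) X^T, exact step size t = ||C||_F^2 / tr(X^T C^T Gamma C X)
   (the maximizer of the quadratic L along B + tC), then projection of B + tC
   onto the sparsity set {B : ||B||_0 <= k} by keeping the k largest entries in
   magnitude of vec(B); covariate columns are exempt from projection;
2. an exact update of Gamma at fixed B: the inverse of the empirical residual
   covariance (1/n)(Y - BX)(Y - BX)^T, which zeroes the Gamma-gradient
   (n/2) Gamma^{-1} - (1/2)(Y - BX)(Y - BX)^T.

Because projection can undo part of the gradient gain, the step is guarded by
step-halving backtracking so accepted iterations never decrease L.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DefinitenessError, SingularResidualError
from .genotype_io import PackedGenotypeMatrix, standardized_matmul

__all__ = [
    "ModelState",
    "DesignSpec",
    "loglikelihood",
    "gradient_B",
    "gradient_Gamma",
    "step_size",
    "project_sparse",
    "update_precision",
    "iht_step",
    "fit_miht",
    "MultivariateIHT",
]

logger = logging.getLogger(__name__)

#: Densify the standardized genotype block when n * p is at most this many
#: entries; above it every product runs through the tiled packed kernel.
DENSE_CACHE_MAX_ENTRIES = 40_000_000


# --------------------------------------------------------------------- types
@dataclass
class ModelState:
    """Fit state: coefficients, precision, and iteration diagnostics."""

    B: np.ndarray  # r x p_total
    Gamma: np.ndarray  # r x r
    loglik: float
    n_iter: int = 0
    step_t: float = 0.0
    backtracks: int = 0
    converged: bool = False
    history: list[float] = field(default_factory=list)
    #: iterations where backtracking was exhausted and the best (possibly
    #: loglik-decreasing) candidate was accepted
    forced_steps: list[int] = field(default_factory=list)


class DesignSpec:
    """Joint design: genotype block (projected) + covariate block (exempt).

    Parameters
    ----------
    genotypes
        A :class:`PackedGenotypeMatrix`, or a dense array of shape
        (n_samples, p) holding raw predictor values (standardized internally
        unless ``standardize_genotypes=False``).
    Y
        Trait matrix, r x n (one trait per row). A 1-D array is treated as a
        single trait.
    covariates
        Optional dense (n_samples, c) array of non-genetic predictors; they
        are standardized (the added intercept column is not) and are never
        zeroed by the sparsity projection.
    standardize_traits
        Center/scale each trait row to mean 0, variance 1 (ddof=1).
    """

    def __init__(
        self,
        genotypes,
        Y: np.ndarray,
        covariates: np.ndarray | None = None,
        *,
        add_intercept: bool = True,
        standardize_traits: bool = True,
        standardize_genotypes: bool = True,
        dense_cache: bool | str = "auto",
        tile: tuple[int, int] = (256, 1024),
    ) -> None:
        Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
        self.n = Y.shape[1]
        self.r = Y.shape[0]
        self.tile = tile

        # genotype block, internally p x n
        self._packed: PackedGenotypeMatrix | None = None
        self._Z: np.ndarray | None = None
        if isinstance(genotypes, PackedGenotypeMatrix):
            if genotypes.n_samples != self.n:
                raise ValueError(
                    f"genotypes have {genotypes.n_samples} samples, traits have {self.n}"
                )
            self._packed = genotypes
            self.p = genotypes.n_variants
            genotypes._check_polymorphic(np.arange(self.p))
            use_cache = dense_cache is True or (
                dense_cache == "auto"
                and self.n * self.p <= DENSE_CACHE_MAX_ENTRIES
            )
            if use_cache:
                self._Z = genotypes.standardized_variants(np.arange(self.p))
            self.x_mean = genotypes.col_stats.mean.copy()
            self.x_scale = genotypes.col_stats.sd.copy()
        else:
            Xg = np.asarray(genotypes, dtype=np.float64)
            if Xg.ndim != 2 or Xg.shape[0] != self.n:
                raise ValueError(
                    f"dense genotypes must be (n_samples={self.n}, p); got {Xg.shape}"
                )
            self.p = Xg.shape[1]
            if standardize_genotypes:
                self.x_mean = Xg.mean(axis=0)
                self.x_scale = Xg.std(axis=0, ddof=1)
                if np.any(self.x_scale == 0):
                    bad = np.flatnonzero(self.x_scale == 0)[:5].tolist()
                    raise ValueError(
                        f"predictor column(s) {bad} have zero variance"
                    )
                self._Z = ((Xg - self.x_mean) / self.x_scale).T
            else:
                self.x_mean = np.zeros(self.p)
                self.x_scale = np.ones(self.p)
                self._Z = Xg.T.copy()

        # covariate block, c x n, intercept first
        blocks = []
        self.has_intercept = bool(add_intercept)
        self.cov_mean = np.zeros(0)
        self.cov_scale = np.ones(0)
        if add_intercept:
            blocks.append(np.ones((1, self.n)))
        if covariates is not None:
            C = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
            if C.shape[0] != self.n:
                C = C.T
            if C.shape[0] != self.n:
                raise ValueError("covariates must have one row per sample")
            self.cov_mean = C.mean(axis=0)
            self.cov_scale = C.std(axis=0, ddof=1)
            self.cov_scale[self.cov_scale == 0] = 1.0
            blocks.append(((C - self.cov_mean) / self.cov_scale).T)
        self.C = (
            np.concatenate(blocks, axis=0) if blocks else np.zeros((0, self.n))
        )
        self.n_covariates = self.C.shape[0]
        self.p_total = self.p + self.n_covariates

        #: columns of B never zeroed by projection (the covariate block)
        self.exempt = np.zeros(self.p_total, dtype=bool)
        self.exempt[self.p :] = True

        self.y_mean = np.zeros(self.r)
        self.y_scale = np.ones(self.r)
        if standardize_traits:
            self.y_mean = Y.mean(axis=1)
            self.y_scale = Y.std(axis=1, ddof=1)
            if np.any(self.y_scale == 0):
                raise ValueError("a trait has zero variance; cannot standardize")
            Y = (Y - self.y_mean[:, None]) / self.y_scale[:, None]
        self.Y = Y

    # ------------------------------------------------------------- products
    def linear_map(self, B: np.ndarray, sparse_hint: bool = True) -> np.ndarray:
        """B X for an r x p_total matrix B; exploits column sparsity of B."""
        Bg, Bc = B[:, : self.p], B[:, self.p :]
        out = Bc @ self.C if self.n_covariates else np.zeros((B.shape[0], self.n))
        cols = np.flatnonzero(np.any(Bg != 0, axis=0))
        if cols.size == 0:
            return out
        if self._Z is not None:
            if sparse_hint and cols.size < self.p // 4:
                out += Bg[:, cols] @ self._Z[cols]
            else:
                out += Bg @ self._Z
        elif sparse_hint and cols.size < self.p // 4:
            out += Bg[:, cols] @ self._packed.standardized_variants(cols)
        else:
            out += standardized_matmul(
                self._packed, Bg.T, transpose_G=True, tile=self.tile
            ).T
        return out

    def grad_contract(self, S: np.ndarray) -> np.ndarray:
        """S X^T for an r x n matrix S; returns r x p_total."""
        if self._Z is not None:
            Gg = S @ self._Z.T
        else:
            Gg = standardized_matmul(
                self._packed, S.T, transpose_G=False, tile=self.tile
            ).T
        if self.n_covariates:
            return np.concatenate([Gg, S @ self.C.T], axis=1)
        return Gg


# ------------------------------------------------------------ core operations
def _chol_logdet(Gamma: np.ndarray):
    """Cholesky factor and log-determinant; raises DefinitenessError."""
    Gamma = np.asarray(Gamma, dtype=np.float64)
    if not np.allclose(Gamma, Gamma.T, atol=1e-10):
        raise DefinitenessError("precision matrix is not symmetric")
    try:
        Lc = np.linalg.cholesky(Gamma)
    except np.linalg.LinAlgError as exc:
        raise DefinitenessError(
            "precision matrix is not positive definite"
        ) from exc
    return Lc, 2.0 * np.log(np.diag(Lc)).sum()


def _loglik_resid(R: np.ndarray, Gamma: np.ndarray, n: int) -> float:
    _, logdet = _chol_logdet(Gamma)
    return 0.5 * n * logdet - 0.5 * float(np.sum((Gamma @ R) * R))


def loglikelihood(
    Y: np.ndarray, X: np.ndarray, B: np.ndarray, Gamma: np.ndarray
) -> float:
    """(n/2) log det Gamma - (1/2) tr[Gamma (Y-BX)(Y-BX)^T], constant dropped."""
    Y, X, B = (np.asarray(a, dtype=np.float64) for a in (Y, X, B))
    R = Y - B @ X
    return _loglik_resid(R, Gamma, Y.shape[1])


def gradient_B(
    Y: np.ndarray, X: np.ndarray, B: np.ndarray, Gamma: np.ndarray
) -> np.ndarray:
    """Gradient of the loglikelihood in B: Gamma (Y - BX) X^T."""
    R = Y - B @ X
    return Gamma @ R @ X.T


def gradient_Gamma(
    Y: np.ndarray, X: np.ndarray, B: np.ndarray, Gamma: np.ndarray
) -> np.ndarray:
    """Gradient in Gamma: (n/2) Gamma^{-1} - (1/2)(Y-BX)(Y-BX)^T (diagnostic)."""
    _chol_logdet(Gamma)
    R = Y - B @ X
    n = Y.shape[1]
    return 0.5 * n * np.linalg.inv(Gamma) - 0.5 * (R @ R.T)


def step_size(C: np.ndarray, X: np.ndarray, Gamma: np.ndarray) -> float:
    """Exact maximizing step along the gradient: ||C||_F^2 / tr(X^T C^T Gamma C X).

    Returns 0.0 for a zero gradient (convergence signal). The denominator is
    evaluated as tr(Gamma D D^T) with D = CX, never forming an n x n product.
    """
    num = float(np.sum(C * C))
    if num == 0.0:
        return 0.0
    D = C @ X
    den = float(np.sum((Gamma @ D) * D))
    if den <= 0.0:
        raise FloatingPointError(
            "non-positive curvature in the step-size denominator"
        )
    return num / den


def project_sparse(
    B: np.ndarray, k: int, exempt: np.ndarray | None = None
) -> np.ndarray:
    """Keep the k largest-magnitude entries of vec(B); zero the rest.

    The top-k is joint over the whole matrix, not per trait. Columns flagged
    in ``exempt`` are never zeroed and do not count toward k. Ties are broken
    by lowest linear index (C order), so the result is deterministic. If k
    exceeds the number of non-exempt entries, B is returned unchanged with a
    warning.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    B = np.asarray(B, dtype=np.float64)
    out = B.copy()
    if exempt is None:
        exempt = np.zeros(B.shape[1], dtype=bool)
    free_cols = np.flatnonzero(~exempt)
    sub = B[:, free_cols]
    if k >= sub.size:
        if k > sub.size:
            warnings.warn(
                f"k={k} exceeds the {sub.size} penalized entries; no projection applied",
                stacklevel=2,
            )
        return out
    flat = np.abs(sub).ravel()
    order = np.argsort(-flat, kind="stable")  # stable => ties to lowest index
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    sub = sub * mask.reshape(sub.shape)
    out[:, free_cols] = sub
    return out


def update_precision(
    Y: np.ndarray, X: np.ndarray, B: np.ndarray, n: int | None = None
) -> np.ndarray:
    """Exact Gamma update: inverse of the empirical residual covariance.

    Gamma = [ (1/n)(Y-BX)(Y-BX)^T ]^{-1}; this zeroes the Gamma-gradient. A
    1e-10 * I jitter is added (with a logged warning) only if the Cholesky of
    the residual covariance fails; if it still fails, raises
    :class:`SingularResidualError`.
    """
    Y = np.asarray(Y, dtype=np.float64)
    R = Y - np.asarray(B) @ np.asarray(X)
    return _precision_from_resid(R, n if n is not None else Y.shape[1])


def _precision_from_resid(R: np.ndarray, n: int) -> np.ndarray:
    S = (R @ R.T) / n
    r = S.shape[0]
    try:
        cf = sla.cho_factor(S, lower=True)
    except np.linalg.LinAlgError:
        cf = None
    if cf is None:
        logger.warning(
            "residual covariance not positive definite; adding 1e-10 jitter"
        )
        try:
            cf = sla.cho_factor(S + 1e-10 * np.eye(r), lower=True)
        except (np.linalg.LinAlgError, sla.LinAlgError) as exc:
            raise SingularResidualError(
                "residual covariance is rank deficient; use fewer traits or "
                "add ridge jitter"
            ) from exc
    Gamma = sla.cho_solve(cf, np.eye(r))
    return 0.5 * (Gamma + Gamma.T)


# --------------------------------------------------------------- block ascent
def _iht_step_core(
    B: np.ndarray,
    Gamma: np.ndarray,
    loglik: float,
    design: DesignSpec,
    k: int,
    max_backtracks: int = 10,
):
    """One block-ascent iteration; returns (B, Gamma, loglik, R, diagnostics)."""
    Y, n = design.Y, design.n
    R = Y - design.linear_map(B)
    C = design.grad_contract(Gamma @ R)
    if not np.any(C):
        return B, Gamma, loglik, R, {"step_t": 0.0, "backtracks": 0, "forced": False, "converged": True}

    D = design.linear_map(C, sparse_hint=False)
    den = float(np.sum((Gamma @ D) * D))
    if den <= 0.0:
        raise FloatingPointError("non-positive curvature in step-size denominator")
    t = float(np.sum(C * C)) / den

    best = None
    accepted = None
    backtracks = 0
    for j in range(max_backtracks + 1):
        tj = t / (2**j)
        Bc = project_sparse(B + tj * C, k, design.exempt)
        Rc = Y - design.linear_map(Bc)
        Lc = _loglik_resid(Rc, Gamma, n)
        if best is None or Lc > best[2]:
            best = (Bc, tj, Lc, Rc)
        if Lc >= loglik:
            accepted = (Bc, tj, Lc, Rc)
            backtracks = j
            break
    forced = accepted is None
    if forced:
        warnings.warn(
            "backtracking exhausted; accepting best candidate despite a "
            "loglikelihood decrease",
            stacklevel=2,
        )
        accepted = best
        backtracks = max_backtracks
    Bn, tj, _, Rn = accepted
    Gn = _precision_from_resid(Rn, n)
    Ln = _loglik_resid(Rn, Gn, n)
    return Bn, Gn, Ln, Rn, {
        "step_t": tj,
        "backtracks": backtracks,
        "forced": forced,
        "converged": False,
    }


def iht_step(
    state: ModelState, design: DesignSpec, k: int, max_backtracks: int = 10
) -> ModelState:
    """Advance one block-ascent iteration from ``state``."""
    B, Gamma, L, _, diag = _iht_step_core(
        state.B, state.Gamma, state.loglik, design, k, max_backtracks
    )
    forced = list(state.forced_steps)
    if diag["forced"]:
        forced.append(state.n_iter + 1)
    return ModelState(
        B=B,
        Gamma=Gamma,
        loglik=L,
        n_iter=state.n_iter + (0 if diag["converged"] else 1),
        step_t=diag["step_t"],
        backtracks=diag["backtracks"],
        converged=diag["converged"],
        history=state.history + ([] if diag["converged"] else [L]),
        forced_steps=forced,
    )


def fit_miht(
    design: DesignSpec,
    k: int,
    *,
    tol: float = 1e-6,
    max_iter: int = 200,
    max_backtracks: int = 10,
) -> ModelState:
    """Fit the k-sparse multivariate model by block ascent from B=0, Gamma=I.

    Iterates until the relative loglikelihood change drops below
    ``tol * (|L| + 1)`` or ``max_iter`` is reached (a warning is issued if the
    latter stops the run first).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    r, p_total, n = design.r, design.p_total, design.n
    B = np.zeros((r, p_total))
    Gamma = np.eye(r)
    L = _loglik_resid(design.Y, Gamma, n)
    state = ModelState(B=B, Gamma=Gamma, loglik=L)
    for _ in range(max_iter):
        prev = state.loglik
        state = iht_step(state, design, k, max_backtracks)
        if state.converged:  # zero gradient
            return state
        if abs(state.loglik - prev) < tol * (abs(state.loglik) + 1.0):
            state.converged = True
            return state
    warnings.warn(
        f"IHT did not converge in {max_iter} iterations (|dL| tolerance {tol})",
        stacklevel=2,
    )
    return state


# ------------------------------------------------------------------ estimator
class MultivariateIHT(RegressorMixin, BaseEstimator):
    """Sparse multivariate-response regression estimator (scikit-learn API).

    Jointly regresses r traits on p predictors keeping at most ``k`` non-zero
    genetic coefficients overall, with an unstructured residual precision
    matrix estimated exactly at each iteration.

    Parameters
    ----------
    k : int
        Sparsity level: maximum non-zero entries in the coefficient matrix
        (covariates and the intercept are always retained and do not count).
    fit_intercept : bool
        Include an (exempt) intercept column.
    standardize_traits : bool
        Standardize each trait to mean 0 / variance 1 before fitting;
        predictions are returned on the original trait scale.
    dense_cache : {"auto", True, False}
        Whether packed genotypes may be densified once (standardized) for
        speed; "auto" densifies when n*p is small enough.

    Attributes
    ----------
    B_ : ndarray of shape (r, p)
        Sparse genetic coefficient matrix on the standardized-predictor,
        standardized-trait scale.
    covar_B_ : ndarray of shape (r, c)
        Coefficients of the intercept/covariate block.
    Gamma_ : ndarray of shape (r, r)
        Residual precision matrix.
    loglik_ : float
        Final loglikelihood (constant dropped).
    n_iter_ : int
        Block-ascent iterations used.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> X = rng.binomial(2, 0.3, size=(200, 50)).astype(float)
    >>> B = np.zeros((2, 50)); B[0, 3] = 1.0; B[1, 7] = -1.0
    >>> Y = (B @ ((X - X.mean(0)) / X.std(0, ddof=1)).T
    ...      + rng.normal(size=(2, 200)) * 0.1)
    >>> est = MultivariateIHT(k=2).fit(X, Y.T)
    >>> sorted(np.flatnonzero(np.any(est.B_ != 0, axis=0)).tolist())
    [3, 7]
    """

    def __init__(
        self,
        k: int = 10,
        *,
        fit_intercept: bool = True,
        standardize_traits: bool = True,
        tol: float = 1e-6,
        max_iter: int = 200,
        max_backtracks: int = 10,
        dense_cache: bool | str = "auto",
    ) -> None:
        self.k = k
        self.fit_intercept = fit_intercept
        self.standardize_traits = standardize_traits
        self.tol = tol
        self.max_iter = max_iter
        self.max_backtracks = max_backtracks
        self.dense_cache = dense_cache

    def fit(self, X, y, covariates: np.ndarray | None = None):
        """Fit on genotypes X ((n, p) array or PackedGenotypeMatrix) and traits y (n, r)."""
        y = np.asarray(y, dtype=np.float64)
        Y = y.T if y.ndim == 2 else y[None, :]
        design = DesignSpec(
            X,
            Y,
            covariates=covariates,
            add_intercept=self.fit_intercept,
            standardize_traits=self.standardize_traits,
            dense_cache=self.dense_cache,
        )
        state = fit_miht(
            design,
            self.k,
            tol=self.tol,
            max_iter=self.max_iter,
            max_backtracks=self.max_backtracks,
        )
        self.design_ = design
        self.state_ = state
        self.B_ = state.B[:, : design.p]
        self.covar_B_ = state.B[:, design.p :]
        self.Gamma_ = state.Gamma
        self.loglik_ = state.loglik
        self.n_iter_ = state.n_iter
        self.converged_ = state.converged
        self.n_features_in_ = design.p
        return self

    def _standardize_new(self, X) -> np.ndarray:
        """Standardized genotype rows (p x n) for new data, training scale."""
        d = self.design_
        if isinstance(X, PackedGenotypeMatrix):
            codes = X.densify().astype(np.float64)
            miss = codes == -1
            Z = (codes - d.x_mean[:, None]) / d.x_scale[:, None]
            Z[miss] = 0.0
            return Z
        Xd = np.asarray(X, dtype=np.float64)
        return ((Xd - d.x_mean) / d.x_scale).T

    def predict(self, X, covariates: np.ndarray | None = None) -> np.ndarray:
        """Predicted traits, (n, r), on the original trait scale."""
        d = self.design_
        Z = self._standardize_new(X)
        out = self.B_ @ Z
        if d.n_covariates:
            n_new = Z.shape[1]
            blocks = []
            if d.has_intercept:
                blocks.append(np.ones((1, n_new)))
            if d.cov_mean.size:
                if covariates is None:
                    raise ValueError(
                        "model was fit with covariates; pass them to predict"
                    )
                C = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
                if C.shape[0] == n_new and C.shape[1] == d.cov_mean.size:
                    C = C.T
                blocks.append(
                    (C - d.cov_mean[:, None]) / d.cov_scale[:, None]
                )
            out = out + self.covar_B_ @ np.concatenate(blocks, axis=0)
        out = out * d.y_scale[:, None] + d.y_mean[:, None]
        return out.T

    def selected_effects(self) -> "pd.DataFrame":
        """Long table of the non-zero genetic effects (variant, trait, effect)."""
        import pandas as pd

        rows, cols = np.nonzero(self.B_)
        meta = None
        if self.design_ is not None and self.design_._packed is not None:
            meta = self.design_._packed.variant_meta
        return pd.DataFrame(
            {
                "variant_index": cols,
                "variant_id": (
                    meta["id"].iloc[cols].to_numpy()
                    if meta is not None
                    else [f"x{j}" for j in cols]
                ),
                "chrom": meta["chrom"].iloc[cols].to_numpy() if meta is not None else 0,
                "pos": meta["pos"].iloc[cols].to_numpy() if meta is not None else 0,
                "trait": rows,
                "effect": self.B_[rows, cols],
            }
        ).sort_values(["variant_index", "trait"], kind="stable").reset_index(drop=True)
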