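"""Cross-validated tuning of the sparsity level k.

The only free hyperparameter of the sparse multivariate model is k, the
number of non-zero coefficients. It is chosen by q-fold cross-validation of
the held-out mean squared prediction error (MSE), averaged over every
(trait, sample) cell of the standardized trait matrix, with a two-stage grid:
a broad coarse scan (default k in {5, 10, ..., 50}) followed by a refinement
over {k_best - 4, ..., k_best + 4} clamped to k >= 1.

Standardization is computed on the training folds only and applied to the
held-out samples (set ``global_standardize=True`` to standardize once on the
full data instead). Inner fits use a relaxed convergence tolerance: model
selection needs the MSE ranking across k, not fully polished coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator

from .genotype_io import PackedGenotypeMatrix
from .model_core import DesignSpec, fit_miht

__all__ = [
    "CVResult",
    "assign_folds",
    "cv_mse",
    "tune_sparsity",
    "SparsityCV",
]

#: Relaxed inner-fit settings used for every cross-validation fit.
CV_TOL = 1e-4
CV_MAX_ITER = 100


@dataclass
class CVResult:
    """Held-out MSE per (fold, k) and the selected sparsity level."""

    grid: np.ndarray  # sorted k values
    mse: np.ndarray  # q x len(grid)
    k_best: int
    fold_assignment: np.ndarray
    seed: int

    @property
    def mean_mse(self) -> np.ndarray:
        return self.mse.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.mse.T,
            columns=[f"fold{f}_mse" for f in range(self.mse.shape[0])],
        )
        df.insert(0, "k", self.grid)
        df.insert(1, "mean_mse", self.mean_mse)
        return df


def assign_folds(n: int, q: int, seed: int) -> np.ndarray:
    """Uniform random partition of n samples into q folds of near-equal size.

    Fold sizes differ by at most 1; reproducible given ``seed``.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    if n < q:
        raise ValueError("need at least one sample per fold")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    folds[perm] = np.arange(n) % q
    return folds


def _subset_genotypes(G, idx: np.ndarray):
    if isinstance(G, PackedGenotypeMatrix):
        return G.take_samples(idx)
    return np.asarray(G)[idx]


def _standardize_rows(Y, mean, scale):
    return (Y - mean[:, None]) / scale[:, None]


def _fold_mse(
    G,
    Y,
    covariates,
    grid,
    train,
    test,
    *,
    global_standardize,
    tol,
    max_iter,
    dense_cache,
):
    """Held-out MSE for one fold at every k in the grid."""
    r = Y.shape[0]
    if len(test) <= r:
        raise ValueError(
            f"held-out fold has {len(test)} samples but there are {r} traits; "
            "use fewer folds"
        )
    cov_tr = covariates[train] if covariates is not None else None
    design = DesignSpec(
        _subset_genotypes(G, train),
        Y[:, train],
        covariates=cov_tr,
        standardize_traits=not global_standardize,
        dense_cache=dense_cache,
    )
    # held-out standardized genotypes on the *training* scale
    if isinstance(G, PackedGenotypeMatrix):
        codes = G.take_samples(test).densify().astype(np.float64)
        miss = codes == -1
        Z_test = _standardize_rows(codes, design.x_mean, design.x_scale)
        Z_test[miss] = 0.0
    else:
        Z_test = _standardize_rows(
            np.asarray(G, dtype=np.float64)[test].T, design.x_mean, design.x_scale
        )
    Y_test = _standardize_rows(Y[:, test], design.y_mean, design.y_scale)
    blocks = [np.ones((1, len(test)))]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=np.float64))[test].T
        blocks.append(_standardize_rows(C, design.cov_mean, design.cov_scale))
    C_test = np.concatenate(blocks, axis=0)

    out = np.empty(len(grid))
    for i, k in enumerate(grid):
        state = fit_miht(design, int(k), tol=tol, max_iter=max_iter)
        Bg = state.B[:, : design.p]
        Bc = state.B[:, design.p :]
        Y_hat = Bg @ Z_test + Bc @ C_test
        out[i] = float(np.mean((Y_test - Y_hat) ** 2))
    return out


def cv_mse(
    G,
    Y: np.ndarray,
    grid,
    q: int = 5,
    seed: int = 0,
    *,
    covariates: np.ndarray | None = None,
    fold_assignment: np.ndarray | None = None,
    global_standardize: bool = False,
    tol: float = CV_TOL,
    max_iter: int = CV_MAX_ITER,
    dense_cache: bool | str = "auto",
    n_jobs: int = 1,
) -> CVResult:
    """q-fold cross-validated held-out MSE over a grid of sparsity levels.

    Parameters
    ----------
    G
        Genotypes: :class:`PackedGenotypeMatrix` or (n, p) dense array.
    Y
        Trait matrix, r x n (one trait per row; 1-D treated as one trait).
    grid
        Candidate k values.
    q, seed
        Fold count and fold-assignment seed.

    Folds are independent computations; results do not depend on execution
    order or on ``n_jobs``. If traits are standardized globally beforehand,
    pass ``global_standardize=True`` to skip per-fold trait scaling.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    n = Y.shape[1]
    grid = np.array(sorted(int(k) for k in grid))
    if grid.size == 0:
        raise ValueError("grid is empty")
    if fold_assignment is None:
        fold_assignment = assign_folds(n, q, seed)
    q = int(fold_assignment.max()) + 1
    splits = [
        (np.flatnonzero(fold_assignment != f), np.flatnonzero(fold_assignment == f))
        for f in range(q)
    ]
    rows = Parallel(n_jobs=n_jobs)(
        delayed(_fold_mse)(
            G,
            Y,
            covariates,
            grid,
            train,
            test,
            global_standardize=global_standardize,
            tol=tol,
            max_iter=max_iter,
            dense_cache=dense_cache,
        )
        for train, test in splits
    )
    mse = np.vstack(rows)
    mean = mse.mean(axis=0)
    k_best = int(grid[int(np.argmin(mean))])  # ties -> smallest k
    return CVResult(
        grid=grid, mse=mse, k_best=k_best, fold_assignment=fold_assignment, seed=seed
    )


def tune_sparsity(
    G,
    Y: np.ndarray,
    coarse_grid=range(5, 55, 5),
    q: int = 5,
    seed: int = 0,
    **kwargs,
) -> CVResult:
    """Two-stage sparsity search: coarse scan, then refine around the winner.

    Stage 1 evaluates ``coarse_grid``; stage 2 evaluates
    {k_best - 4, ..., k_best + 4} clamped to k >= 1, on the same folds. The
    returned :class:`CVResult` merges both stages (the final ``k_best`` is the
    argmin of mean MSE over the union grid).
    """
    coarse = sorted(int(k) for k in coarse_grid)
    if not coarse or any(b <= a for a, b in zip(coarse, coarse[1:])):
        raise ValueError("coarse_grid must be non-empty and strictly increasing")
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    folds = assign_folds(Y.shape[1], q, seed)
    stage1 = cv_mse(G, Y, coarse, seed=seed, fold_assignment=folds, **kwargs)
    refine = [
        k
        for k in range(stage1.k_best - 4, stage1.k_best + 5)
        if k >= 1 and k not in set(coarse)
    ]
    if not refine:
        return stage1
    stage2 = cv_mse(G, Y, refine, seed=seed, fold_assignment=folds, **kwargs)
    grid = np.concatenate([stage1.grid, stage2.grid])
    order = np.argsort(grid)
    grid = grid[order]
    mse = np.concatenate([stage1.mse, stage2.mse], axis=1)[:, order]
    mean = mse.mean(axis=0)
    k_best = int(grid[int(np.argmin(mean))])
    return CVResult(grid=grid, mse=mse, k_best=k_best, fold_assignment=folds, seed=seed)


class SparsityCV(BaseEstimator):
    """Model-selection estimator: two-stage CV over k, then a final refit.

    A scikit-learn-style wrapper around :func:`tune_sparsity` followed by a
    :class:`~miht.model_core.MultivariateIHT` fit at the selected k on the
    full data.

    Attributes
    ----------
    cv_result_ : CVResult
    k_best_ : int
    best_estimator_ : MultivariateIHT
    """

    def __init__(
        self,
        coarse_grid=tuple(range(5, 55, 5)),
        q: int = 5,
        seed: int = 0,
        *,
        global_standardize: bool = False,
        n_jobs: int = 1,
        dense_cache: bool | str = "auto",
    ) -> None:
        self.coarse_grid = coarse_grid
        self.q = q
        self.seed = seed
        self.global_standardize = global_standardize
        self.n_jobs = n_jobs
        self.dense_cache = dense_cache

    def fit(self, X, y, covariates: np.ndarray | None = None):
        from .model_core import MultivariateIHT

        y = np.asarray(y, dtype=np.float64)
        Y = y.T if y.ndim == 2 else y[None, :]
        self.cv_result_ = tune_sparsity(
            X,
            Y,
            coarse_grid=self.coarse_grid,
            q=self.q,
            seed=self.seed,
            covariates=covariates,
            global_standardize=self.global_standardize,
            n_jobs=self.n_jobs,
            dense_cache=self.dense_cache,
        )
        self.k_best_ = self.cv_result_.k_best
        self.best_estimator_ = MultivariateIHT(
            k=self.k_best_, dense_cache=self.dense_cache
        ).fit(X, y, covariates=covariates)
        return self

    def predict(self, X, covariates: np.ndarray | None = None):
        return self.best_estimator_.predict(X, covariates=covariates)
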