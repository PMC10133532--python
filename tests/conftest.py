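import numpy as np
import pytest

from miht import PackedGenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_codes(rng, p, n, missing_rate=0.0):
    """Dense int8 genotype codes (p variants x n samples), -1 = missing."""
    codes = rng.integers(0, 3, size=(p, n)).astype(np.int8)
    if missing_rate:
        codes[rng.random((p, n)) < missing_rate] = -1
    return codes


def random_packed(rng, p, n, missing_rate=0.0, polymorphic=True):
    """Random PackedGenotypeMatrix; resamples monomorphic variants if asked."""
    codes = random_codes(rng, p, n, missing_rate)
    if polymorphic:
        for j in range(p):
            nm = codes[j][codes[j] >= 0]
            while nm.size < 2 or np.all(nm == nm[0]):
                codes[j] = rng.integers(0, 3, size=n).astype(np.int8)
                nm = codes[j]
    return PackedGenotypeMatrix.from_dense(codes), codes


def dense_standardized(codes):
    """Oracle standardization: mean-impute missing, center, scale (ddof=1)."""
    X = codes.astype(float)
    Z = np.empty_like(X)
    for j in range(X.shape[0]):
        col = X[j]
        nm = col[codes[j] >= 0]
        mu, sd = nm.mean(), nm.std(ddof=1)
        z = (col - mu) / sd
        z[codes[j] < 0] = 0.0
        Z[j] = z
    return Z


@pytest.fixture
def small_design(rng):
    """Dense standardized toy design: Y (r x n), X (p x n), sparse true B."""
    r, p, n = 2, 30, 120
    X = rng.standard_normal((p, n))
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
    B = np.zeros((r, p))
    B[0, 2], B[0, 11], B[1, 5] = 1.2, -0.8, 0.9
    Y = B @ X + 0.3 * rng.standard_normal((r, n))
    return Y, X, B
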