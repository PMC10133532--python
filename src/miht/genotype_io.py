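"""PLINK binary genotype I/O and linear algebra on the packed 2-bit representation.

A binary PLINK fileset (.bed/.bim/.fam) stores one genotype in two bits, four
genotypes per byte, variant-major. This module memory-maps that payload and
performs standardized (mean-0, variance-1, mean-imputed) matrix products
directly on the packed bytes, decoding only small tiles at a time, so a
genome-sized matrix is never densified.

Bit convention (little-endian within a byte; lowest-order pair = first sample):

    00 -> 0 copies of the counted allele
    10 -> 1
    11 -> 2
    01 -> missing

so the byte 0b01110010 decodes to genotypes [1, 0, 2, missing]. Effect sizes
downstream refer to the allele coded 2 (the A1 dosage of the .bim file).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    MonomorphicVariantError,
    PlinkConsistencyError,
    PlinkFormatError,
)

__all__ = [
    "MISSING",
    "PackedGenotypeMatrix",
    "decode_block",
    "read_plink",
    "write_plink",
    "column_stats",
    "standardized_matmul",
    "ld_prune",
    "read_phenotypes",
]

MAGIC = bytes([0x6C, 0x1B])
SNP_MAJOR_MODE = 0x01

#: Sentinel for a missing genotype in decoded int8 arrays.
MISSING: int = -1

# bit-pair value -> genotype code (00->0, 01->missing, 10->1, 11->2)
_PAIR_TO_CODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
# genotype code -> bit-pair value; index by (code & 3) so MISSING=-1 maps via index 3...
# use an explicit dict-free mapping below instead.
_CODE_TO_PAIR = np.zeros(256, dtype=np.uint8)
_CODE_TO_PAIR[0] = 0b00
_CODE_TO_PAIR[1] = 0b10
_CODE_TO_PAIR[2] = 0b11
_CODE_TO_PAIR[MISSING & 0xFF] = 0b01  # -1 viewed as uint8 (255)

# byte value -> 4 genotype codes
_DECODE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _s in range(4):
        _DECODE_LUT[_b, _s] = _PAIR_TO_CODE[(_b >> (2 * _s)) & 0b11]
del _b, _s

_DEFAULT_TILE = (256, 1024)  # (variants, samples)


def decode_block(byte: int) -> np.ndarray:
    """Decode one packed byte into its four genotype codes.

    Returns an int8 array of length 4 in sample order (lowest-order bit pair
    first); missing genotypes are ``MISSING`` (-1).
    """
    return _DECODE_LUT[int(byte) & 0xFF].copy()


def _pack_codes(codes: np.ndarray) -> np.ndarray:
    """Pack an int8 code matrix (variants x samples) into PLINK bytes."""
    p, n = codes.shape
    n_pad = (-n) % 4
    if n_pad:
        codes = np.concatenate(
            [codes, np.zeros((p, n_pad), dtype=np.int8)], axis=1
        )
    pairs = _CODE_TO_PAIR[codes.view(np.uint8)]
    pairs = pairs.reshape(p, -1, 4)
    packed = (
        pairs[:, :, 0]
        | (pairs[:, :, 1] << 2)
        | (pairs[:, :, 2] << 4)
        | (pairs[:, :, 3] << 6)
    )
    return np.ascontiguousarray(packed, dtype=np.uint8)


@dataclass
class ColumnStats:
    """Per-variant genotype summaries over non-missing entries."""

    mean: np.ndarray  # NaN where all entries are missing
    sd: np.ndarray  # ddof=1; 0.0 where undefined
    missing_count: np.ndarray


@dataclass
class PackedGenotypeMatrix:
    """2-bit packed genotypes with variant/sample metadata.

    ``packed_bytes`` has shape (n_variants, ceil(n_samples/4)); each row holds
    one variant's samples in little-endian bit pairs, matching the on-disk
    SNP-major .bed layout so it can be a read-only memmap of the file.
    """

    packed_bytes: np.ndarray
    n_samples: int
    variant_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    _stats: ColumnStats | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        expected = self.bytes_per_variant
        if self.packed_bytes.ndim != 2 or self.packed_bytes.shape[1] != expected:
            raise PlinkConsistencyError(
                f"packed buffer has {self.packed_bytes.shape[1]} bytes per "
                f"variant; expected ceil({self.n_samples}/4) = {expected}"
            )

    # ------------------------------------------------------------------ shape
    @property
    def n_variants(self) -> int:
        return self.packed_bytes.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(n_variants, n_samples)."""
        return (self.n_variants, self.n_samples)

    @property
    def bytes_per_variant(self) -> int:
        return (self.n_samples + 3) // 4

    # ----------------------------------------------------------------- decode
    def decode_variants(
        self, idx: np.ndarray | slice, sample_slice: slice | None = None
    ) -> np.ndarray:
        """Decode the selected variants to an int8 matrix (variants x samples).

        Missing genotypes are ``MISSING``. ``sample_slice`` restricts the
        sample range (need not be byte aligned).
        """
        s0, s1 = (0, self.n_samples)
        if sample_slice is not None:
            s0, s1, step = sample_slice.indices(self.n_samples)
            if step != 1:
                raise ValueError("sample_slice must be contiguous")
        b0, b1 = s0 // 4, (s1 + 3) // 4
        chunk = self.packed_bytes[idx, b0:b1]
        codes = _DECODE_LUT[chunk].reshape(chunk.shape[0], -1)
        return codes[:, s0 - 4 * b0 : s0 - 4 * b0 + (s1 - s0)]

    def densify(self) -> np.ndarray:
        """Full int8 genotype matrix (n_variants x n_samples); test/small-data helper."""
        return self.decode_variants(slice(None))

    # ------------------------------------------------------------------ stats
    @property
    def col_stats(self) -> ColumnStats:
        """Lazily computed per-variant mean, sd (ddof=1) and missing count."""
        if self._stats is None:
            self._stats = column_stats(self)
        return self._stats

    def standardized_variants(self, idx: np.ndarray) -> np.ndarray:
        """Standardized rows (variants) as float64; missing entries become 0.

        Raises :class:`MonomorphicVariantError` if any requested variant has
        zero genotype variance.
        """
        idx = np.atleast_1d(np.asarray(idx))
        st = self.col_stats
        self._check_polymorphic(idx)
        codes = self.decode_variants(idx).astype(np.float64)
        miss = codes == MISSING
        z = (codes - st.mean[idx, None]) / st.sd[idx, None]
        z[miss] = 0.0
        return z

    def _check_polymorphic(self, idx: np.ndarray) -> None:
        sd = self.col_stats.sd[idx]
        if np.any(sd == 0):
            bad = np.asarray(idx)[sd == 0]
            names = self.variant_meta["id"].iloc[bad].tolist()
            raise MonomorphicVariantError(
                f"variant(s) {names} are monomorphic (sd = 0) and cannot be "
                "standardized; remove them before fitting"
            )

    # ----------------------------------------------------------------- subset
    def take_samples(self, idx: np.ndarray) -> "PackedGenotypeMatrix":
        """New packed matrix restricted to the given samples (repacked)."""
        idx = np.asarray(idx)
        rows = []
        tile = _DEFAULT_TILE[0]
        for v0 in range(0, self.n_variants, tile):
            v1 = min(v0 + tile, self.n_variants)
            codes = self.decode_variants(slice(v0, v1))[:, idx]
            rows.append(_pack_codes(codes))
        packed = (
            np.concatenate(rows, axis=0)
            if rows
            else np.zeros((0, (len(idx) + 3) // 4), dtype=np.uint8)
        )
        return PackedGenotypeMatrix(
            packed_bytes=packed,
            n_samples=len(idx),
            variant_meta=self.variant_meta.reset_index(drop=True),
            sample_meta=self.sample_meta.iloc[idx].reset_index(drop=True),
        )

    def take_variants(self, idx: np.ndarray) -> "PackedGenotypeMatrix":
        """New packed matrix restricted to the given variants (zero-copy rows)."""
        idx = np.asarray(idx)
        return PackedGenotypeMatrix(
            packed_bytes=np.ascontiguousarray(self.packed_bytes[idx]),
            n_samples=self.n_samples,
            variant_meta=self.variant_meta.iloc[idx].reset_index(drop=True),
            sample_meta=self.sample_meta.reset_index(drop=True),
        )

    @classmethod
    def from_dense(
        cls,
        codes: np.ndarray,
        variant_meta: pd.DataFrame | None = None,
        sample_meta: pd.DataFrame | None = None,
    ) -> "PackedGenotypeMatrix":
        """Pack a dense int8 code matrix (variants x samples, MISSING=-1)."""
        codes = np.asarray(codes, dtype=np.int8)
        if not np.isin(codes, [0, 1, 2, MISSING]).all():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        p, n = codes.shape
        if variant_meta is None:
            variant_meta = default_variant_meta(p)
        if sample_meta is None:
            sample_meta = default_sample_meta(n)
        return cls(
            packed_bytes=_pack_codes(codes),
            n_samples=n,
            variant_meta=variant_meta.reset_index(drop=True),
            sample_meta=sample_meta.reset_index(drop=True),
        )


def default_variant_meta(p: int, chrom: int = 1) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": np.full(p, chrom),
            "id": [f"snp{j + 1}" for j in range(p)],
            "cm": np.zeros(p),
            "pos": np.arange(1, p + 1) * 1000,
            "a1": ["A"] * p,
            "a2": ["G"] * p,
        }
    )


def default_sample_meta(n: int) -> pd.DataFrame:
    ids = [f"sample{i + 1}" for i in range(n)]
    return pd.DataFrame(
        {
            "fid": ids,
            "iid": ids,
            "father": ["0"] * n,
            "mother": ["0"] * n,
            "sex": np.zeros(n, dtype=int),
            "phenotype": np.full(n, -9),
        }
    )


# --------------------------------------------------------------------- file IO
def read_plink(prefix: str | os.PathLike, mmap: bool = True) -> PackedGenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triplet; the .bed payload is memory-mapped.

    Only SNP-major mode (mode byte 0x01) is supported. Raises
    :class:`PlinkFormatError` on a bad magic/mode byte and
    :class:`PlinkConsistencyError` if the payload size disagrees with the
    .bim/.fam row counts.
    """
    prefix = Path(prefix)
    bed = prefix.with_suffix(".bed")
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    n, p = len(fam), len(bim)
    with open(bed, "rb") as fh:
        header = fh.read(3)
    if header[:2] != MAGIC:
        raise PlinkFormatError(
            f"{bed} does not start with the PLINK magic bytes 0x6c 0x1b"
        )
    if header[2] != SNP_MAJOR_MODE:
        raise PlinkFormatError(
            f"{bed} mode byte is {header[2]:#04x}; only SNP-major (0x01) is supported"
        )
    bpv = (n + 3) // 4
    expected = 3 + p * bpv
    actual = bed.stat().st_size
    if actual != expected:
        raise PlinkConsistencyError(
            f"{bed} holds {actual} bytes but .bim/.fam imply "
            f"3 + {p} * {bpv} = {expected}"
        )
    if mmap:
        packed = np.memmap(bed, dtype=np.uint8, mode="r", offset=3, shape=(p, bpv))
    else:
        packed = np.fromfile(bed, dtype=np.uint8, offset=3).reshape(p, bpv)
    return PackedGenotypeMatrix(
        packed_bytes=packed, n_samples=n, variant_meta=bim, sample_meta=fam
    )


def write_plink(
    prefix: str | os.PathLike,
    genotypes: PackedGenotypeMatrix | np.ndarray,
    variant_meta: pd.DataFrame | None = None,
    sample_meta: pd.DataFrame | None = None,
) -> None:
    """Write a .bed/.bim/.fam triplet (SNP-major, little-endian bit pairs)."""
    if isinstance(genotypes, np.ndarray):
        genotypes = PackedGenotypeMatrix.from_dense(
            genotypes, variant_meta, sample_meta
        )
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(MAGIC + bytes([SNP_MAJOR_MODE]))
        fh.write(np.ascontiguousarray(genotypes.packed_bytes).tobytes())
    genotypes.variant_meta.to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False
    )
    genotypes.sample_meta.to_csv(
        prefix.with_suffix(".fam"), sep="\t", header=False, index=False
    )


def read_phenotypes(
    path: str | os.PathLike, sample_meta: pd.DataFrame
) -> pd.DataFrame:
    """Read a delimited phenotype/covariate table and align it to .fam order.

    The table must have FID and IID as its first two columns (a header row is
    required); remaining columns are numeric traits/covariates. Raises
    ``ValueError`` if the sample ids do not cover the .fam samples.
    """
    tab = pd.read_csv(path, sep=r"\s+")
    id_cols = list(tab.columns[:2])
    tab = tab.set_index(tab[id_cols[1]].astype(str)).drop(columns=id_cols)
    fam_ids = sample_meta["iid"].astype(str)
    missing = set(fam_ids) - set(tab.index)
    if missing:
        some = sorted(missing)[:5]
        raise ValueError(
            f"{len(missing)} sample id(s) in the .fam file are absent from the "
            f"phenotype table (e.g. {some})"
        )
    return tab.loc[fam_ids].reset_index(drop=True)


# ----------------------------------------------------------------- statistics
def column_stats(G: PackedGenotypeMatrix) -> ColumnStats:
    """Per-variant mean, sd (ddof=1) and missing count over non-missing entries."""
    p = G.n_variants
    mean = np.empty(p)
    sd = np.zeros(p)
    missing = np.zeros(p, dtype=np.int64)
    tile = _DEFAULT_TILE[0]
    for v0 in range(0, p, tile):
        v1 = min(v0 + tile, p)
        codes = G.decode_variants(slice(v0, v1)).astype(np.float64)
        miss = codes == MISSING
        codes[miss] = np.nan
        nm = (~miss).sum(axis=1)
        missing[v0:v1] = miss.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = np.nansum(codes, axis=1) / nm
            mu[nm == 0] = np.nan
            var = np.nansum((codes - mu[:, None]) ** 2, axis=1)
            ok = nm > 1
            sd_t = np.zeros(v1 - v0)
            sd_t[ok] = np.sqrt(var[ok] / (nm[ok] - 1))
        mean[v0:v1] = mu
        sd[v0:v1] = sd_t
    return ColumnStats(mean=mean, sd=sd, missing_count=missing)


# -------------------------------------------------------------- linear algebra
def standardized_matmul(
    G: PackedGenotypeMatrix,
    M: np.ndarray,
    transpose_G: bool = False,
    tile: tuple[int, int] = _DEFAULT_TILE,
) -> np.ndarray:
    """Product of the standardized genotype matrix Z (p x n) with a dense M.

    Z's row j is variant j centered by its non-missing mean and scaled by its
    sd; missing entries are mean-imputed, hence exactly 0 after centering.
    Returns Z @ M (M is n x q) or, with ``transpose_G``, Z.T @ M (M is p x q).
    The computation is tiled: only ``tile`` = (variants, samples) sized blocks
    are ever decoded. Raises on shape mismatch or a zero-sd variant.
    """
    M = np.asarray(M, dtype=np.float64)
    squeeze = M.ndim == 1
    if squeeze:
        M = M[:, None]
    p, n = G.n_variants, G.n_samples
    inner = p if transpose_G else n
    if M.shape[0] != inner:
        raise ValueError(
            f"shape mismatch: M has {M.shape[0]} rows, expected {inner}"
        )
    G._check_polymorphic(np.arange(p))
    st = G.col_stats
    tv, ts = max(1, tile[0]), max(1, tile[1])
    out = np.zeros((n if transpose_G else p, M.shape[1]))
    for v0 in range(0, p, tv):
        v1 = min(v0 + tv, p)
        for s0 in range(0, n, ts):
            s1 = min(s0 + ts, n)
            codes = G.decode_variants(slice(v0, v1), slice(s0, s1)).astype(
                np.float64
            )
            miss = codes == MISSING
            Z = (codes - st.mean[v0:v1, None]) / st.sd[v0:v1, None]
            Z[miss] = 0.0
            if transpose_G:
                out[s0:s1] += Z.T @ M[v0:v1]
            else:
                out[v0:v1] += Z @ M[s0:s1]
    return out[:, 0] if squeeze else out


def ld_prune(
    G: PackedGenotypeMatrix, r_threshold: float, window: int = 50
) -> np.ndarray:
    """Greedy left-to-right LD pruning by pairwise Pearson correlation.

    A variant is kept iff its absolute correlation with every previously kept
    variant within the trailing ``window`` (in map order) is <= ``r_threshold``.
    Monomorphic variants have undefined correlation, treated as 0 (kept).
    Returns the kept variant indices, strictly increasing.
    """
    if not (0 < r_threshold <= 1):
        raise ValueError("r_threshold must be in (0, 1]")
    if window < 1:
        raise ValueError("window must be >= 1")
    p, n = G.n_variants, G.n_samples
    st = G.col_stats
    kept: list[int] = []
    zcache: dict[int, np.ndarray | None] = {}

    def zrow(j: int) -> np.ndarray | None:
        if j not in zcache:
            zcache[j] = (
                None if st.sd[j] == 0 else G.standardized_variants([j])[0]
            )
        return zcache[j]

    for j in range(p):
        zj = zrow(j)
        ok = True
        if zj is not None:
            for i in reversed(kept):
                if j - i > window:
                    break
                zi = zrow(i)
                if zi is None:
                    continue
                r = float(zi @ zj) / (n - 1)
                if abs(r) > r_threshold:
                    ok = False
                    break
        if ok:
            kept.append(j)
        # evict cache entries that fell out of every future window
        for i in list(zcache):
            if j - i >= window and i != j:
                zcache.pop(i)
    return np.array(kept, dtype=np.int64)
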