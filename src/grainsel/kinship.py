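"""Genomic relationship matrix (GRM) estimation.

The GRM estimates realized relatedness between lines from standardized SNP
dosages.  For lines j, k and SNP i with dosage x and allele frequency p_i,

    A_jk = (1 / m_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

over the SNPs non-missing in both lines (m_jk of them).  Two diagonal
conventions are supported: ``standard`` uses the same cross-product formula
with j = k (so that with no missingness A = W W'/m, the form the ridge
SNP-BLUP identity requires), while ``yang`` uses

    A_jj = 1 + (1/m) * sum_i [x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2]
                               / (2 p_i (1 - p_i)),

the less-sampling-noisy self-relatedness estimator used by the common GRM
tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypePanel

__all__ = ["GRM", "allele_frequencies", "compute_grm", "write_grm_tsv",
           "read_grm_tsv", "write_grm_binary", "read_grm_binary"]


@dataclass
class GRM:
    """n x n relationship matrix with its sample index.

    ``n_snps_used`` holds, per pair, the number of SNPs that entered the
    average (equal everywhere when there is no missingness).
    """

    sample_ids: np.ndarray
    matrix: np.ndarray
    n_snps_used: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM matrix shape does not match sample_ids")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("GRM must be exactly symmetric")
        if not np.isfinite(self.matrix).all():
            raise ValueError("GRM contains non-finite entries")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, idx) -> "GRM":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GRM(
            sample_ids=self.sample_ids[idx],
            matrix=self.matrix[np.ix_(idx, idx)],
            n_snps_used=self.n_snps_used[np.ix_(idx, idx)],
        )


def allele_frequencies(panel: GenotypePanel) -> np.ndarray:
    """Frequency of ``allele1`` per SNP, computed over non-missing calls."""
    if panel.n_snps == 0 or panel.n_samples == 0:
        raise ValueError("empty panel")
    called = ~panel.missing_mask()
    n_called = called.sum(axis=0)
    dead = n_called == 0
    if dead.any():
        names = panel.snp_ids[dead][:5]
        raise ValueError(f"SNP(s) with all calls missing: {list(names)}")
    with np.errstate(invalid="ignore"):
        return np.nansum(panel.dosages, axis=0) / (2.0 * n_called)


def compute_grm(
    panel: GenotypePanel,
    diagonal: str = "yang",
    grm_missing_max: float = 0.02,
) -> GRM:
    """Estimate the GRM from a QC-passed panel.

    SNPs whose missing fraction exceeds ``grm_missing_max`` (default 2 %,
    i.e. genotyping quality above 98 %) are excluded before computation;
    monomorphic SNPs are skipped with a warning.  Missing calls are handled
    pairwise-complete: each A_jk averages over the SNPs called in both
    lines, which keeps the matrix exactly symmetric.
    """
    if panel.n_samples < 2:
        raise ValueError("GRM needs at least 2 samples")
    if diagonal not in ("standard", "yang"):
        raise ValueError(f"unknown diagonal convention {diagonal!r}")

    miss = panel.missing_mask()
    keep = miss.mean(axis=0) <= grm_missing_max
    sub = panel.subset(snps=keep)
    p = allele_frequencies(sub)
    poly = (p > 0.0) & (p < 1.0)
    if not poly.all():
        warnings.warn(
            f"{int((~poly).sum())} monomorphic SNP(s) skipped in GRM computation"
        )
    sub = sub.subset(snps=poly)
    p = p[poly]
    if sub.n_snps == 0:
        raise ValueError("no usable (polymorphic, well-called) SNPs for the GRM")

    x = sub.dosages
    called = ~np.isnan(x)
    sd = np.sqrt(2.0 * p * (1.0 - p))
    z = np.where(called, (np.nan_to_num(x) - 2.0 * p[None, :]) / sd[None, :], 0.0)
    counts = called.astype(float) @ called.astype(float).T
    if (counts == 0).any():
        raise ValueError("sample pair(s) share zero called SNPs")
    a = (z @ z.T) / counts

    if diagonal == "yang":
        xs = np.nan_to_num(x)
        num = xs * xs - (1.0 + 2.0 * p[None, :]) * xs + 2.0 * p[None, :] ** 2
        num = np.where(called, num / (2.0 * p * (1.0 - p))[None, :], 0.0)
        m_j = called.sum(axis=1).astype(float)
        np.fill_diagonal(a, 1.0 + num.sum(axis=1) / m_j)

    a = (a + a.T) / 2.0  # enforce exact symmetry against float noise
    return GRM(sample_ids=sub.sample_ids, matrix=a, n_snps_used=counts.astype(np.int64))


# ---------------------------------------------------------------------------
# GRM persistence: plain TSV and the conventional binary triple
# (<prefix>.grm.bin float32 lower triangle, <prefix>.grm.N.bin float32
# pair counts, <prefix>.grm.id two-column id file).


def write_grm_tsv(grm: GRM, path: str | Path) -> None:
    df = pd.DataFrame(grm.matrix, index=grm.sample_ids, columns=grm.sample_ids)
    df.to_csv(path, sep="\t", index_label="id")


def read_grm_tsv(path: str | Path) -> GRM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    mat = df.to_numpy(dtype=float)
    mat = (mat + mat.T) / 2.0
    n = len(df.index)
    return GRM(
        sample_ids=df.index.to_numpy(dtype=object),
        matrix=mat,
        n_snps_used=np.zeros((n, n), dtype=np.int64),
    )


def write_grm_binary(grm: GRM, prefix: str | Path) -> None:
    prefix = Path(prefix)
    tril = np.tril_indices(grm.n)
    with open(f"{prefix}.grm.bin", "wb") as fh:
        fh.write(grm.matrix[tril].astype("<f4").tobytes())
    with open(f"{prefix}.grm.N.bin", "wb") as fh:
        fh.write(grm.n_snps_used[tril].astype("<f4").tobytes())
    with open(f"{prefix}.grm.id", "w") as fh:
        for sid in grm.sample_ids:
            fh.write(f"{sid}\t{sid}\n")


def read_grm_binary(prefix: str | Path) -> GRM:
    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(f"{prefix}.grm.id")]
    n = len(ids)
    n_tri = n * (n + 1) // 2
    vals = np.frombuffer(Path(f"{prefix}.grm.bin").read_bytes(), dtype="<f4")
    if vals.size != n_tri:
        raise ValueError(f"{prefix}.grm.bin has {vals.size} values, expected {n_tri}")
    counts = np.frombuffer(Path(f"{prefix}.grm.N.bin").read_bytes(), dtype="<f4")
    mat = np.zeros((n, n))
    cnt = np.zeros((n, n))
    tril = np.tril_indices(n)
    mat[tril] = vals
    cnt[tril] = counts
    mat = mat + np.tril(mat, -1).T
    cnt = cnt + np.tril(cnt, -1).T
    return GRM(
        sample_ids=np.asarray(ids, dtype=object),
        matrix=mat,
        n_snps_used=cnt.astype(np.int64),
    )
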