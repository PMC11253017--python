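"""Genotype and phenotype containers, PLINK text/binary I/O, and QC filtering.

Dosage convention
-----------------
The dosage matrix counts copies of ``allele1`` per SNP, so a line carrying
two copies of ``allele1`` has dosage 2 and a line carrying none has dosage 0.
Missing calls are ``NaN``.  When a text ``.ped`` is read, ``allele1`` is the
lexicographically smaller of the two observed alleles (a deterministic
convention; the binary ``.bim`` stores both alleles explicitly so no
convention is needed there).  Downstream scoring carries allele labels with
every coefficient, so the convention never leaks into predictions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "PhenotypeTable",
    "QCReport",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "qc_filter",
    "line_means",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major bed header


class PlinkFormatError(ValueError):
    """Raised when a PLINK fileset is malformed or internally inconsistent."""


@dataclass
class GenotypePanel:
    """A biallelic dosage matrix (lines x SNPs) with its marker map.

    Attributes
    ----------
    sample_ids : array of unique line identifiers (rows).
    snp_ids : array of unique SNP identifiers (columns).
    chromosomes, positions : marker map, one entry per SNP.
    allele1, allele2 : allele labels per SNP; ``dosages`` counts ``allele1``.
    dosages : float array of shape (n_samples, n_snps) with entries in
        {0, 1, 2} or NaN for a missing call.
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = len(self.sample_ids), len(self.snp_ids)
        if self.dosages.shape != (n, m):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"({n} samples, {m} SNPs)"
            )
        for name, arr in (
            ("chromosomes", self.chromosomes),
            ("positions", self.positions),
            ("allele1", self.allele1),
            ("allele2", self.allele2),
        ):
            if len(arr) != m:
                raise ValueError(f"{name} has length {len(arr)}, expected {m}")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(set(self.snp_ids)) != m:
            raise ValueError("snp_ids are not unique")
        if np.any(self.positions < 0):
            raise ValueError("positions must be non-negative")
        if m and np.any(self.allele1 == self.allele2):
            raise ValueError("allele1 and allele2 must differ per SNP")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, samples=None, snps=None) -> "GenotypePanel":
        """Return a new panel restricted to the given integer/boolean indices."""
        s = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        if s.dtype == bool:
            s = np.flatnonzero(s)
        k = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if k.dtype == bool:
            k = np.flatnonzero(k)
        return GenotypePanel(
            sample_ids=self.sample_ids[s],
            snp_ids=self.snp_ids[k],
            chromosomes=self.chromosomes[k],
            positions=self.positions[k],
            allele1=self.allele1[k],
            allele2=self.allele2[k],
            dosages=self.dosages[np.ix_(s, k)],
        )

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.snp_ids, other.snp_ids)
            and np.array_equal(self.chromosomes, other.chromosomes)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.allele1, other.allele1)
            and np.array_equal(self.allele2, other.allele2)
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


# ---------------------------------------------------------------------------
# PLINK I/O


def read_plink(path_prefix: str | Path, dialect: str | None = None) -> GenotypePanel:
    """Read a PLINK fileset ``<prefix>.{ped,map}`` or ``<prefix>.{bed,bim,fam}``.

    ``dialect`` is ``"text"``, ``"binary"`` or ``None`` (auto-detect, binary
    preferred when both exist).
    """
    prefix = Path(path_prefix)
    if dialect is None:
        dialect = "binary" if prefix.with_suffix(".bed").exists() else "text"
    if dialect == "binary":
        return _read_bed(prefix)
    if dialect == "text":
        return _read_ped(prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_plink(panel: GenotypePanel, path_prefix: str | Path, dialect: str = "binary") -> None:
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "binary":
        _write_bed(panel, prefix)
    elif dialect == "text":
        _write_ped(panel, prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PlinkFormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            rows.append(parts)
    df = pd.DataFrame(rows, columns=["chrom", "snp_id", "cm", "pos"])
    df["pos"] = df["pos"].astype(np.int64)
    return df


def _read_ped(prefix: Path) -> GenotypePanel:
    map_df = _read_map(prefix.with_suffix(".map"))
    m = len(map_df)
    ped_path = prefix.with_suffix(".ped")
    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields for "
                    f"{m} SNPs in {prefix.with_suffix('.map')}, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])
    alleles = np.asarray(allele_rows, dtype=object).reshape(len(sample_ids), m, 2)

    a1 = np.empty(m, dtype=object)
    a2 = np.empty(m, dtype=object)
    dosages = np.full((len(sample_ids), m), np.nan)
    for j in range(m):
        col = alleles[:, j, :]
        observed = sorted({a for a in col.ravel() if a != "0"})
        if len(observed) > 2:
            raise PlinkFormatError(
                f"{ped_path}: SNP {map_df['snp_id'][j]} has >2 alleles: {observed}"
            )
        if len(observed) == 2:
            a1[j], a2[j] = observed  # lexicographic: smaller allele is counted
        elif len(observed) == 1:
            a1[j], a2[j] = "0", observed[0]
        else:
            a1[j], a2[j] = "0", "?"
        called = (col != "0").all(axis=1)
        dosages[called, j] = (col[called] == a1[j]).sum(axis=1)
    return GenotypePanel(
        sample_ids=np.asarray(sample_ids, dtype=object),
        snp_ids=map_df["snp_id"].to_numpy(dtype=object),
        chromosomes=map_df["chrom"].to_numpy(dtype=object),
        positions=map_df["pos"].to_numpy(),
        allele1=a1,
        allele2=a2,
        dosages=dosages,
    )


def _write_ped(panel: GenotypePanel, prefix: Path) -> None:
    # Canonical orientation: the counted allele is the lexicographically
    # smaller label, mirroring _read_ped, so write->read is the identity for
    # panels already in that orientation.
    flip = panel.allele1 > panel.allele2
    a1 = np.where(flip, panel.allele2, panel.allele1)
    a2 = np.where(flip, panel.allele1, panel.allele2)
    dos = np.where(flip[None, :], 2.0 - panel.dosages, panel.dosages)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for c, s, p in zip(panel.chromosomes, panel.snp_ids, panel.positions):
            fh.write(f"{c}\t{s}\t0\t{p}\n")
    pair = {2.0: "{a1} {a1}", 1.0: "{a1} {a2}", 0.0: "{a2} {a2}"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(panel.sample_ids):
            fields = [str(sid), str(sid), "0", "0", "0", "-9"]
            for j in range(panel.n_snps):
                d = dos[i, j]
                if np.isnan(d):
                    fields.append("0 0")
                else:
                    fields.append(pair[d].format(a1=a1[j], a2=a2[j]))
            fh.write(" ".join(fields) + "\n")


def _read_bed(prefix: Path) -> GenotypePanel:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype=str,
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes {raw[:3]!r} "
            f"(expected SNP-major bed header {_BED_MAGIC!r})"
        )
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{prefix.with_suffix('.bed')}: {body.size} data bytes, expected "
            f"{bytes_per_snp * m} for {n} samples x {m} SNPs"
        )
    codes = body.reshape(m, bytes_per_snp)
    # unpack 2-bit genotype codes, lowest bits first
    shifts = np.arange(4, dtype=np.uint8) * 2
    geno = (codes[:, :, None] >> shifts[None, None, :]) & 3  # (m, bpS, 4)
    geno = geno.reshape(m, -1)[:, :n].T  # (n, m)
    # bed code -> dosage of allele1: 00 hom A1, 10 het, 11 hom A2, 01 missing
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[geno]
    return GenotypePanel(
        sample_ids=fam[1].to_numpy(dtype=object),
        snp_ids=bim["snp_id"].to_numpy(dtype=object),
        chromosomes=bim["chrom"].to_numpy(dtype=object),
        positions=bim["pos"].astype(np.int64).to_numpy(),
        allele1=bim["a1"].to_numpy(dtype=object),
        allele2=bim["a2"].to_numpy(dtype=object),
        dosages=dosages,
    )


def _write_bed(panel: GenotypePanel, prefix: Path) -> None:
    n, m = panel.n_samples, panel.n_snps
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(m):
            fh.write(
                f"{panel.chromosomes[j]}\t{panel.snp_ids[j]}\t0\t"
                f"{panel.positions[j]}\t{panel.allele1[j]}\t{panel.allele2[j]}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in panel.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    d = panel.dosages
    code = np.full(d.shape, 1, dtype=np.uint8)  # missing
    code[d == 2.0] = 0
    code[d == 1.0] = 2
    code[d == 0.0] = 3
    bytes_per_snp = (n + 3) // 4
    padded = np.ones((m, bytes_per_snp * 4), dtype=np.uint8) * 0  # pad with code 0
    padded[:, :n] = code.T
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCReport:
    """Counts of markers/samples removed at each QC stage."""

    n_snps_in: int
    n_samples_in: int
    n_snps_removed_missingness: int
    n_snps_removed_maf: int
    n_samples_removed_missingness: int
    max_snp_missing: float
    min_maf: float
    max_sample_missing: float

    @property
    def n_snps_out(self) -> int:
        return self.n_snps_in - self.n_snps_removed_missingness - self.n_snps_removed_maf

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.n_samples_removed_missingness

    def to_json(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["n_snps_out"] = self.n_snps_out
        d["n_samples_out"] = self.n_samples_out
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


def qc_filter(
    panel: GenotypePanel,
    max_snp_missing: float = 0.05,
    min_maf: float = 0.01,
    max_sample_missing: float = 0.05,
) -> tuple[GenotypePanel, QCReport]:
    """Apply marker/sample QC in a fixed, documented order.

    1. remove SNPs with missing-call fraction > ``max_snp_missing``;
    2. recompute allele frequencies on the survivors (non-missing calls
       only) and remove SNPs with minor allele frequency < ``min_maf``;
    3. remove samples whose missing fraction over the retained SNPs
       exceeds ``max_sample_missing``.

    Because removing samples can push a surviving SNP back under the MAF
    or missingness threshold, the three steps are repeated in this order
    until a full pass removes nothing; the reported counts are cumulative.
    This makes the filter idempotent.  The defaults mirror common array-QC
    practice for inbred crop panels (5 % marker missingness, 1 % MAF, 5 %
    sample missingness).
    """
    for name, t in (
        ("max_snp_missing", max_snp_missing),
        ("min_maf", min_maf),
        ("max_sample_missing", max_sample_missing),
    ):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name}={t} outside [0, 1]")

    n, m = panel.n_samples, panel.n_snps
    n_rm_miss = n_rm_maf = n_rm_samp = 0
    current = panel
    while True:
        miss = current.missing_mask()
        keep1 = miss.mean(axis=0) <= max_snp_missing
        n_rm_miss += int((~keep1).sum())
        p1 = current.subset(snps=keep1)

        with np.errstate(invalid="ignore"):
            p_freq = np.nanmean(p1.dosages, axis=0) / 2.0
        maf = np.minimum(p_freq, 1.0 - p_freq)
        maf = np.where(np.isnan(maf), 0.0, maf)  # all-missing column: MAF 0
        keep2 = maf >= min_maf
        n_rm_maf += int((~keep2).sum())
        p2 = p1.subset(snps=keep2)
        if p2.n_snps == 0:
            raise ValueError(
                "QC removed every SNP; thresholds too strict for this panel"
            )

        sample_miss = p2.missing_mask().mean(axis=1)
        keep_s = sample_miss <= max_sample_missing
        n_rm_samp += int((~keep_s).sum())
        p3 = p2.subset(samples=keep_s)
        if p3.n_samples == 0:
            raise ValueError(
                "QC removed every sample; thresholds too strict for this panel"
            )
        removed_this_pass = (~keep1).sum() + (~keep2).sum() + (~keep_s).sum()
        current = p3
        if removed_this_pass == 0:
            break

    report = QCReport(
        n_snps_in=m,
        n_samples_in=n,
        n_snps_removed_missingness=n_rm_miss,
        n_snps_removed_maf=n_rm_maf,
        n_samples_removed_missingness=n_rm_samp,
        max_snp_missing=max_snp_missing,
        min_maf=min_maf,
        max_sample_missing=max_sample_missing,
    )
    return current, report


# ---------------------------------------------------------------------------
# Phenotypes


@dataclass
class PhenotypeTable:
    """Replicated trait measurements, long format.

    ``records`` has columns ``line_id, trait, year, replicate, value``; one
    row per measurement (e.g. 2 years x 2 replicates = 4 rows per line and
    trait, values in mg/kg for grain element content).
    """

    records: pd.DataFrame = field(repr=False)

    REQUIRED = ("line_id", "trait", "year", "replicate", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        vals = self.records["value"].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("phenotype values must be finite")

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.records["trait"]))

    def line_means(self, trait: str, sample_ids=None) -> pd.Series:
        return line_means(self, trait, sample_ids=sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "trait": str})
        return cls(records=df)


def line_means(phenos: PhenotypeTable, trait: str, sample_ids=None) -> pd.Series:
    """Arithmetic mean of each line's measurements for one trait.

    Returns a Series indexed by line id.  When ``sample_ids`` is given the
    result follows that ordering; lines with no record for the trait are
    dropped with a warning rather than propagated as NaN.
    """
    sub = phenos.records[phenos.records["trait"] == trait]
    if sub.empty:
        raise KeyError(f"trait {trait!r} not present in phenotype table")
    means = sub.groupby("line_id", sort=False)["value"].mean()
    if sample_ids is not None:
        sample_ids = [str(s) for s in sample_ids]
        absent = [s for s in sample_ids if s not in means.index]
        if absent:
            warnings.warn(
                f"{len(absent)} line(s) have no {trait!r} records and were "
                f"excluded: {absent[:5]}{'...' if len(absent) > 5 else ''}"
            )
        means = means.reindex([s for s in sample_ids if s in means.index])
    means.name = trait
    return means
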