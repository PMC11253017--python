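"""Synthetic genotype/phenotype panels for an inbred crop collection.

The generator emulates the structure of a spring-wheat variety panel
genotyped on a fixed SNP array and phenotyped for grain element content
over two seasons with two replicates each: ~150 near-homozygous lines,
~11k biallelic markers with local linkage disequilibrium, and seven
correlated element-content traits measured four times per line.

Genotypes come from a latent Gaussian model: within each chromosome a
first-order autoregressive latent process (correlation ``ld_rho`` between
adjacent markers) is thresholded at the quantile of the marker's allele
frequency, giving dosages concentrated at {0, 2} for fully inbred lines.
Traits are polygenic: causal markers get i.i.d. normal effects on the
standardized genotype scale, a configurable fraction of causal markers is
shared between traits (pleiotropy), and the genetic values are rescaled so
that the heritability of the per-line mean phenotype hits the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotype_io import GenotypePanel, PhenotypeTable

__all__ = [
    "PanelConfig",
    "TrueArchitecture",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_panel",
]

_NUCLEOTIDES = np.array(["A", "C", "G", "T"], dtype=object)

# Plausible grain element means for spring bread wheat (mg/kg dry weight):
# K, Ca, Mg, Mn, Fe, Zn, Cu in the usual reporting order.
_DEFAULT_TRAITS = ("K", "Ca", "Mg", "Mn", "Fe", "Zn", "Cu")
_DEFAULT_MEANS = (4500.0, 450.0, 1200.0, 45.0, 40.0, 30.0, 5.0)


def _per_trait(value, n_traits: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(n_traits, arr[0])
    if arr.size != n_traits:
        raise ValueError(f"{name} must be scalar or length {n_traits}, got {arr.size}")
    return arr


@dataclass
class PanelConfig:
    """Study-design parameters for one synthetic panel.

    Defaults mirror the design this package targets: 149 inbred lines,
    11,405 array SNPs on 21 chromosomes, 7 element-content traits, each
    measured in 2 years x 2 replicates.  ``year_sd`` and ``resid_sd``
    default to 5 % and 8 % of each trait mean (field-trial-scale
    non-genetic variation); set them explicitly for other regimes.
    """

    n_lines: int = 149
    n_snps: int = 11405
    n_chromosomes: int = 21
    maf_low: float = 0.01
    maf_high: float = 0.5
    ld_rho: float = 0.6
    n_traits: int = 7
    h2: float | tuple = 0.5
    n_causal: int = 100
    pleiotropy_frac: float = 0.3
    n_years: int = 2
    reps_per_year: int = 2
    year_sd: float | tuple | None = None
    resid_sd: float | tuple | None = None
    trait_means: tuple = _DEFAULT_MEANS
    trait_names: tuple = _DEFAULT_TRAITS
    heterozygosity: float = 0.0
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        # adapt the 7-trait defaults when another trait count is requested
        if self.trait_names == _DEFAULT_TRAITS and self.n_traits != len(_DEFAULT_TRAITS):
            if self.n_traits <= len(_DEFAULT_TRAITS):
                self.trait_names = _DEFAULT_TRAITS[: self.n_traits]
            else:
                self.trait_names = tuple(f"trait{i + 1}" for i in range(self.n_traits))
        if self.trait_means == _DEFAULT_MEANS and self.n_traits != len(_DEFAULT_MEANS):
            if self.n_traits <= len(_DEFAULT_MEANS):
                self.trait_means = _DEFAULT_MEANS[: self.n_traits]
            else:
                self.trait_means = tuple(100.0 for _ in range(self.n_traits))
        self.validate()

    def validate(self) -> None:
        for name in ("n_lines", "n_snps", "n_chromosomes", "n_traits", "n_causal",
                     "n_years", "reps_per_year"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_snps < self.n_chromosomes:
            raise ValueError("n_snps must be >= n_chromosomes")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0.0 <= self.pleiotropy_frac <= 1.0:
            raise ValueError("pleiotropy_frac must be in [0, 1]")
        if not 0.0 <= self.heterozygosity <= 1.0:
            raise ValueError("heterozygosity must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        h2 = _per_trait(self.h2, self.n_traits, "h2")
        if np.any((h2 < 0) | (h2 > 1)):
            raise ValueError("h2 must lie in [0, 1]")
        if len(self.trait_means) != self.n_traits:
            raise ValueError("trait_means must have length n_traits")
        if len(self.trait_names) != self.n_traits:
            raise ValueError("trait_names must have length n_traits")

    # Resolved per-trait arrays -------------------------------------------
    @property
    def h2_per_trait(self) -> np.ndarray:
        return _per_trait(self.h2, self.n_traits, "h2")

    @property
    def year_sd_per_trait(self) -> np.ndarray:
        if self.year_sd is None:
            return 0.05 * np.asarray(self.trait_means, dtype=float)
        return _per_trait(self.year_sd, self.n_traits, "year_sd")

    @property
    def resid_sd_per_trait(self) -> np.ndarray:
        if self.resid_sd is None:
            return 0.08 * np.asarray(self.trait_means, dtype=float)
        return _per_trait(self.resid_sd, self.n_traits, "resid_sd")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("h2", "year_sd", "resid_sd", "trait_means", "trait_names"):
            if isinstance(d.get(k), list):
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class TrueArchitecture:
    """Ground truth behind a simulated phenotype set.

    ``causal_effects`` are on the standardized-genotype scale after the
    heritability rescale; ``true_bv`` is in trait units (deviation from the
    trait mean); ``realized_h2`` is Var(true BV)/Var(per-line mean) in the
    generated sample.
    """

    trait_names: list[str]
    causal_indices: list[np.ndarray]
    causal_effects: list[np.ndarray]
    true_bv: np.ndarray  # (n_lines, n_traits)
    realized_h2: np.ndarray
    sample_ids: np.ndarray = field(default=None)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.true_bv, columns=self.trait_names)
        df.insert(0, "line_id", self.sample_ids)
        df.to_csv(path, sep="\t", index=False)


def _rng_children(seed, n: int):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def simulate_genotypes(config: PanelConfig) -> GenotypePanel:
    """Draw a dosage panel under the latent AR(1) linkage model.

    Per-SNP allele frequencies are uniform on [maf_low, maf_high]; the
    latent process restarts at each chromosome boundary so correlation does
    not cross chromosomes.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = _rng_children(config.seed, 2)[0]
    n, m = config.n_lines, config.n_snps
    rho = config.ld_rho

    p = rng.uniform(config.maf_low, config.maf_high, size=m)
    chrom_sizes = [len(b) for b in np.array_split(np.arange(m), config.n_chromosomes)]

    def _latent() -> np.ndarray:
        z = np.empty((n, m))
        start = 0
        innov = rng.standard_normal((n, m))
        for size in chrom_sizes:
            block = z[:, start:start + size]
            block[:, 0] = innov[:, start]
            scale = np.sqrt(1.0 - rho * rho)
            for j in range(1, size):
                block[:, j] = rho * block[:, j - 1] + scale * innov[:, start + j]
            start += size
        return z

    thresh = _ppf(p)
    hap_a = (_latent() < thresh[None, :]).astype(float)
    if config.heterozygosity > 0:
        hap_b_indep = (_latent() < thresh[None, :]).astype(float)
        use_b = rng.random((n, m)) < config.heterozygosity
        hap_b = np.where(use_b, hap_b_indep, hap_a)
    else:
        hap_b = hap_a
    dosages = hap_a + hap_b

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dosages = np.where(miss, np.nan, dosages)

    pair_idx = np.array([rng.choice(4, size=2, replace=False) for _ in range(m)])
    pair = np.sort(_NUCLEOTIDES[pair_idx], axis=1)
    chroms = np.repeat(
        [str(c + 1) for c in range(config.n_chromosomes)], chrom_sizes
    ).astype(object)
    positions = np.concatenate(
        [np.arange(1, size + 1) * 1000 for size in chrom_sizes]
    )
    width = len(str(m))
    snp_ids = np.array([f"snp{j + 1:0{width}d}" for j in range(m)], dtype=object)
    wn = len(str(n))
    sample_ids = np.array([f"line{i + 1:0{wn}d}" for i in range(n)], dtype=object)
    return GenotypePanel(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        chromosomes=chroms,
        positions=positions,
        allele1=pair[:, 0],
        allele2=pair[:, 1],
        dosages=dosages,
    )


def _ppf(p: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf(p)


def simulate_phenotypes(
    panel: GenotypePanel, config: PanelConfig
) -> tuple[PhenotypeTable, TrueArchitecture]:
    """Simulate replicated trait measurements on top of a genotype panel.

    Observation model per line i, year t, replicate r:

        y_itr = trait_mean + bv_i + u_it + e_itr,

    with u_it ~ N(0, year_sd^2) drawn per (line, year) cell and
    e_itr ~ N(0, resid_sd^2).  True breeding values are linear in the
    standardized causal genotypes and rescaled so that
    Var(bv) / Var(per-line mean) equals the target h2 in expectation over
    the noise draws (exactly for the bv part, which is rescaled on its
    realized sample variance).  At h2 = 1 all non-genetic terms are zero.
    """
    config.validate()
    if panel.n_samples != config.n_lines or panel.n_snps != config.n_snps:
        raise ValueError("panel dimensions do not match config")
    rng = _rng_children(config.seed, 2)[1]
    n, m, T = config.n_lines, config.n_snps, config.n_traits
    h2 = config.h2_per_trait
    year_sd = config.year_sd_per_trait
    resid_sd = config.resid_sd_per_trait
    means = np.asarray(config.trait_means, dtype=float)

    dos = panel.dosages
    freq = np.nanmean(dos, axis=0) / 2.0  # per-SNP sample frequency
    var_ok = (freq > 0) & (freq < 1)
    candidates = np.flatnonzero(var_ok)
    if candidates.size < config.n_causal:
        raise ValueError("not enough polymorphic SNPs for the requested n_causal")

    n_shared = int(round(config.pleiotropy_frac * config.n_causal))
    shared = rng.choice(candidates, size=n_shared, replace=False)
    shared_eff = rng.normal(0.0, np.sqrt(1.0 / config.n_causal), size=n_shared)
    remaining = np.setdiff1d(candidates, shared)

    causal_indices: list[np.ndarray] = []
    causal_effects: list[np.ndarray] = []
    bv = np.zeros((n, T))
    for t in range(T):
        n_priv = config.n_causal - n_shared
        priv = rng.choice(remaining, size=n_priv, replace=False)
        idx = np.concatenate([shared, priv]).astype(np.intp)
        eff = np.concatenate(
            [shared_eff, rng.normal(0.0, np.sqrt(1.0 / config.n_causal), size=n_priv)]
        )
        W = np.nan_to_num(_standardize(dos[:, idx], freq[idx]))  # missing -> mean
        raw = W @ eff
        # rescale to the genetic variance implied by target h2 and the
        # non-genetic variance of the per-line mean
        v_nonmean = year_sd[t] ** 2 / config.n_years + resid_sd[t] ** 2 / (
            config.n_years * config.reps_per_year
        )
        sample_var = raw.var(ddof=1)
        if h2[t] == 0.0 or sample_var == 0.0:
            scale = 0.0
            raw = np.zeros(n)
        elif h2[t] == 1.0:
            target = v_nonmean if v_nonmean > 0 else 1.0
            scale = np.sqrt(target / sample_var)
        else:
            target = h2[t] / (1.0 - h2[t]) * v_nonmean
            scale = np.sqrt(target / sample_var)
        bv[:, t] = raw * scale
        causal_indices.append(idx)
        causal_effects.append(eff * scale)

    zero_noise = h2 == 1.0
    records = []
    n_years, reps = config.n_years, config.reps_per_year
    for t in range(T):
        ysd = 0.0 if zero_noise[t] else year_sd[t]
        esd = 0.0 if zero_noise[t] else resid_sd[t]
        u = rng.normal(0.0, ysd, size=(n, n_years)) if ysd > 0 else np.zeros((n, n_years))
        e = (
            rng.normal(0.0, esd, size=(n, n_years, reps))
            if esd > 0
            else np.zeros((n, n_years, reps))
        )
        vals = means[t] + bv[:, t][:, None, None] + u[:, :, None] + e
        for yi in range(n_years):
            for ri in range(reps):
                records.append(
                    pd.DataFrame(
                        {
                            "line_id": panel.sample_ids,
                            "trait": config.trait_names[t],
                            "year": 2018 + yi,
                            "replicate": ri + 1,
                            "value": vals[:, yi, ri],
                        }
                    )
                )
    table = PhenotypeTable(records=pd.concat(records, ignore_index=True))

    realized = np.empty(T)
    for t in range(T):
        lm = table.line_means(config.trait_names[t], sample_ids=panel.sample_ids)
        denom = lm.to_numpy().var(ddof=1)
        realized[t] = bv[:, t].var(ddof=1) / denom if denom > 0 else np.nan
    arch = TrueArchitecture(
        trait_names=list(config.trait_names),
        causal_indices=causal_indices,
        causal_effects=causal_effects,
        true_bv=bv,
        realized_h2=realized,
        sample_ids=panel.sample_ids,
    )
    return table, arch


def _standardize(dosages: np.ndarray, freq: np.ndarray) -> np.ndarray:
    sd = np.sqrt(2.0 * freq * (1.0 - freq))
    return (dosages - 2.0 * freq[None, :]) / sd[None, :]


def simulate_panel(config: PanelConfig):
    """Convenience: genotypes + phenotypes + ground truth in one call."""
    panel = simulate_genotypes(config)
    phenos, arch = simulate_phenotypes(panel, config)
    return panel, phenos, arch
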