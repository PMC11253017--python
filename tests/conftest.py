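import numpy as np
import pytest

from grainsel import PanelConfig, simulate_genotypes, simulate_panel


def make_config(**kw) -> PanelConfig:
    """Small-panel config for fast tests; override any field."""
    base = dict(
        n_lines=40,
        n_snps=120,
        n_chromosomes=3,
        maf_low=0.1,
        maf_high=0.4,
        ld_rho=0.3,
        n_traits=2,
        h2=0.5,
        n_causal=30,
        seed=0,
    )
    base.update(kw)
    return PanelConfig(**base)


@pytest.fixture
def small_panel():
    """40 lines x 120 SNPs, fully inbred, no missingness."""
    return simulate_genotypes(make_config())


@pytest.fixture
def small_dataset():
    """(panel, phenotypes, architecture) for a 40-line, 2-trait panel."""
    return simulate_panel(make_config())


def random_spd(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric positive-definite matrix with diagonal near 1."""
    b = rng.standard_normal((n, 2 * n))
    a = b @ b.T / (2 * n)
    return (a + a.T) / 2.0
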