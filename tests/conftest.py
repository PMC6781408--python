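import numpy as np
import pandas as pd
import pytest

from spgwas.geno import GenotypeMatrix


def make_geno(dosage, chrom=None, pos=None, **marker_cols) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw dosage array with default metadata."""
    dosage = np.asarray(dosage)
    n, m = dosage.shape
    markers = pd.DataFrame(
        {
            "chrom": ["1"] * m if chrom is None else list(chrom),
            "pos": np.arange(1, m + 1) * 1000 if pos is None else list(pos),
            "ref": "A",
            "alt": "T",
        }
    )
    for key, val in marker_cols.items():
        markers[key] = val
    ids = np.array([f"ind{i:04d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(dosage=dosage, individual_ids=ids, markers=markers)


def hwe_geno(rng, n, m, freq_range=(0.05, 0.95), n_chrom=1) -> GenotypeMatrix:
    """Random HWE genotypes at uniform frequencies, split over chromosomes."""
    p = rng.uniform(*freq_range, size=m)
    dosage = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    per = m // n_chrom
    chrom = np.repeat([str(c + 1) for c in range(n_chrom)], per)[:m]
    pos = np.tile(np.arange(1, per + 1) * 100_000, n_chrom)[:m]
    return make_geno(dosage, chrom=chrom, pos=pos)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_experiment():
    """A small but complete simulated selection experiment, shared read-only."""
    from spgwas.simpop import SimConfig, simulate_experiment

    cfg = SimConfig(
        n_chromosomes=2,
        markers_per_chromosome=60,
        n_plants_per_plot=300,
        n_qtl=8,
        seed=11,
    )
    return simulate_experiment(cfg)
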