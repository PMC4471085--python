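import numpy as np
import pandas as pd
import pytest

from fstscan import GenotypeMatrix, SimConfig, simulate_genotypes


def make_matrix(dosages, chrom=None, pos=None, pops=None):
    """Small GenotypeMatrix from a plain nested list of dosages."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_loci = dosages.shape
    chrom = chrom if chrom is not None else [1] * n_loci
    pos = pos if pos is not None else [1000 * (j + 1) for j in range(n_loci)]
    pops = pops if pops is not None else ["P1"] * n_samples
    loci = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"snp{j}" for j in range(n_loci)],
            "ref": "A",
            "alt": "B",
        }
    )
    samples = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(n_samples)], "population": pops}
    )
    return GenotypeMatrix(dosages=dosages, loci=loci, samples=samples)


@pytest.fixture(scope="session")
def small_sim():
    """Three populations, two chromosomes, no sweeps; reused read-only."""
    cfg = SimConfig(
        n_chrom=2,
        chrom_length_bp=10_000_000,
        n_per_pop=40,
        snp_spacing_bp=50_000,
        drift_F=0.15,
        missing_rate=0.02,
        seed=42,
    )
    gm, truth = simulate_genotypes(cfg)
    return cfg, gm, truth


@pytest.fixture(scope="session")
def sweep_sim():
    """Simulation with planted sweeps for power-style checks."""
    cfg = SimConfig(
        n_chrom=6,
        chrom_length_bp=30_000_000,
        n_per_pop=50,
        snp_spacing_bp=50_000,
        drift_F=0.05,
        n_sweep_regions=1,
        sweep_width_bp=300_000,
        sweep_shift=0.45,
        seed=7,
    )
    gm, truth = simulate_genotypes(cfg)
    return cfg, gm, truth
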