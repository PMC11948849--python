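import numpy as np
import pytest

import pollenpop as pp


@pytest.fixture(scope="session")
def drift_panel():
    """Two populations, mild drift, no sweeps: 2x50 individuals, 2000 SNPs."""
    cfg = pp.SimConfig(seed=1, n_pop_a=50, n_pop_b=50, n_snps=2000, drift_F=0.05)
    geno, truth = pp.simulate_genotypes(cfg)
    return cfg, geno, truth


@pytest.fixture(scope="session")
def labeled_particles():
    """1000 particles (10 individuals x 100), 10% of each contaminant class."""
    cfg = pp.SimConfig(
        seed=7,
        pollen_per_individual=100,
        contaminant_rates={
            "aborted": 0.1,
            "stacked": 0.1,
            "debris": 0.1,
            "blurred": 0.1,
        },
    )
    individuals = [f"I{i:02d}" for i in range(10)]
    particles, truth = pp.simulate_mifc_particles(individuals, cfg)
    return particles, truth


@pytest.fixture(scope="session")
def heritable_panel():
    """400 individuals, 2000 SNPs, polygenic trait at h2 = 0.8."""
    cfg = pp.SimConfig(
        seed=3, n_pop_a=200, n_pop_b=200, n_snps=2000, h2=0.8, n_qtl=200
    )
    geno, _ = pp.simulate_genotypes(cfg)
    pheno, truth = pp.simulate_phenotypes(geno, cfg)
    return cfg, geno, pheno, truth


@pytest.fixture(scope="session")
def qtl_panel():
    """400 individuals, one planted QTL explaining 10% of trait variance."""
    cfg = pp.SimConfig(seed=11, n_pop_a=200, n_pop_b=200, n_snps=2000, h2=0.10, n_qtl=1)
    geno, _ = pp.simulate_genotypes(cfg)
    pheno, truth = pp.simulate_phenotypes(geno, cfg)
    causal = list(truth.causal_effects)[0]
    return cfg, geno, pheno["trait"].to_numpy(), causal


def toy_genotable(calls, depths=None, chrom=None, pos=None, ref=None, alt=None):
    """Small hand-specified GenotypeTable for oracle tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if depths is None:
        depths = np.full((n, m), 20)
    return pp.GenotypeTable(
        individuals=[f"s{i}" for i in range(n)],
        chrom=np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, m + 1) * 1000),
        ref=np.array(ref if ref is not None else ["A"] * m, dtype=object),
        alt=np.array(alt if alt is not None else ["T"] * m, dtype=object),
        calls=calls,
        depths=np.asarray(depths, dtype=np.int32),
    )
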