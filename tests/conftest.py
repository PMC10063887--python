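import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from racesig import simulate as sim


@pytest.fixture(scope="session")
def race_panel():
    """Small 5-race panel with 10 single-race PAV genes, error-free genomes."""
    pavs = [
        sim.PavSpec(f"gene{g:04d}",
                    [p for p in sim.RACE_NAMES if p != sim.RACE_NAMES[g % 5]])
        for g in range(1, 11)
    ]
    cfg = sim.SimConfig(
        seed=7, n_chromosomes=1, chrom_length=60_000, n_populations=5,
        pop_sizes=[2] * 5, fst_targets=0.1, theta=1e-3, n_genes=20,
        pav_specs=pavs,
    )
    return cfg, sim.simulate_genomes(cfg)


@pytest.fixture(scope="session")
def neutral_hap():
    """Single-population neutral panel, 50 diploids over 1 Mb."""
    cfg = sim.SimConfig(
        seed=2, n_chromosomes=1, chrom_length=1_000_000, n_populations=1,
        pop_sizes=[50], fst_targets=0.0, theta=1e-3, freq_model="neutral",
    )
    hap, _ = sim.simulate_haplotypes(sim.simulate_frequencies(cfg), cfg)
    return cfg, hap


@pytest.fixture(scope="session")
def two_pop_vcf(tmp_path_factory):
    """Two-population panel written to VCF, plus its config and matrix."""
    cfg = sim.SimConfig(
        seed=11, n_chromosomes=2, chrom_length=50_000, n_populations=2,
        pop_sizes=[6, 6], fst_targets=0.15, theta=1e-3, n_genes=10,
    )
    path = tmp_path_factory.mktemp("vcf") / "panel.vcf"
    hap, _ = sim.simulate_haplotypes(sim.simulate_frequencies(cfg), cfg,
                                     vcf_path=path)
    return cfg, hap, str(path)


def random_haplotypes(rng: np.random.Generator, n_hap: int, n_sites: int,
                      ensure_polymorphic: bool = True) -> np.ndarray:
    """Random 0/1 haplotype block; optionally guarantees >= 1 segregating site."""
    while True:
        block = (rng.uniform(size=(n_hap, n_sites)) < rng.uniform(0.1, 0.9)).astype(np.int8)
        counts = block.sum(axis=0)
        if not ensure_polymorphic or np.any((counts > 0) & (counts < n_hap)):
            return block
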