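import numpy as np
import pandas as pd
import pytest

from sexscan.core import GenotypeTable, PedigreeTable, MARKER_COLUMNS
from sexscan.simulate import CrossConfig, simulate_f2


def make_gt(g, depth=None, chrom=None, bp=None, samples=None) -> GenotypeTable:
    """Build a small GenotypeTable from a genotype matrix."""
    g = np.asarray(g, dtype=np.int8)
    n_sites, n_samples = g.shape
    if depth is None:
        depth = np.full_like(g, 30, dtype=np.int32)
    if chrom is None:
        chrom = ["chr01"] * n_sites
    if bp is None:
        bp = np.arange(1, n_sites + 1) * 1000
    if samples is None:
        samples = [f"S{i}" for i in range(n_samples)]
    markers = pd.DataFrame({
        "chrom": chrom, "bp": bp,
        "marker_id": [f"{c}_{p}" for c, p in zip(chrom, bp)],
        "ref": ["A"] * n_sites, "alt": ["T"] * n_sites,
    })[MARKER_COLUMNS]
    return GenotypeTable(markers, list(samples), g, np.asarray(depth, dtype=np.int32))


def make_ped(samples, generation=None, sex=None, family=None, species=None) -> PedigreeTable:
    n = len(samples)
    return PedigreeTable(pd.DataFrame({
        "sample_id": list(samples),
        "generation": generation or ["F2"] * n,
        "family": family or ["A"] * n,
        "sex": sex or ["M"] * n,
        "species": species or ["-"] * n,
    }))


def f2_sex_ped(n_males, n_females):
    """F2-only pedigree: males S0..., then females."""
    samples = [f"S{i}" for i in range(n_males + n_females)]
    sex = ["M"] * n_males + ["F"] * n_females
    return samples, make_ped(samples, sex=sex)


@pytest.fixture(scope="session")
def xy_cross():
    """A moderately sized fully penetrant XY cross used by several tests."""
    cfg = CrossConfig(n_chromosomes=4, chrom_lengths_bp=30_000_000,
                      chrom_lengths_cM=50.0, n_markers=1000, n_f2=150,
                      n_families=2, sd_system="XY", sd_chromosome=1,
                      sd_position_cM=25.0, seed=2024)
    gt, ped, truth = simulate_f2(cfg)
    return cfg, gt, ped, truth


@pytest.fixture(scope="session")
def zw_cross():
    cfg = CrossConfig(n_chromosomes=4, chrom_lengths_bp=30_000_000,
                      chrom_lengths_cM=50.0, n_markers=1000, n_f2=150,
                      n_families=2, sd_system="ZW", sd_chromosome=2,
                      sd_position_cM=20.0, seed=515)
    gt, ped, truth = simulate_f2(cfg)
    return cfg, gt, ped, truth
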