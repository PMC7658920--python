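import numpy as np
import pandas as pd
import pytest

from medseqdmr import (
    GroupComparison,
    generate_genome,
    generate_methylation_profiles,
    simulate_sample_sheet,
    simulate_site_counts,
)


@pytest.fixture(scope="session")
def genome_small():
    """Three-chromosome genome (one flagged as sex) used across modules."""
    return generate_genome(
        {"chr1": 30_000, "chr2": 20_000, "chrX": 10_000},
        cpg_rate=0.05,
        n_genes=8,
        n_islands=5,
        sex_chrom_names={"chrX"},
        seed=7,
    )


@pytest.fixture(scope="session")
def sheet():
    return simulate_sample_sheet(seed=7)


@pytest.fixture(scope="session")
def groups(sheet):
    return GroupComparison.from_sample_sheet(sheet)


@pytest.fixture(scope="session")
def null_matrix(genome_small, sheet):
    """Poisson site counts with no injected group difference."""
    profile, _ = generate_methylation_profiles(
        genome_small, sheet, [], noise_sd=0.0, seed=70
    )
    return simulate_site_counts(profile, mean_depth=30, dispersion=0.0, seed=71)


def brute_force_cg_positions(sequence: str) -> list[int]:
    return [i for i in range(len(sequence) - 1) if sequence[i : i + 2] == "CG"]


@pytest.fixture(scope="session")
def cg_oracle():
    return brute_force_cg_positions
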