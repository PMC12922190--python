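"""Shared fixtures: small genomes/populations for unit tests, a reduced-scale
scenario configuration for strategy contrasts, and the full-scale baseline
replicates shared by the acceptance tests."""

import numpy as np
import pytest

from breedsim import build_genome, sample_founders
from breedsim.pipeline import StrategyConfig, run_replicates


@pytest.fixture(scope="session")
def tiny_genome():
    return build_genome(3, n_chr=3, chr_length=1.0, n_snp=120, n_qtl=30)


@pytest.fixture()
def tiny_founders(tiny_genome):
    return sample_founders(tiny_genome, n=60, seed=5)


def reduced_config(**overrides) -> StrategyConfig:
    """Scaled-down study conditions: same structure as the full program
    (2:5 sex ratio, phenotypic burn-in, GBLUP truncation selection) on a
    smaller genome and cohort so a replicate runs in seconds."""
    base = dict(
        n_chr=5, chr_length=1.0, n_snp=1500, n_qtl=150,
        n_founders=250, n_offspring=250, n_production=250,
        n_males=10, n_females=25, burnin_males=10, burnin_females=25,
        burnin_generations=5, n_generations=15, compute_msv=False,
    )
    base.update(overrides)
    return StrategyConfig(**base)


@pytest.fixture(scope="session")
def reduced_baseline():
    """Six reduced-scale baseline replicates (seeds 900..905)."""
    return run_replicates(reduced_config(), 6, 900)


@pytest.fixture(scope="session")
def full_baseline():
    """Three full-scale baseline replicates of the reference breeding
    program; shared by all baseline acceptance checks."""
    return run_replicates(StrategyConfig(), 3, 7021)
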