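import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from codonuse import (
    IndexConfig,
    SyntheticGenomeSpec,
    simulate_expression,
    simulate_genome,
    simulate_tdr_table,
    simulate_trna_pool,
    standard_code,
)


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_genome():
    """A 30-gene synthetic genome with its expression and auxiliary tables."""
    gen = simulate_genome(SyntheticGenomeSpec(n_genes=30, length_codons=120, seed=7))
    expr = simulate_expression(gen.beta, noise_sd=0.3, seed=8)
    pool = simulate_trna_pool(gen.optimal_codon_map)
    tdr = simulate_tdr_table(seed=9, optimal_codon_map=gen.optimal_codon_map)
    return gen, expr, pool, tdr


@pytest.fixture(scope="session")
def small_config(small_genome):
    gen, expr, pool, tdr = small_genome
    return IndexConfig(expression=expr, trna_pool=pool, mrna=expr, tdr=tdr)
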