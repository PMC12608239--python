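import dataclasses

import numpy as np
import pytest

from recmap.synthetic_data import SimConfig, simulate_dataset


def small_config(**overrides) -> SimConfig:
    """A fast, small-scale variant of the default simulation."""
    base = dict(
        seed=7,
        chrom_length_bp=2_000_000,
        n_snps=400,
        causal_pos=1_000_000,
        n_offspring_per_cross=150,
        pool_sizes={"affected_pool_1": 20, "affected_pool_2": 20,
                    "unaffected_pool": 30},
        share_flank_bp=300_000,
        second_causal_offset_bp=600_000,
        n_genes=30,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
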