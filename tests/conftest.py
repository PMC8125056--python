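import numpy as np
import pandas as pd
import pytest

from otunet.containers import OtuTable, SampleMetadata
from otunet.simulate import SimConfig, simulate_dataset


@pytest.fixture
def small_table() -> OtuTable:
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(6, 8))
    counts[:, -1] = 0  # one never-observed OTU
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"S{i}" for i in range(6)],
            columns=[f"OTU{j}" for j in range(8)],
        )
    )


@pytest.fixture
def small_metadata(small_table) -> SampleMetadata:
    groups = ["grains", "grains", "grains", "flesh", "flesh", "flesh"]
    return SampleMetadata(
        pd.DataFrame(
            {
                "host_species": [f"sp{i % 2}" for i in range(6)],
                "feeding_habit": ["granivore"] * 3 + ["carnivore"] * 3,
                "diet_group": groups,
            },
            index=small_table.sample_ids,
        )
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """One deterministic draw of the tiny study design, shared across tests."""
    cfg = SimConfig(
        n_samples=24,
        n_otus=60,
        group_names=("fruits", "flesh"),
        n_species=6,
        depth_mean=4000.0,
        depth_sd=900.0,
        n_blocks=2,
        block_sizes=(8, 8),
        negative_pair=(0, 1),
        effect_otus_per_group=4,
        n_phylo_otus=8,
        sparsity_target=0.4,
        seed=20240917,
    )
    return simulate_dataset(cfg)
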