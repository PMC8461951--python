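import numpy as np
import pandas as pd
import pytest

from sigmap.containers import ExpressionMatrix
from sigmap.synthetic_data import (
    BlockSpec,
    CompendiumSpec,
    generate_compendium,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def four_block_spec(
    n_per_group: int = 6,
    block_size: int = 25,
    n_features: int = 150,
    noise_sd: float = 0.25,
    seed: int = 7,
) -> CompendiumSpec:
    """Compendium with 4 disjoint blocks, each elevated in one of 4 groups."""
    groups = tuple((f"family_{i}", n_per_group) for i in range(4))
    blocks = tuple(
        BlockSpec(
            feature_indices=tuple(range(i * block_size, (i + 1) * block_size)),
            high_groups=(f"family_{i}",),
            effect_log2=2.0,
        )
        for i in range(4)
    )
    return CompendiumSpec(
        groups=groups, n_features=n_features, blocks=blocks, noise_sd=noise_sd, seed=seed
    )


@pytest.fixture
def planted_compendium():
    """Four reference families, four disjoint co-expression blocks."""
    return generate_compendium(four_block_spec())


@pytest.fixture
def planted_block_of():
    """feature_id -> planted block index for the four_block_spec layout."""
    spec = four_block_spec()
    comp = generate_compendium(spec)
    mapping = {}
    for b_i, block in enumerate(spec.blocks):
        for idx in block.feature_indices:
            mapping[comp.expr.features[idx]] = b_i
    return mapping


def small_matrix(values, scale="log2", prefix="f"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])],
        ),
        scale=scale,
    )
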