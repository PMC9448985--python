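import numpy as np
import pytest

from lncda.network import BipartiteAdjacency, EntityRegistry


def adjacency(values, row_kind="lncRNA", col_kind="disease",
              row_prefix=None, col_prefix=None) -> BipartiteAdjacency:
    """Build a labeled adjacency from a nested list with auto-named entities."""
    values = np.asarray(values)
    prefixes = {"lncRNA": "L", "miRNA": "M", "disease": "D"}
    rp = row_prefix or prefixes[row_kind]
    cp = col_prefix or prefixes[col_kind]
    rows = EntityRegistry(row_kind, tuple(f"{rp}{i+1}" for i in range(values.shape[0])))
    cols = EntityRegistry(col_kind, tuple(f"{cp}{j+1}" for j in range(values.shape[1])))
    return BipartiteAdjacency(rows, cols, values)


def random_adjacency(rng, n_rows, n_cols, density=0.4, **kwargs) -> BipartiteAdjacency:
    values = (rng.random((n_rows, n_cols)) < density).astype(int)
    return BipartiteAdjacency and adjacency(values, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_ld():
    """The 2x3 matrix behind the hand-worked Jaccard/GIP values."""
    return adjacency([[1, 0, 1], [1, 1, 0]])


@pytest.fixture
def small_network():
    """A small planted tripartite network shared by pipeline-level tests."""
    from lncda.synthetic import SyntheticConfig, generate_network

    cfg = SyntheticConfig(
        l=40, m=50, d=30, rank=4,
        ld_density=0.08, lm_density=0.08, md_density=0.12,
        holdout_fraction=0.1, seed=77,
    )
    return generate_network(cfg)
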