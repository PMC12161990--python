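import numpy as np
import pytest

from resort import FixtureSpec, SpatialCounts, make_reference


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_spec():
    return FixtureSpec(
        fine_types=["a1", "a2", "b1"],
        grouping={"a1": "A", "a2": "A", "b1": "B"},
        n_genes=60,
        markers_per_type=5,
        cells_per_type=30,
    )


@pytest.fixture
def tiny_ref(tiny_spec, rng):
    return make_reference(tiny_spec, rng)


def random_spatial_counts(rng, n_rows=4, n_cols=5, n_genes=7):
    n = n_rows * n_cols
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    return SpatialCounts(
        counts=rng.integers(0, 20, size=(n, n_genes)),
        gene_ids=[f"g{j}" for j in range(n_genes)],
        spot_ids=[f"s{i}" for i in range(n)],
        coords=np.column_stack([rr.ravel(), cc.ravel()]),
    )


@pytest.fixture
def small_counts(rng):
    return random_spatial_counts(rng)
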