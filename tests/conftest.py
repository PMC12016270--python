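import numpy as np
import pytest

from pertbench import PerturbDataset, SimConfig, normalize_counts, simulate_study


@pytest.fixture
def tiny_counts():
    """Hand-built 8-cell, 4-gene count dataset: ctrl + 2 perturbations."""
    matrix = np.array(
        [
            [10, 5, 1, 4],
            [12, 6, 0, 2],
            [11, 5, 2, 2],
            [30, 1, 1, 8],  # gA cells: gA up, gB down
            [28, 2, 0, 10],
            [5, 5, 20, 10],  # gC cells: gC up
            [6, 4, 18, 12],
            [4, 6, 22, 8],
        ],
        dtype=float,
    )
    conditions = np.array(["ctrl"] * 3 + ["gA"] * 2 + ["gC"] * 3, dtype=object)
    return PerturbDataset(matrix=matrix, conditions=conditions,
                          gene_names=np.array(["gA", "gB", "gC", "gD"], dtype=object))


@pytest.fixture
def tiny_normalized(tiny_counts):
    return normalize_counts(tiny_counts)


@pytest.fixture(scope="session")
def small_study():
    """Seeded synthetic study reused across modules (cheap to simulate)."""
    cfg = SimConfig(
        n_genes=200,
        n_perturbations=10,
        cells_per_condition=20,
        control_cells=60,
        shared_fraction=0.3,
        count_depth=2000,
        seed=7,
    )
    ds, truth, emb = simulate_study(cfg)
    return cfg, ds, truth, emb
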