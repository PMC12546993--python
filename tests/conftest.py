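import numpy as np
import pytest

from microst.cooccurrence import normalize_adjacency
from microst.preprocess import prepare_datasets
from microst.synthetic import SimulatorSpec, simulate_series
from microst.tables_io import AbundanceTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table():
    """3 taxa x 4 samples with taxonomy, used across I/O tests."""
    return AbundanceTable(
        taxon_ids=["otu1", "otu2", "otu3"],
        sample_ids=["d1", "d2", "d3", "d4"],
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [0.0, 5.0, 0.0, 1.0],
                [2.0, 2.0, 2.0, 2.0],
            ]
        ),
        taxonomy=[
            "k__Bacteria;p__Firmicutes;c__Bacilli;o__;f__;g__Rothia",
            "k__Bacteria;p__Firmicutes;c__Bacilli;o__;f__;g__Rothia",
            "k__Bacteria;p__Proteobacteria;c__;o__;f__;g__Neisseria",
        ],
    )


def true_adjacency(phi):
    """Ground-truth normalized adjacency from a simulator transition matrix."""
    graph = phi - np.diag(np.diag(phi))
    return normalize_adjacency(graph)


@pytest.fixture(scope="session")
def coupled_data():
    """Graph-coupled noisy series with its ground-truth Ahat and splits.

    Small enough (D=8, T=160) for unit-level training tests; the
    acceptance suite uses the full-size stated world separately.
    """
    spec = SimulatorSpec(
        n_taxa=8, n_steps=160, density=0.3, sigma_noise=0.3, seed=11
    )
    series, phi = simulate_series(spec)
    train_set, val_set, params = prepare_datasets(series, 8, 1, 0.8)
    return {
        "spec": spec,
        "series": series,
        "phi": phi,
        "a_hat": true_adjacency(phi),
        "train": train_set,
        "val": val_set,
        "standardizer": params,
    }
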