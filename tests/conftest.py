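"""Shared fixtures: one default simulated dataset and its derived objects,
generated once per session since several suites interrogate the same run."""

import numpy as np
import pytest

import gradprof as gp


@pytest.fixture(scope="session")
def dataset():
    return gp.simulate(gp.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def rna_norm(dataset):
    return gp.normalize_profiles(dataset.rna, min_total=1.0)


@pytest.fixture(scope="session")
def prot_norm(dataset):
    return gp.normalize_profiles(dataset.protein, min_total=0.0)


@pytest.fixture(scope="session")
def clusters_all(rna_norm):
    return gp.hierarchical_cluster(rna_norm)


@pytest.fixture(scope="session")
def clusters_filtered(clusters_all):
    return gp.filter_clusters_by_size(clusters_all, min_size=20)


@pytest.fixture()
def small_matrix():
    """A tiny 4-gene, 4-fraction raw matrix for unit tests."""
    return gp.FractionProfileMatrix(
        entity_ids=["g1", "g2", "g3", "g4"],
        fraction_indices=np.array([3, 4, 5, 6]),
        values=np.array([
            [1.0, 1.0, 2.0, 0.0],
            [0.0, 2.0, 2.0, 4.0],
            [5.0, 3.0, 1.0, 1.0],
            [2.0, 2.0, 2.0, 2.0],
        ]),
        entity_kind="rna",
    )
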