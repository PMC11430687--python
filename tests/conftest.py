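"""Shared fixtures and helpers for the dynlayer test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dynlayer import MultilayerNetwork, PartitionEnsemble
from dynlayer.community import MultilayerPartition


def make_network(intra: np.ndarray, omega: np.ndarray,
                 similarity: str = "literal") -> MultilayerNetwork:
    """Build a MultilayerNetwork directly from weighted layers and couplings
    (bypassing TVFC), for hand-constructed test graphs."""
    adjacency = (intra > 0).astype(np.uint8)
    return MultilayerNetwork(intra=np.asarray(intra, dtype=float),
                             adjacency=adjacency,
                             omega=np.asarray(omega, dtype=float),
                             rule="positive", similarity=similarity)


def random_network(rng: np.random.Generator, n_nodes: int,
                   n_layers: int) -> MultilayerNetwork:
    """Random weighted multilayer network with symmetric layers in [0, 1]."""
    intra = np.empty((n_layers, n_nodes, n_nodes))
    for l in range(n_layers):
        w = rng.random((n_nodes, n_nodes))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        # occasionally sparsify so degenerate layers get exercised too
        w[w < rng.random() * 0.5] = 0.0
        intra[l] = w
    omega = rng.random((n_nodes, n_layers - 1))
    return make_network(intra, omega)


def ensemble_from_labels(*label_mats: np.ndarray) -> PartitionEnsemble:
    """Wrap explicit (N, T) label matrices as a partition ensemble; Q values
    are placeholders since only the labels matter for the metrics."""
    runs = [MultilayerPartition(labels=np.asarray(m, dtype=np.int64),
                                q_value=0.0, seed=r)
            for r, m in enumerate(label_mats)]
    return PartitionEnsemble(runs=runs, base_seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def two_cliques_3layers() -> MultilayerNetwork:
    """Two disconnected 3-node cliques, identical over 3 layers, ω = 1."""
    layer = np.zeros((6, 6))
    layer[:3, :3] = 1.0
    layer[3:, 3:] = 1.0
    np.fill_diagonal(layer, 0.0)
    intra = np.stack([layer] * 3)
    omega = np.ones((6, 2))
    return make_network(intra, omega)
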