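"""Multilayer community detection by modularity maximization.

The quality function couples per-layer Newman–Girvan terms with node-specific
rewards for keeping a node in the same community across adjacent layers:

    Q = (1/2μ) Σ_{ijlr} [ (A_ijl − γ_l k_il k_jl / 2m_l) δ_lr
                          + δ_ij ω_jlr ] δ(g_il, g_jr)

where k_il is the weighted degree of node i in layer l, m_l half the total
weight of layer l, γ_l the resolution (1 by default), and ω_jlr the
neighborhood-similarity coupling of node j, nonzero only for |l − r| = 1.
2μ normalizes by the total strength attached to all (node, layer) vertices:
Σ_{jl} k_jl plus the inter-layer couplings each vertex touches.

Optimization is a greedy two-phase (move + aggregate) heuristic in the
GenLouvain style on the supra-graph of (node, layer) vertices, with seeded
random sweep orders.  The move phase is re-entered at the finest level after
every aggregation round, so the returned partition is locally optimal: no
single supra-vertex move can increase Q.  An empty layer (m_l = 0)
contributes no null-model term rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._louvain import louvain_pass
from .multilayer import MultilayerNetwork

__all__ = [
    "MultilayerPartition",
    "PartitionEnsemble",
    "supra_modularity_matrix",
    "compute_modularity",
    "optimize",
    "run_ensemble",
]

# pass-level unnormalized-gain threshold below which phase 1 stops
_PASS_TOL = 1e-10


@dataclass(frozen=True)
class MultilayerPartition:
    """Community labels per (node, layer) with the achieved Q.

    ``labels`` has shape ``(N, T)`` and holds positive integer community ids,
    contiguous from 1 in order of first appearance; an id may span layers.
    """

    labels: np.ndarray
    q_value: float
    seed: int

    @property
    def n_communities(self) -> int:
        return int(len(np.unique(self.labels)))


@dataclass(frozen=True)
class PartitionEnsemble:
    """Independent seeded optimization runs over one subject's network.

    Run ``r`` uses seed ``base_seed + r``, so the ensemble is reproducible
    from ``base_seed`` alone.
    """

    runs: list[MultilayerPartition] = field(default_factory=list)
    base_seed: int = 0

    def __len__(self) -> int:
        return len(self.runs)

    @property
    def q_values(self) -> np.ndarray:
        return np.array([run.q_value for run in self.runs])

    def label_array(self) -> np.ndarray:
        """Stack run labels into an ``(R, N, T)`` array."""
        return np.stack([run.labels for run in self.runs])


def supra_modularity_matrix(network: MultilayerNetwork,
                            gamma: float | np.ndarray = 1.0
                            ) -> tuple[sp.csr_matrix, float]:
    """Supra modularity matrix B and the normalization 2μ.

    Supra-vertex ``u = l*N + i`` is node ``i`` in layer ``l``.  B carries the
    dense intra-layer modularity blocks on the block diagonal and the
    node-specific couplings on the two adjacent off-diagonals, so that
    ``Q = (1/2μ) Σ_{uv} B_uv δ(g_u, g_v)``.
    """
    A = network.intra
    T, N, _ = A.shape
    gammas = np.broadcast_to(np.asarray(gamma, dtype=float), (T,))
    blocks = []
    total_strength = 0.0
    for l in range(T):
        k = A[l].sum(axis=1)
        two_m = k.sum()
        total_strength += two_m
        if two_m > 0:
            block = A[l] - gammas[l] * np.outer(k, k) / two_m
        else:
            block = A[l].copy()
        blocks.append(sp.csr_matrix(block))
    B = sp.block_diag(blocks, format="csr")
    omega = network.omega
    nz_i, nz_t = np.nonzero(omega)
    if nz_i.size:
        u = nz_t * N + nz_i
        v = (nz_t + 1) * N + nz_i
        w = omega[nz_i, nz_t]
        coupling = sp.coo_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([u, v]), np.concatenate([v, u]))),
            shape=B.shape)
        B = (B + coupling).tocsr()
    two_mu = total_strength + 2.0 * omega.sum()
    return B, two_mu


def _modularity_from_supra(B: sp.csr_matrix, two_mu: float,
                           flat_labels: np.ndarray) -> float:
    if two_mu == 0:
        return 0.0
    coo = B.tocoo()
    same = flat_labels[coo.row] == flat_labels[coo.col]
    return float(coo.data[same].sum() / two_mu)


def compute_modularity(network: MultilayerNetwork, labels: np.ndarray,
                       gamma: float | np.ndarray = 1.0) -> float:
    """Multilayer modularity Q of a given ``(N, T)`` label matrix."""
    labels = np.asarray(labels)
    N, T = network.n_regions, network.n_layers
    if labels.shape != (N, T):
        raise ValueError(f"labels must have shape {(N, T)}, got {labels.shape}")
    B, two_mu = supra_modularity_matrix(network, gamma)
    return _modularity_from_supra(B, two_mu, labels.T.ravel())


def _relabel(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Compress labels to 0..K−1 in order of first appearance."""
    uniq, first, inv = np.unique(labels, return_index=True, return_inverse=True)
    rank = np.empty(uniq.size, dtype=np.int64)
    rank[np.argsort(first, kind="stable")] = np.arange(uniq.size)
    return rank[inv].astype(np.int64), uniq.size


def _phase1(B: sp.csr_matrix, labels: np.ndarray,
            rng: np.random.Generator) -> bool:
    """Sweep until no single-vertex move improves Q.  Mutates ``labels``."""
    n = labels.shape[0]
    sizes = np.bincount(labels, minlength=n).astype(np.int64)
    improved = False
    while True:
        order = rng.permutation(n)
        n_moves, gain = louvain_pass(B.indptr, B.indices, B.data,
                                     labels, sizes, order)
        if n_moves > 0:
            improved = True
        if n_moves == 0 or gain < _PASS_TOL:
            break
    return improved


def _aggregate(B: sp.csr_matrix, labels: np.ndarray, k: int) -> sp.csr_matrix:
    n = labels.shape[0]
    S = sp.csr_matrix((np.ones(n), (np.arange(n), labels)), shape=(n, k))
    return (S.T @ B @ S).tocsr()


def _optimize_labels(B: sp.csr_matrix, rng: np.random.Generator) -> np.ndarray:
    """Iterated move/aggregate cycles until the partition is locally optimal
    with respect to single supra-vertex moves."""
    labels = np.arange(B.shape[0], dtype=np.int64)
    while True:
        _phase1(B, labels, rng)
        labels, k = _relabel(labels)
        Bagg = _aggregate(B, labels, k)
        agg_labels = np.arange(k, dtype=np.int64)
        if not _phase1(Bagg, agg_labels, rng):
            break
        labels = agg_labels[labels]
    labels, _ = _relabel(labels)
    return labels


def _optimize_from_supra(B: sp.csr_matrix, two_mu: float, N: int, T: int,
                         seed: int) -> MultilayerPartition:
    rng = np.random.default_rng(seed)
    flat = _optimize_labels(B, rng)
    q = _modularity_from_supra(B, two_mu, flat)
    labels = (flat.reshape(T, N).T + 1).astype(np.int64)
    return MultilayerPartition(labels=labels, q_value=q, seed=seed)


def optimize(network: MultilayerNetwork, gamma: float | np.ndarray = 1.0,
             seed: int = 0) -> MultilayerPartition:
    """One seeded Louvain-style optimization of the multilayer modularity.

    The returned partition is locally optimal (no single supra-vertex move
    increases Q) and its ``q_value`` is recomputed from the labels.
    """
    B, two_mu = supra_modularity_matrix(network, gamma)
    return _optimize_from_supra(B, two_mu, network.n_regions,
                                network.n_layers, seed)


def run_ensemble(network: MultilayerNetwork, gamma: float | np.ndarray = 1.0,
                 n_runs: int = 100, base_seed: int = 0) -> PartitionEnsemble:
    """Ensemble of independently seeded optimization runs.

    The supra-modularity matrix is assembled once and shared by all runs;
    only the sweep randomization differs between runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    B, two_mu = supra_modularity_matrix(network, gamma)
    N, T = network.n_regions, network.n_layers
    runs = [_optimize_from_supra(B, two_mu, N, T, base_seed + r)
            for r in range(n_runs)]
    return PartitionEnsemble(runs=runs, base_seed=base_seed)
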