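"""Multilayer temporal network assembly.

A subject's multilayer network keeps two views of the same TVFC stack:

* the *weighted* clamped layers ``A[t]`` that enter the intra-layer
  modularity terms, and
* *binarized* layers ``a[t]`` used only to measure how similar a node's
  neighborhood is across adjacent timepoints.

The node-specific inter-layer coupling between layers ``t`` and ``t+1`` is a
neighborhood-overlap similarity of the binary layers,

    ω_i^{t,t+1} = Σ_j a_ij^t a_ij^{t+1} / (Σ_j a_ij^t · Σ_j a_ij^{t+1})

taken literally with the product of the two degree sums in the denominator
(``similarity="literal"``, the default).  Because the literal form makes ω
degree-dependent — identical neighborhoods of size k score 1/k — a binary
cosine variant with the square root of the product (``similarity="cosine"``)
is also provided.  Nodes isolated in either layer get ω = 0: no evidence of
persistence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tvfc import TVFCStack

__all__ = [
    "MultilayerNetwork",
    "binarize",
    "interlayer_coupling",
    "build_multilayer",
]

SIMILARITY_VARIANTS = ("literal", "cosine")


@dataclass(frozen=True)
class MultilayerNetwork:
    """Weighted intra-layer matrices plus per-node adjacent-layer couplings.

    Attributes
    ----------
    intra:
        ``(T, N, N)`` clamped weighted layers, entries in [0, 1].
    adjacency:
        ``(T, N, N)`` binary layers (0/1, symmetric, zero diagonal).
    omega:
        ``(N, T−1)`` couplings; ``omega[i, t]`` links node ``i`` between
        layers ``t`` and ``t+1``.  Entries lie in [0, 1].
    rule, similarity:
        The binarization rule and ω variant used, recorded for provenance.
    """

    intra: np.ndarray
    adjacency: np.ndarray
    omega: np.ndarray
    rule: str = "positive"
    similarity: str = "literal"

    @property
    def n_regions(self) -> int:
        return self.intra.shape[1]

    @property
    def n_layers(self) -> int:
        return self.intra.shape[0]

    def mean_coupling(self, per_node: bool = False) -> np.ndarray | float:
        """Inter-layer coupling strength: per-node mean over layer pairs, or
        the subject-level mean over nodes and layer pairs."""
        node_means = self.omega.mean(axis=1)
        return node_means if per_node else float(node_means.mean())


def _parse_rule(rule: str) -> tuple[str, float | None]:
    if rule == "positive":
        return "positive", None
    if rule.startswith("density:"):
        d = float(rule.split(":", 1)[1])
        if not 0.0 < d <= 1.0:
            raise ValueError(f"density must be in (0, 1], got {d}")
        return "density", d
    raise ValueError(f"unknown binarization rule {rule!r}")


def binarize(stack: TVFCStack, rule: str = "positive") -> np.ndarray:
    """Binarize a clamped TVFC stack into adjacency layers.

    ``rule="positive"`` keeps every edge with weight > 0 (phase difference
    below 90°).  ``rule="density:d"`` keeps, per layer, the strongest fraction
    ``d`` of off-diagonal weights; edges tied at the threshold weight are all
    kept, and zero-weight edges are never kept.
    """
    kind, d = _parse_rule(rule)
    if not stack.clamped:
        raise ValueError("binarize expects a clamped (non-negative) stack")
    W = stack.data
    if kind == "positive":
        return (W > 0).astype(np.uint8)
    T, N, _ = W.shape
    iu, ju = np.triu_indices(N, k=1)
    adj = np.zeros_like(W, dtype=np.uint8)
    n_keep = int(np.ceil(d * iu.size - 1e-9))
    for t in range(T):
        w = W[t, iu, ju]
        if n_keep >= w.size:
            thresh = 0.0
        else:
            thresh = np.sort(w)[::-1][n_keep - 1]
        keep = (w >= thresh) & (w > 0)
        adj[t, iu[keep], ju[keep]] = 1
        adj[t, ju[keep], iu[keep]] = 1
    return adj


def interlayer_coupling(a_t: np.ndarray, a_t1: np.ndarray,
                        similarity: str = "literal") -> np.ndarray:
    """ω for every node between two adjacent binary layers.

    Returns the length-N coupling vector.  If a node has zero degree in
    either layer its coupling is 0 by convention.
    """
    a_t = np.asarray(a_t)
    a_t1 = np.asarray(a_t1)
    if a_t.shape != a_t1.shape:
        raise ValueError(f"layer shape mismatch: {a_t.shape} vs {a_t1.shape}")
    if similarity not in SIMILARITY_VARIANTS:
        raise ValueError(f"similarity must be one of {SIMILARITY_VARIANTS}")
    shared = (a_t * a_t1).sum(axis=1).astype(float)
    deg_t = a_t.sum(axis=1).astype(float)
    deg_t1 = a_t1.sum(axis=1).astype(float)
    denom = deg_t * deg_t1
    if similarity == "cosine":
        denom = np.sqrt(denom)
    omega = np.divide(shared, denom, out=np.zeros_like(shared),
                      where=denom > 0)
    return omega


def build_multilayer(stack: TVFCStack, rule: str = "positive",
                     similarity: str = "literal") -> MultilayerNetwork:
    """Assemble the full multilayer network from a clamped TVFC stack.

    Weighted layers are retained as-is for the modularity intra-layer terms;
    binarized layers feed the neighborhood-similarity couplings for every
    node and every adjacent layer pair.
    """
    if stack.n_layers < 2:
        raise ValueError("need at least 2 layers to form adjacent-layer couplings")
    adjacency = binarize(stack, rule=rule)
    T, N, _ = adjacency.shape
    omega = np.empty((N, T - 1))
    for t in range(T - 1):
        omega[:, t] = interlayer_coupling(adjacency[t], adjacency[t + 1],
                                          similarity=similarity)
    return MultilayerNetwork(intra=stack.data, adjacency=adjacency,
                             omega=omega, rule=rule, similarity=similarity)
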