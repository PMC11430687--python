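"""JIT-compiled inner loop of the multilayer Louvain optimizer.

Operates on the supra-modularity matrix in CSR form.  One call performs one
full sweep over the supplied vertex order, greedily relocating each vertex to
the community with the largest strictly positive modularity gain (ties broken
toward the lowest community id).  Besides communities incident to the vertex,
a fresh singleton community is considered, which matters when the vertex's
links into its own community are net negative.  Gains are unnormalized
(2μ-free): the argmax is unaffected by the constant.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["louvain_pass"]


@njit(cache=True)
def louvain_pass(indptr, indices, data, labels, sizes, order):  # pragma: no cover
    """One move sweep.  Mutates ``labels`` and ``sizes`` in place.

    ``sizes[c]`` is the number of vertices currently labelled ``c`` (labels
    live in ``0..n−1``, so an empty slot always exists when a vertex needs a
    fresh community).  Returns ``(n_moves, total_gain)`` with ``total_gain``
    the sum of the strictly positive unnormalized gains of accepted moves.
    """
    n = labels.shape[0]
    acc = np.zeros(n, dtype=np.float64)
    touched = np.empty(n, dtype=np.int64)
    n_moves = 0
    total_gain = 0.0
    for oi in range(order.shape[0]):
        u = order[oi]
        cu = labels[u]
        n_touched = 0
        for k in range(indptr[u], indptr[u + 1]):
            v = indices[k]
            if v == u:
                continue  # self-term moves with u; cancels in the gain
            c = labels[v]
            if acc[c] == 0.0:
                touched[n_touched] = c
                n_touched += 1
            acc[c] += data[k]
        w_cu = acc[cu]
        best_c = cu
        best_gain = 0.0
        for k in range(n_touched):
            c = touched[k]
            if c == cu:
                continue
            gain = acc[c] - w_cu
            if gain > best_gain or (best_gain > 0.0 and gain == best_gain and c < best_c):
                best_gain = gain
                best_c = c
        for k in range(n_touched):
            acc[touched[k]] = 0.0
        # escaping to a fresh singleton pays off iff u's links home are net
        # negative and beat every incident community
        if w_cu < 0.0 and sizes[cu] > 1 and -w_cu > best_gain:
            best_gain = -w_cu
            best_c = -1
        if best_c != cu and best_gain > 0.0:
            if best_c == -1:
                for c in range(n):
                    if sizes[c] == 0:
                        best_c = c
                        break
            labels[u] = best_c
            sizes[cu] -= 1
            sizes[best_c] += 1
            n_moves += 1
            total_gain += best_gain
    return n_moves, total_gain
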