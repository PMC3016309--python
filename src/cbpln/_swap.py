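"""JIT-compiled inner loop for degree-preserving edge-swap randomization.

The kernel mutates flat endpoint arrays in place; edge weights stay attached
to their array slot, so the weight multiset is preserved and the surviving
endpoint of each original edge deterministically keeps its weight. All
randomness (edge-pair indices, orientation bits) is drawn outside the kernel
with a seeded numpy Generator.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _swap_kernel(eu, ev, adj, pair_i, pair_j, orient):  # pragma: no cover - compiled
    for t in range(pair_i.shape[0]):
        i = pair_i[t]
        j = pair_j[t]
        if i == j:
            continue
        u = eu[i]
        v = ev[i]
        x = eu[j]
        y = ev[j]
        if orient[t] == 1:
            a1, b1, a2, b2 = u, y, x, v
        else:
            a1, b1, a2, b2 = u, x, v, y
        if a1 == b1 or a2 == b2:
            continue  # self-loop
        if adj[a1, b1] or adj[a2, b2]:
            continue  # candidate already exists
        if (a1 == a2 and b1 == b2) or (a1 == b2 and b1 == a2):
            continue  # both candidates are the same edge
        adj[u, v] = False
        adj[v, u] = False
        adj[x, y] = False
        adj[y, x] = False
        adj[a1, b1] = True
        adj[b1, a1] = True
        adj[a2, b2] = True
        adj[b2, a2] = True
        eu[i] = a1
        ev[i] = b1
        eu[j] = a2
        ev[j] = b2


def swap_edge_arrays(
    eu: np.ndarray,
    ev: np.ndarray,
    n_nodes: int,
    q: int,
    rng: np.random.Generator,
) -> tuple:
    """Return rewired copies of (eu, ev) after q * |E| swap attempts.

    Each attempt picks two edge slots uniformly; picking the same slot twice
    is a no-op attempt. Degrees, the node set and the per-slot weights are
    untouched by construction.
    """
    eu = eu.copy()
    ev = ev.copy()
    n_edges = eu.shape[0]
    attempts = int(q) * n_edges
    if attempts == 0 or n_edges < 2:
        return eu, ev
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    adj[eu, ev] = True
    adj[ev, eu] = True
    pair_i = rng.integers(0, n_edges, size=attempts)
    pair_j = rng.integers(0, n_edges, size=attempts)
    orient = rng.integers(0, 2, size=attempts)
    _swap_kernel(eu, ev, adj, pair_i, pair_j, orient.astype(np.int64))
    return eu, ev
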