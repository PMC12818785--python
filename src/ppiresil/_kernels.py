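"""Compiled union-find kernels for fragmentation-entropy simulation.

The resilience metrics require component-size partitions of a graph under
~10^5–10^6 independent random node-isolation events per network; a per-call
union-find over the edge array is orders of magnitude cheaper than building
a graph object per event.  Entropy is evaluated in the algebraically
equivalent form

    H = 1 - (sum_i s_i * ln s_i) / (N * ln N),

which makes the two anchor values exact in floating point: an intact
connected graph gives H = 0 and a fully isolated one gives H = 1, with no
rounding residue from ``log(1/N)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["entropy_isolated_batch", "component_roots"]


@njit(cache=True)
def _find(parent, i):
    while parent[i] != i:
        parent[i] = parent[parent[i]]
        i = parent[i]
    return i


@njit(cache=True)
def entropy_isolated_batch(u, v, n, removed):  # pragma: no cover - exercised via wrappers
    """Fragmentation entropy after isolating each row of ``removed``.

    Parameters
    ----------
    u, v : int64[:]
        Edge endpoint indices (0..n-1).
    n : int
        Node count of the reference network (the entropy normalizer).
    removed : int64[:, :]
        One row per replicate; the node indices isolated in that replicate
        (all incident edges dropped, nodes kept as singletons).

    Returns
    -------
    float64[:]
        H value per replicate, each in [0, 1].
    """
    reps = removed.shape[0]
    m = removed.shape[1]
    out = np.empty(reps, np.float64)
    parent = np.empty(n, np.int64)
    size = np.empty(n, np.int64)
    alive = np.empty(n, np.bool_)
    log_norm = n * np.log(n)
    for r in range(reps):
        for i in range(n):
            parent[i] = i
            size[i] = 0
            alive[i] = True
        for j in range(m):
            alive[removed[r, j]] = False
        for e in range(u.size):
            a = u[e]
            b = v[e]
            if alive[a] and alive[b]:
                ra = _find(parent, a)
                rb = _find(parent, b)
                if ra != rb:
                    parent[rb] = ra
        for i in range(n):
            if alive[i]:
                size[_find(parent, i)] += 1
        acc = 0.0
        for i in range(n):
            if size[i] > 1:
                acc += size[i] * np.log(np.float64(size[i]))
        out[r] = 1.0 - acc / log_norm
    return out


@njit(cache=True)
def component_roots(u, v, n, alive):  # pragma: no cover - exercised via wrappers
    """Connected-component root label per node; -1 for nodes not alive."""
    parent = np.empty(n, np.int64)
    for i in range(n):
        parent[i] = i
    for e in range(u.size):
        a = u[e]
        b = v[e]
        if alive[a] and alive[b]:
            ra = _find(parent, a)
            rb = _find(parent, b)
            if ra != rb:
                parent[rb] = ra
    roots = np.empty(n, np.int64)
    for i in range(n):
        roots[i] = _find(parent, i) if alive[i] else -1
    return roots
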