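"""JIT-compiled coalescent kernels for unlinked-site simulation.

Simulating one independent genealogy per SNP (the structure of a
one-SNP-per-locus reduced-representation dataset) needs thousands of
small event-driven simulations per dataset; these kernels run the
two-deme coalescent with an optional exponentially growing deme entirely
inside numba.  Randomness uses numba's thread-local legacy RNG, seeded
per dataset, so results are reproducible for a given seed.
"""

from __future__ import annotations

import math

import numba as nb
import numpy as np


@nb.njit(cache=True)
def _exp_wait(k: int, t0: float, x_present: float, alpha: float) -> float:
    """Waiting time to coalescence among k lineages in a deme of relative
    size x(t) = x_present * exp(-alpha t) backward in time."""
    if k < 2:
        return np.inf
    rate0 = k * (k - 1) / x_present
    e = np.random.exponential(1.0)
    if alpha == 0.0:
        return e / rate0
    arg = math.exp(alpha * t0) + e * alpha / rate0
    if arg <= 0.0:
        return np.inf
    return math.log(arg) / alpha - t0


@nb.njit(cache=True)
def _coalesce(pool: np.ndarray, off: int, k: int, nxt: int, t: float,
              parent: np.ndarray, times: np.ndarray,
              child1: np.ndarray, child2: np.ndarray) -> int:
    """Merge a uniform random pair in pool[off : off + k]; returns k - 1."""
    i = np.random.randint(k)
    j = np.random.randint(k - 1)
    if j >= i:
        j += 1
    a, b = pool[off + i], pool[off + j]
    child1[nxt] = a
    child2[nxt] = b
    times[nxt] = t
    parent[a] = nxt
    parent[b] = nxt
    hi = i if i > j else j
    lo = j if i > j else i
    pool[off + hi] = pool[off + k - 1]      # remove hi (swap with last)
    k -= 1
    pool[off + lo] = pool[off + k - 1]      # remove lo
    k -= 1
    pool[off + k] = nxt                     # append merged lineage
    return k + 1


@nb.njit(cache=True)
def _genealogy(
    model: int, ct: float,
    x1: float, a1: float, x2: float, a2: float,
    n1: int, n2: int,
    parent: np.ndarray, times: np.ndarray,
    child1: np.ndarray, child2: np.ndarray,
    pool: np.ndarray,
) -> None:
    """One two-deme genealogy written into the preallocated arrays.

    ``pool`` slots [0, k1) hold deme-1 lineages and [n, n + k2) deme-2
    lineages (n = n1 + n2).  Time is in units of 4*Ne generations.
    """
    n = n1 + n2
    for i in range(2 * n - 1):
        parent[i] = -1
        times[i] = 0.0
        child1[i] = -1
        child2[i] = -1
    for i in range(n1):
        pool[i] = i
    for i in range(n2):
        pool[n + i] = n1 + i
    k1, k2 = n1, n2
    nxt = n
    t = 0.0

    if model != 1 and ct > 0.0:
        while t < ct and k1 + k2 > 1:
            w1 = _exp_wait(k1, t, x1, a1)
            w2 = _exp_wait(k2, t, x2, a2)
            w = w1 if w1 <= w2 else w2
            if not np.isfinite(w) or t + w >= ct:
                break
            t += w
            if w1 <= w2:
                k1 = _coalesce(pool, 0, k1, nxt, t, parent, times, child1, child2)
            else:
                k2 = _coalesce(pool, n, k2, nxt, t, parent, times, child1, child2)
            nxt += 1
        t = ct

    # merge demes into one constant-size ancestral pool
    for i in range(k2):
        pool[k1 + i] = pool[n + i]
    k = k1 + k2
    while k > 1:
        t += np.random.exponential(1.0 / (k * (k - 1)))
        k = _coalesce(pool, 0, k, nxt, t, parent, times, child1, child2)
        nxt += 1


@nb.njit(cache=True)
def unlinked_matrix(
    model: int, ct: float,
    x1: float, a1: float, x2: float, a2: float,
    n1: int, n2: int, n_sites: int, seed: int,
) -> np.ndarray:
    """(haploids x sites) 0/1 matrix with one independent genealogy per
    site and exactly one mutation per site, placed on an edge chosen
    proportionally to its length."""
    np.random.seed(seed)
    n = n1 + n2
    n_nodes = 2 * n - 1
    parent = np.empty(n_nodes, np.int64)
    times = np.empty(n_nodes, np.float64)
    child1 = np.empty(n_nodes, np.int64)
    child2 = np.empty(n_nodes, np.int64)
    pool = np.empty(2 * n, np.int64)
    stack = np.empty(n_nodes, np.int64)
    lengths = np.empty(n_nodes - 1, np.float64)
    out = np.zeros((n, n_sites), np.int8)

    for s in range(n_sites):
        _genealogy(model, ct, x1, a1, x2, a2, n1, n2,
                   parent, times, child1, child2, pool)
        total = 0.0
        for e in range(n_nodes - 1):
            lengths[e] = times[parent[e]] - times[e]
            total += lengths[e]
        u = np.random.random() * total
        acc = 0.0
        edge = n_nodes - 2
        for e in range(n_nodes - 1):
            acc += lengths[e]
            if u < acc:
                edge = e
                break
        # mark leaves below `edge`
        top = 0
        stack[top] = edge
        top += 1
        while top > 0:
            top -= 1
            v = stack[top]
            if v < n:
                out[v, s] = 1
            else:
                stack[top] = child1[v]
                top += 1
                stack[top] = child2[v]
                top += 1
    return out


@nb.njit(cache=True)
def linked_genealogy(
    model: int, ct: float,
    x1: float, a1: float, x2: float, a2: float,
    n1: int, n2: int, seed: int,
):
    """One genealogy (parent, times) for the linked, shared-tree mode."""
    np.random.seed(seed)
    n = n1 + n2
    n_nodes = 2 * n - 1
    parent = np.empty(n_nodes, np.int64)
    times = np.empty(n_nodes, np.float64)
    child1 = np.empty(n_nodes, np.int64)
    child2 = np.empty(n_nodes, np.int64)
    pool = np.empty(2 * n, np.int64)
    _genealogy(model, ct, x1, a1, x2, a2, n1, n2,
               parent, times, child1, child2, pool)
    return parent, times
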