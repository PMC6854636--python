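"""Deterministic Dijkstra on weighted psychometric networks.

Edge length is a transform of the association weight (default ``1/|w|``;
``-log|w|`` optional), so strong associations are short. Ties are broken
first toward fewer hops and then toward the lexicographically smallest
node sequence, which makes reported paths reproducible.
"""

from __future__ import annotations

import heapq

import numpy as np

from .errors import DomainError


def edge_lengths(W: np.ndarray, transform: str = "inverse-absolute") -> np.ndarray:
    """Length matrix from a weight matrix; absent edges become +inf."""
    A = np.abs(np.asarray(W, dtype=float))
    L = np.full_like(A, np.inf)
    nz = A > 0
    if transform == "inverse-absolute":
        L[nz] = 1.0 / A[nz]
    elif transform == "neg-log-absolute":
        if A[nz].max() >= 1.0:
            raise DomainError("-log|w| transform needs |w| < 1")
        L[nz] = -np.log(A[nz])
    else:
        raise DomainError(f"unknown length transform {transform!r}")
    np.fill_diagonal(L, np.inf)
    return L


def dijkstra(L: np.ndarray, source: int):
    """Single-source shortest paths on a dense length matrix.

    Returns ``(dist, paths)`` where ``paths[v]`` is the node sequence from
    ``source`` to ``v`` (``None`` if unreachable). Priority is
    (distance, hop count, node sequence), giving deterministic tie-breaks.
    """
    p = L.shape[0]
    dist = np.full(p, np.inf)
    best_key: list[tuple | None] = [None] * p
    paths: list[list[int] | None] = [None] * p
    start_key = (0.0, 0, (source,))
    heap = [start_key]
    while heap:
        d, hops, seq = heapq.heappop(heap)
        v = seq[-1]
        if best_key[v] is not None and (d, hops, seq) > best_key[v]:
            continue
        for u in range(p):
            lu = L[v, u]
            if not np.isfinite(lu):
                continue
            cand = (d + lu, hops + 1, seq + (u,))
            if best_key[u] is None or cand < best_key[u]:
                best_key[u] = cand
                dist[u] = cand[0]
                paths[u] = list(cand[2])
                heapq.heappush(heap, cand)
    dist[source] = 0.0
    paths[source] = [source]
    return dist, paths
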