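"""Independent brute-force references used to check the spatial statistics.

These deliberately avoid scipy.spatial: nearest-neighbour distances come
from the full O(n²) distance matrix, and Delaunay adjacency from the
defining empty-circumcircle property evaluated over all point triples.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_nnd(points: np.ndarray) -> np.ndarray:
    """Nearest-neighbour distance of each point via the full distance matrix."""
    pts = np.asarray(points, dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def brute_delaunay_adjacency(points: np.ndarray) -> dict[int, set[int]]:
    """Delaunay adjacency from the empty-circumcircle criterion.

    A triple forms a Delaunay triangle iff its circumcircle contains no
    other point strictly inside; the triangle's edges are then adjacent
    pairs. Assumes points in general position (no exact cocircular
    quadruples), which holds almost surely for the random fields tested.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    triples = np.array(list(combinations(range(n), 3)))
    a, b, c = pts[triples[:, 0]], pts[triples[:, 1]], pts[triples[:, 2]]
    d = 2.0 * (
        a[:, 0] * (b[:, 1] - c[:, 1])
        + b[:, 0] * (c[:, 1] - a[:, 1])
        + c[:, 0] * (a[:, 1] - b[:, 1])
    )
    ok = np.abs(d) > 1e-12
    asq = (a**2).sum(1)
    bsq = (b**2).sum(1)
    csq = (c**2).sum(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ux = (asq * (b[:, 1] - c[:, 1]) + bsq * (c[:, 1] - a[:, 1])
              + csq * (a[:, 1] - b[:, 1])) / d
        uy = (asq * (c[:, 0] - b[:, 0]) + bsq * (a[:, 0] - c[:, 0])
              + csq * (b[:, 0] - a[:, 0])) / d
    center = np.column_stack([ux, uy])
    r2 = ((a - center) ** 2).sum(1)
    dist2 = ((pts[None, :, :] - center[:, None, :]) ** 2).sum(2)  # (T, n)
    tol = 1e-9 * np.maximum(r2, 1.0)
    inside = dist2 < (r2 - tol)[:, None]
    inside[np.arange(len(triples))[:, None], triples] = False
    empty = ok & ~inside.any(axis=1)
    for t, (i, j, k) in zip(empty, triples):
        if t:
            adj[i].update((j, k))
            adj[j].update((i, k))
            adj[k].update((i, j))
    return adj
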