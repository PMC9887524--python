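"""Relative shortest-path score: the core outlier statistic.

Copy-number gains and losses are a minority of segments, so in the 2-D
feature space they appear as isolated points or small sparse clusters.
For each object ``o`` we take its k-distance neighbourhood, grow a
Prim-style tree over {o} ∪ neighbourhood (the shortest path set), and
average the tree's edge costs into the mean shortest-path cost SPCm(o).
The relative shortest-path score

    RSPS(o) = |N(o)| * SPCm(o) / sum_{a in N(o)} SPCm(a)

compares an object's local sparsity with its neighbours': interior points
of a homogeneous cloud score ~1, isolated points score above 1.  Unlike a
plain k-NN distance, the tree cost also separates a small *cluster* of
aberrant segments whose members are mutually close but far from everything
else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .feature_space import FeatureObject

# Default neighbourhood ceiling.  k must exceed the number of aberrant
# segments forming one cluster in feature space (a realistic profile
# carries ~14 events plus boundary fragments), otherwise clustered CNVs
# normalise each other's scores toward 1 and mask themselves; yet the
# neighbourhood must stay local, so the default also caps k at a fifth of
# the profile.
DEFAULT_K = 40


def default_k(n: int) -> int:
    """Default neighbourhood size for an ``n``-object profile."""
    return max(1, min(DEFAULT_K, n // 5, n - 1))


@dataclass(frozen=True)
class NeighborhoodModel:
    """k-distance and tie-expanded neighbour list of one object."""

    index: int
    k: int
    k_dist: float
    neighbors: tuple[int, ...]  # ascending (distance, index)


@dataclass(frozen=True)
class ShortestPathResult:
    """Prim tree over an object and its neighbourhood.

    ``sps`` lists nodes in absorption order (the object first); ``sprs``
    the edges (u, v) with u already in the tree when v was absorbed;
    ``spcs`` the corresponding edge costs.
    """

    sps: tuple[int, ...]
    sprs: tuple[tuple[int, int], ...]
    spcs: tuple[float, ...]


@dataclass(frozen=True)
class ScoreProfile:
    """Per-object mean shortest-path cost and relative score."""

    k: int
    spcm: np.ndarray
    rsps: np.ndarray


def pairwise_distance(a: FeatureObject, b: FeatureObject) -> float:
    """Euclidean distance on the scaled coordinates."""
    return math.hypot(a.scaled_x - b.scaled_x, a.scaled_y - b.scaled_y)


def _distance_matrix(objects: Sequence[FeatureObject]) -> np.ndarray:
    pts = np.array([[o.scaled_x, o.scaled_y] for o in objects])
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def k_neighborhood(
    o: int,
    all_objects: Sequence[FeatureObject],
    k: int,
    dist: np.ndarray | None = None,
) -> NeighborhoodModel:
    """k-distance neighbourhood of object ``o``.

    The k-distance is the distance to the k-th closest *other* object; the
    neighbourhood holds every other object at distance <= k-distance, so
    exact ties can expand it beyond k members.  Ordering is ascending
    (distance, index), which makes runs bit-reproducible.
    """
    n = len(all_objects)
    if k >= n:
        raise ValueError(f"k={k} requires at least k+1 objects, got n={n}")
    if k < 1:
        raise ValueError(f"k must be positive, got {k}")
    if dist is None:
        dist = _distance_matrix(all_objects)
    others = [(dist[o, j], j) for j in range(n) if j != o]
    others.sort()
    k_dist = others[k - 1][0]
    neighbors = tuple(j for d, j in others if d <= k_dist)
    return NeighborhoodModel(index=o, k=k, k_dist=k_dist, neighbors=neighbors)


def shortest_path_sets(
    o: int,
    neighborhood: NeighborhoodModel | Sequence[int],
    all_objects: Sequence[FeatureObject],
    dist: np.ndarray | None = None,
) -> ShortestPathResult:
    """Grow the shortest path set of ``o`` by Prim's rule.

    Starting from {o}, repeatedly absorb the unconnected neighbour with the
    minimum distance to any connected node; ties break by ascending
    (distance, connected-node index, neighbour index).
    """
    if dist is None:
        dist = _distance_matrix(all_objects)
    members = (
        neighborhood.neighbors
        if isinstance(neighborhood, NeighborhoodModel)
        else tuple(neighborhood)
    )
    if not members:
        raise ValueError("neighbourhood must be non-empty")

    sps: list[int] = [o]
    sprs: list[tuple[int, int]] = []
    spcs: list[float] = []
    # per-remaining-node best connection (distance, tree-node index); the
    # update rule keeps the smallest tree-node index among equal distances,
    # so picking min (d, u, v) reproduces the global pair tie-break
    best: dict[int, tuple[float, int]] = {v: (dist[o, v], o) for v in members}
    while best:
        d, u, v = min((d, u, v) for v, (d, u) in best.items())
        sps.append(v)
        sprs.append((u, v))
        spcs.append(float(d))
        del best[v]
        for w, (dw, uw) in best.items():
            dvw = dist[v, w]
            if dvw < dw or (dvw == dw and v < uw):
                best[w] = (dvw, v)
    return ShortestPathResult(sps=tuple(sps), sprs=tuple(sprs), spcs=tuple(spcs))


def mean_shortest_path_cost(result: ShortestPathResult) -> float:
    """Arithmetic mean of the tree's edge costs.

    The divisor is the number of edges, which equals k unless exact
    distance ties expanded the neighbourhood.
    """
    if not result.spcs:
        raise ValueError("shortest path cost set is empty")
    return float(np.mean(result.spcs))


def rsps_scores(all_objects: Sequence[FeatureObject], k: int | None = None) -> ScoreProfile:
    """Compute SPCm and RSPS for every object.

    Conventions for degenerate geometry (exact duplicates after scaling):
    if an object's SPCm and all its neighbours' SPCm are zero the score is
    1 (the object is as dense as its neighbourhood); if the neighbours'
    total is zero but the object's SPCm is positive the score is +inf.
    """
    n = len(all_objects)
    if k is None:
        k = default_k(n)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} objects, got {n}")
    dist = _distance_matrix(all_objects)

    hoods = [k_neighborhood(i, all_objects, k, dist) for i in range(n)]
    spcm = np.array(
        [
            mean_shortest_path_cost(shortest_path_sets(i, hoods[i], all_objects, dist))
            for i in range(n)
        ]
    )
    rsps = np.empty(n)
    for i in range(n):
        neigh = list(hoods[i].neighbors)
        total = float(spcm[neigh].sum())
        if total > 0:
            rsps[i] = len(neigh) * spcm[i] / total
        elif spcm[i] == 0:
            rsps[i] = 1.0
        else:
            rsps[i] = math.inf
    return ScoreProfile(k=k, spcm=spcm, rsps=rsps)
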