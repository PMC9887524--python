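import math

import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree

from spcnv import (
    from_coordinates,
    k_neighborhood,
    mean_shortest_path_cost,
    pairwise_distance,
    rsps_scores,
    shortest_path_sets,
)


class TestPairwiseDistance:
    def test_identical_points_zero(self):
        a, b = from_coordinates([(0.3, 0.7), (0.3, 0.7)])
        assert pairwise_distance(a, b) == 0.0

    def test_hand_values(self, ten_points):
        objs = from_coordinates(ten_points)
        assert pairwise_distance(objs[0], objs[5]) == pytest.approx(
            math.hypot(0.03, 0.06)
        )
        assert pairwise_distance(objs[0], objs[3]) == pytest.approx(
            math.hypot(0.3, 0.1)
        )


class TestKNeighborhood:
    def test_ten_object_example(self, ten_points):
        nb = k_neighborhood(0, from_coordinates(ten_points), 5)
        assert [j + 1 for j in nb.neighbors] == [6, 7, 8, 5, 4]

    def test_two_points_mutual(self):
        objs = from_coordinates([(0.0, 0.0), (0.6, 0.8)])
        nb = k_neighborhood(0, objs, 1)
        assert nb.neighbors == (1,)
        assert nb.k_dist == pytest.approx(1.0)

    def test_tie_expansion_beyond_k(self):
        # 1-D lattice {0, 1, 2}: both ends are at distance 1 from the middle
        objs = from_coordinates([(0.0, 0.5), (0.5, 0.5), (1.0, 0.5)])
        nb = k_neighborhood(1, objs, 1)
        assert set(nb.neighbors) == {0, 2}

    def test_k_too_large_rejected(self):
        objs = from_coordinates([(0, 0), (1, 1)])
        with pytest.raises(ValueError, match="k=2"):
            k_neighborhood(0, objs, 2)


class TestShortestPathSets:
    def test_ten_object_example(self, ten_points):
        objs = from_coordinates(ten_points)
        nb = k_neighborhood(0, objs, 5)
        r = shortest_path_sets(0, nb, objs)
        assert [i + 1 for i in r.sps] == [1, 6, 7, 8, 5, 4]
        assert [(u + 1, v + 1) for u, v in r.sprs] == [
            (1, 6), (1, 7), (7, 8), (6, 5), (5, 4)
        ]
        assert [round(c, 2) for c in r.spcs] == [0.07, 0.12, 0.06, 0.16, 0.12]

    def test_single_neighbor(self):
        objs = from_coordinates([(0, 0), (0.3, 0.4)])
        r = shortest_path_sets(0, [1], objs)
        assert r.sps == (0, 1) and r.sprs == ((0, 1),)
        assert r.spcs[0] == pytest.approx(0.5)

    def test_collinear_chain(self):
        objs = from_coordinates([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)])
        r = shortest_path_sets(0, [1, 2], objs)
        assert r.sprs == ((0, 1), (1, 2))
        assert list(r.spcs) == [1.0, 1.0]

    def test_tree_structure_invariants(self, ten_points):
        objs = from_coordinates(ten_points)
        for o in range(10):
            nb = k_neighborhood(o, objs, 4)
            r = shortest_path_sets(o, nb, objs)
            assert len(r.sps) == len(nb.neighbors) + 1
            assert len(r.sprs) == len(r.spcs) == len(r.sps) - 1
            # every edge joins a previously absorbed node to a new one
            seen = {r.sps[0]}
            for (u, v), nxt in zip(r.sprs, r.sps[1:]):
                assert u in seen and v == nxt
                seen.add(v)


def mst_weight(points):
    """Kruskal-based oracle: total MST weight over a point set."""
    pts = np.asarray(points)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return minimum_spanning_tree(d).sum()


class TestMstEquivalence:
    def test_prim_cost_equals_kruskal_mst_weight(self):
        """sum(SPCS) attains the MST weight of the spanned node set."""
        rng = np.random.default_rng(2024)
        for trial in range(200):
            n = int(rng.integers(10, 51))
            k = int(rng.integers(3, 11))
            pts = rng.random((n, 2))
            objs = from_coordinates([tuple(p) for p in pts])
            for o in range(n):
                nb = k_neighborhood(o, objs, k)
                r = shortest_path_sets(o, nb, objs)
                ref = mst_weight([pts[i] for i in r.sps])
                assert abs(sum(r.spcs) - ref) < 1e-9


class TestScores:
    def test_mean_cost_of_example_object(self, ten_points):
        objs = from_coordinates(ten_points)
        r = shortest_path_sets(0, k_neighborhood(0, objs, 5), objs)
        exact_edges = [
            math.hypot(0.03, 0.06),   # 1-6
            math.hypot(0.06, 0.10),   # 1-7
            math.hypot(0.04, 0.04),   # 7-8
            math.hypot(0.15, 0.06),   # 6-5
            math.hypot(0.12, 0.02),   # 5-4
        ]
        assert mean_shortest_path_cost(r) == pytest.approx(
            sum(exact_edges) / 5, abs=1e-12
        )
        # arithmetic on the 2-dp displayed costs
        assert round(sum([0.07, 0.12, 0.06, 0.16, 0.12]) / 5, 3) == 0.106

    def test_all_equal_costs_mean(self):
        objs = from_coordinates([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)])
        r = shortest_path_sets(0, [1, 2], objs)
        assert mean_shortest_path_cost(r) == 1.0

    def test_uniform_lattice_interior_scores_one(self):
        pts = [(i / 29, 0.0) for i in range(30)]
        prof = rsps_scores(from_coordinates(pts), k=3)
        interior = prof.rsps[8:22]
        assert np.allclose(interior, 1.0)

    def test_isolated_corner_object_scores_above_one(self, ten_points):
        prof = rsps_scores(from_coordinates(ten_points), k=5)
        assert prof.rsps[9] > 1.0

    def test_duplicate_cloud_convention(self):
        objs = from_coordinates([(0.4, 0.4)] * 6)
        prof = rsps_scores(objs, k=5)
        assert np.all(prof.spcm == 0)
        assert np.all(prof.rsps == 1.0)

    def test_affine_invariance_of_rsps(self, ten_points):
        base = rsps_scores(from_coordinates(ten_points), k=4).rsps
        mapped = [(0.3 * x + 7.0, 0.3 * y + 7.0) for x, y in ten_points]
        moved = rsps_scores(from_coordinates(mapped), k=4).rsps
        assert np.allclose(base, moved, atol=1e-9)

    def test_rsps_monotone_in_separation(self):
        rng = np.random.default_rng(0)
        cloud = rng.random((40, 2)) * 0.3
        scores = []
        for sep in (0.2, 0.4, 0.8, 1.6):
            pts = [tuple(p) for p in cloud] + [(0.15 + sep, 0.15 + sep)]
            prof = rsps_scores(from_coordinates(pts), k=10)
            scores.append(prof.rsps[-1])
        assert scores == sorted(scores)
        assert scores[-1] > 1.0
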