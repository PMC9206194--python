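import math

import numpy as np
import pytest

from txaccess.catchment import (
    RoadNetwork,
    Tract,
    haversine_km,
    population_weighted_centroid,
    shortest_travel_time,
    straight_line_minutes,
    tract_within_drive,
    travel_time_to_nearest,
)
from txaccess.synthetic import grid_network

from conftest import enumerate_min_path_minutes, random_connected_graph


class TestCentroid:
    def test_single_point_is_identity(self):
        assert population_weighted_centroid([(3.0, -2.0, 5.0)]) == (3.0, -2.0)

    def test_equal_weights_symmetric_pair(self):
        assert population_weighted_centroid([(0, 0, 2.0), (2, 0, 2.0)]) == (1.0, 0.0)

    def test_matches_direct_summation_oracle_and_rescaling(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(0, 10, (10, 2))
        w = rng.uniform(0.1, 5.0, 10)
        # independent oracle: plain accumulation loops
        sx = sum(p[0] * ww for p, ww in zip(pts, w)) / sum(w)
        sy = sum(p[1] * ww for p, ww in zip(pts, w)) / sum(w)
        got = population_weighted_centroid(np.column_stack([pts, w]))
        assert got == pytest.approx((sx, sy), abs=1e-12)
        rescaled = population_weighted_centroid(np.column_stack([pts, 17.3 * w]))
        assert rescaled == pytest.approx(got, abs=1e-9)

    def test_zero_total_weight_is_error(self):
        with pytest.raises(ValueError):
            population_weighted_centroid([(0, 0, 0.0), (1, 1, 0.0)])


class TestShortestTime:
    def test_single_edge_weight(self):
        net = RoadNetwork({0: (0, 0), 1: (10, 0)}, [(0, 1, 10.0)])
        assert shortest_travel_time(net, (0, 0), [(10, 0)])[0] == pytest.approx(10.0)

    def test_path_additivity(self):
        net = RoadNetwork(
            {"A": (0, 0), "B": (1, 0), "C": (2, 0)},
            [("A", "B", 10.0), ("B", "C", 15.0)],
        )
        assert shortest_travel_time(net, (0, 0), [(2, 0)])[0] == pytest.approx(25.0)

    def test_origin_equals_target_is_zero(self):
        net = RoadNetwork({0: (0, 0), 1: (5, 5)}, [(0, 1, 3.0)])
        assert shortest_travel_time(net, (0, 0), [(0, 0)])[0] == pytest.approx(0.0)

    def test_grid_equals_manhattan_distance(self):
        mpu = 2.5
        net = grid_network(5, 4, spacing=1.0, minutes_per_unit=mpu)
        for (a, b) in [((0, 0), (4, 3)), ((1, 2), (3, 0)), ((2, 1), (2, 3))]:
            t = shortest_travel_time(net, net.coords[a], [net.coords[b]])[0]
            manhattan = abs(a[0] - b[0]) + abs(a[1] - b[1])
            assert t == pytest.approx(manhattan * mpu)

    def test_unreachable_is_infinite_and_empty_targets_empty(self):
        net = RoadNetwork({0: (0, 0), 1: (1, 0), 2: (50, 50)}, [(0, 1, 1.0)])
        assert math.isinf(shortest_travel_time(net, (0, 0), [(50, 50)])[0])
        assert shortest_travel_time(net, (0, 0), []).size == 0

    @pytest.mark.parametrize("n_nodes,n_extra", [(8, 6), (20, 8), (40, 6)])
    def test_matches_exhaustive_path_enumeration(self, n_nodes, n_extra):
        """Dijkstra times equal brute-force enumeration of simple paths."""
        rng = np.random.default_rng(100 + n_nodes)
        nodes, edges = random_connected_graph(rng, n_nodes, n_extra)
        net = RoadNetwork(nodes, edges)
        for _ in range(15):
            s, t = rng.integers(0, n_nodes, 2)
            got = shortest_travel_time(net, nodes[int(s)], [nodes[int(t)]])[0]
            want = 0.0 if s == t else enumerate_min_path_minutes(edges, n_nodes, int(s), int(t))
            assert got == pytest.approx(want, abs=1e-9)

    def test_triangle_inequality_of_path_costs(self):
        rng = np.random.default_rng(7)
        nodes, edges = random_connected_graph(rng, 25, 20)
        net = RoadNetwork(nodes, edges)
        pts = [nodes[i] for i in range(25)]
        d = np.array([shortest_travel_time(net, p, pts) for p in pts])
        for _ in range(200):
            i, j, k = rng.integers(0, 25, 3)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_multi_source_equals_rowwise_minimum(self):
        rng = np.random.default_rng(5)
        nodes, edges = random_connected_graph(rng, 30, 12)
        net = RoadNetwork(nodes, edges)
        origins = [nodes[i] for i in range(0, 30, 3)]
        clinics = [nodes[i] for i in (1, 8, 23)]
        bulk = travel_time_to_nearest(net, origins, clinics)
        rowwise = [min(shortest_travel_time(net, o, clinics)) for o in origins]
        assert bulk == pytest.approx(rowwise, abs=1e-9)


class TestDriveDecision:
    @pytest.fixture
    def line_net(self):
        # chain with 10-minute links: clinic distance controlled exactly
        nodes = {i: (float(i * 10), 0.0) for i in range(5)}
        edges = [(i, i + 1, 10.0) for i in range(4)]
        return RoadNetwork(nodes, edges)

    def _tract(self):
        return Tract(id="T", state="S", centroid=(0.0, 0.0), rucc=1)

    def test_within_threshold(self, line_net):
        assert tract_within_drive(line_net, self._tract(), [(20.0, 0.0)], 30.0, 0.0)

    def test_beyond_threshold(self, line_net):
        assert not tract_within_drive(line_net, self._tract(), [(40.0, 0.0)], 30.0, 0.0)

    def test_boundary_is_inclusive(self, line_net):
        """A clinic at exactly the threshold time still grants access."""
        assert tract_within_drive(line_net, self._tract(), [(30.0, 0.0)], 30.0, 0.0)

    def test_no_clinics_means_no_access_not_error(self, line_net):
        assert tract_within_drive(line_net, self._tract(), []) is False

    def test_monotone_in_clinics_and_threshold(self):
        """Adding a clinic or raising the threshold never removes access."""
        rng = np.random.default_rng(31)
        nodes, edges = random_connected_graph(rng, 20, 10)
        net = RoadNetwork(nodes, edges)
        tract = Tract(id="T", state="S", centroid=nodes[0], rucc=1)
        clinics = [nodes[i] for i in (5, 9)]
        for thr in (5.0, 15.0, 40.0):
            base = tract_within_drive(net, tract, clinics, thr)
            more = tract_within_drive(net, tract, clinics + [nodes[12]], thr)
            assert more >= base
            assert tract_within_drive(net, tract, clinics, thr + 10.0) >= base


def test_haversine_fallback_agrees_with_network_on_complete_graph():
    """A complete graph whose edges encode straight-line times reproduces the
    straight-line (haversine-free, planar) fallback exactly."""
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 10, (12, 2))
    speed = 2.0
    nodes = {i: tuple(pts[i]) for i in range(12)}
    edges = [
        (i, j, float(np.linalg.norm(pts[i] - pts[j]) * speed))
        for i in range(12)
        for j in range(i + 1, 12)
    ]
    net = RoadNetwork(nodes, edges)
    targets = [tuple(p) for p in pts[5:]]
    net_times = shortest_travel_time(net, tuple(pts[0]), targets)
    direct = straight_line_minutes(tuple(pts[0]), targets, minutes_per_unit=speed)
    assert net_times == pytest.approx(direct, abs=1e-9)


def test_haversine_known_distance():
    # one degree of longitude at the equator is ~111.19 km
    assert float(haversine_km(0, 0, 1, 0)) == pytest.approx(111.19, abs=0.05)


def test_geographic_snapping_picks_great_circle_nearest():
    net = RoadNetwork({0: (0.0, 0.0), 1: (0.0, 60.0)}, [(0, 1, 5.0)], geographic=True)
    node, dist = net.nearest_node((1.0, 59.0))
    assert node == 1
    assert dist == pytest.approx(float(haversine_km(1.0, 59.0, 0.0, 60.0)), rel=1e-6)


def test_invalid_edges_rejected():
    with pytest.raises(ValueError):
        RoadNetwork({0: (0, 0), 1: (1, 1)}, [(0, 1, 0.0)])
    with pytest.raises(ValueError):
        RoadNetwork({0: (0, 0)}, [(0, 99, 1.0)])
    with pytest.raises(ValueError):
        Tract(id="T", state="S", centroid=(0, 0), rucc=12)
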