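"""G2SFCA checks: decay kernel, network distances vs all-pairs oracle,
supply-demand ratios, accessibility conservation, and geometric intervals."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from parkequity.access import (
    CatchmentConfig,
    accessibility,
    classify_geometric,
    compute_accessibility,
    gaussian_decay,
    network_distance,
    park_supply,
    residence_park_distances,
    supply_demand_ratios,
)
from parkequity.quality import DEFAULT_WEIGHTS, ParkQuality
from parkequity.synthcity.generate import generate_city

from conftest import (
    area_only_weights,
    constant_quality,
    line_graph,
    make_park,
    make_residence,
    small_scenario,
    toy_city,
)


class TestGaussianDecay:
    def test_boundary_values_exact(self):
        assert gaussian_decay(0.0, 2000.0) == 1.0
        assert gaussian_decay(2000.0, 2000.0) == 0.0
        assert gaussian_decay(5000.0, 2000.0) == 0.0

    def test_half_radius_value(self):
        # direct evaluation of the truncated-Gaussian kernel
        d0 = 2000.0
        want = (math.exp(-0.5 * 0.25) - math.exp(-0.5)) / (1 - math.exp(-0.5))
        assert gaussian_decay(1000.0, d0) == pytest.approx(want, abs=1e-12)
        assert gaussian_decay(1000.0, d0) == pytest.approx(0.7013666, abs=1e-6)

    def test_strictly_decreasing_and_continuous(self):
        d = np.linspace(0, 2000, 1000)
        w = gaussian_decay(d, 2000.0)
        assert (np.diff(w) < 0).all()
        assert gaussian_decay(2000.0 - 1e-9, 2000.0) == pytest.approx(0.0, abs=1e-9)

    def test_rejects_bad_domain(self):
        with pytest.raises(ValueError):
            gaussian_decay(100.0, 0.0)
        with pytest.raises(ValueError):
            gaussian_decay(-1.0, 100.0)


class TestNetworkDistance:
    def test_same_node_zero(self):
        g = line_graph(5)
        d = network_distance(g, [(0, 0)], [(0, 0)], cutoff=1000)
        assert d[(0, 0)] == pytest.approx(0.0)

    def test_single_edge_distance(self):
        g = nx.Graph()
        g.add_node(0, x=0.0, y=0.0)
        g.add_node(1, x=700.0, y=0.0)
        g.add_edge(0, 1, length_m=700.0)
        d = network_distance(g, [(0, 0)], [(700, 0)], cutoff=1000)
        assert d[(0, 0)] == pytest.approx(700.0)

    def test_cutoff_excludes_far_pairs(self):
        g = line_graph(40)
        d = network_distance(g, [(0, 0)], [(3500, 0)], cutoff=3000)
        assert (0, 0) not in d

    def test_matches_floyd_warshall(self):
        rng = np.random.default_rng(0)
        g = nx.Graph()
        for i in range(25):
            g.add_node(i, x=(i % 5) * 100 + rng.uniform(-20, 20),
                       y=(i // 5) * 100 + rng.uniform(-20, 20))
        for i in range(25):
            if i % 5 < 4:
                g.add_edge(i, i + 1)
            if i // 5 < 4:
                g.add_edge(i, i + 5)
        for u, v in g.edges:
            g[u][v]["length_m"] = math.hypot(
                g.nodes[u]["x"] - g.nodes[v]["x"],
                g.nodes[u]["y"] - g.nodes[v]["y"])

        from scipy.sparse.csgraph import floyd_warshall
        from scipy.sparse import lil_matrix
        adj = lil_matrix((25, 25))
        for u, v, data in g.edges(data=True):
            adj[u, v] = adj[v, u] = data["length_m"]
        full = floyd_warshall(adj.tocsr(), directed=False)

        nodes = [3, 7, 11, 19, 22]
        pts = [(g.nodes[n]["x"], g.nodes[n]["y"]) for n in nodes]
        got = network_distance(g, pts, pts, cutoff=10_000)
        for i, u in enumerate(nodes):
            for j, v in enumerate(nodes):
                assert got[(i, j)] == pytest.approx(full[u, v], abs=1e-9)

    def test_far_point_excluded_with_warning(self):
        g = line_graph(5)
        with pytest.warns(UserWarning, match="excluded"):
            d = network_distance(g, [(0, 5000)], [(0, 0)], cutoff=10_000)
        assert not d

    def test_empty_graph_error(self):
        with pytest.raises(ValueError, match="empty"):
            network_distance(nx.Graph(), [(0, 0)], [(0, 0)], cutoff=100)

    def test_min_over_entrances(self):
        """A two-entrance park is reached through the nearer gate."""
        g = line_graph(40)
        park = make_park("P0", entrance_node=0, graph=g)
        park.entrances.append((3000.0, 0.0))
        park.entrance_nodes.append(30)
        res = make_residence("R0", 25, g)  # 2500 m from node 0, 500 m from node 30
        city = toy_city([park], [res], g)
        d = residence_park_distances(city, cutoff=3500)
        assert d.get("R0", "P0") == pytest.approx(500.0)


class TestSupplyAndRatios:
    def test_park_supply_linear_combination(self):
        q = ParkQuality(park_id="p", S=10, ESV=0, FCs=0)
        assert park_supply(q, DEFAULT_WEIGHTS) == pytest.approx(7.236)
        q0 = ParkQuality(park_id="p", S=0, ESV=0, FCs=0)
        assert park_supply(q0, DEFAULT_WEIGHTS) == 0.0

    def test_park_supply_hand_arithmetic(self):
        q = ParkQuality(park_id="p", S=12.5, ESV=-8.26, FCs=3.1)
        want = 0.7236 * 12.5 + 0.1931 * 3.1 + 0.0833 * (-8.26)
        assert park_supply(q, DEFAULT_WEIGHTS) == pytest.approx(want, abs=1e-12)

    def test_negative_supply_floored(self):
        q = ParkQuality(park_id="p", S=0.1, ESV=-500.0, FCs=0.0)
        with pytest.warns(UserWarning, match="floored"):
            assert park_supply(q, DEFAULT_WEIGHTS) == 0.0

    def test_single_residence_at_gate(self, line_city):
        """C = 50, one residence P = 100 at d = 0 gives R = C / (1 * 100)."""
        g = line_graph()
        park = make_park("P0", entrance_node=0, graph=g, area_hm2=50.0)
        res = make_residence("R0", 0, g, population=100.0)
        city = toy_city([park], [res], g)
        cc = CatchmentConfig(mode="type_specific")
        dist = residence_park_distances(city, cc.max_radius)
        ratios = supply_demand_ratios(city, constant_quality([park]),
                                      area_only_weights(), cc, dist)
        assert ratios.loc["P0", "R_j"] == pytest.approx(0.5)
        acc = accessibility(city, ratios, dist, cc)
        assert acc.loc["R0", "A"] == pytest.approx(0.5)

    def test_two_residences_at_half_radius(self):
        """C = 70.1359, two residences of P = 100 at d0/2: R = C/(G*200) = 0.5."""
        g = line_graph()
        park = make_park("P0", entrance_node=0, graph=g, area_hm2=70.1359)
        residences = [make_residence("R0", 10, g, population=100.0),
                      make_residence("R1", 10, g, population=100.0)]
        city = toy_city([park], residences, g)
        cc = CatchmentConfig(mode="uniform", d0_uniform=2000.0)
        dist = residence_park_distances(city, cc.max_radius)
        ratios = supply_demand_ratios(city, constant_quality([park]),
                                      area_only_weights(), cc, dist)
        g_half = gaussian_decay(1000.0, 2000.0)
        assert ratios.loc["P0", "R_j"] == pytest.approx(
            70.1359 / (g_half * 200.0), abs=1e-9)

    def test_park_with_no_demand_has_zero_ratio(self):
        g = line_graph()
        park = make_park("P0", entrance_node=0, graph=g, area_hm2=1.0)  # 500 m
        res = make_residence("R0", 20, g)  # 2000 m away, out of range
        city = toy_city([park], [res], g)
        cc = CatchmentConfig(mode="type_specific")
        dist = residence_park_distances(city, cc.max_radius)
        ratios = supply_demand_ratios(city, constant_quality([park]),
                                      area_only_weights(), cc, dist)
        assert ratios.loc["P0", "R_j"] == 0.0
        acc = accessibility(city, ratios, dist, cc)
        assert acc.loc["R0", "A"] == 0.0


class TestAccessibilityOracle:
    def brute_force(self, city, qualities, weights, cc):
        """Naive double loop over (residence, park) with explicit min over
        entrances via per-entrance Dijkstra."""
        import networkx as nx

        a = {r.residence_id: 0.0 for r in city.residences}
        ratios = {}
        dists = {}
        for park in city.parks:
            d0 = cc.radius_for(park)
            c = weights.w_s * qualities[park.park_id].S \
                + weights.w_fcs * qualities[park.park_id].FCs \
                + weights.w_esv * qualities[park.park_id].ESV
            c = max(c, 0.0)
            d_j = 0.0
            for res in city.residences:
                best = math.inf
                for node in park.entrance_nodes:
                    try:
                        d = nx.dijkstra_path_length(
                            city.roads, node,
                            self.node_of(city, res), weight="length_m")
                    except nx.NetworkXNoPath:
                        continue
                    best = min(best, d)
                dists[(res.residence_id, park.park_id)] = best
                if best < d0:
                    d_j += gaussian_decay(best, d0) * res.population
            ratios[park.park_id] = 0.0 if d_j == 0 else c / d_j
        for res in city.residences:
            for park in city.parks:
                d0 = cc.radius_for(park)
                d = dists[(res.residence_id, park.park_id)]
                if d < d0:
                    a[res.residence_id] += gaussian_decay(d, d0) * ratios[park.park_id]
        return a

    @staticmethod
    def node_of(city, res):
        best, best_d = None, math.inf
        for n, data in city.roads.nodes(data=True):
            d = math.hypot(data["x"] - res.point.x, data["y"] - res.point.y)
            if d < best_d:
                best, best_d = n, d
        return best

    def test_two_parks_three_residences_match_loop(self):
        g = line_graph()
        parks = [make_park("P0", 0, g, area_hm2=10.0),
                 make_park("P1", 30, g, area_hm2=30.0)]
        residences = [make_residence("R0", 5, g, population=200.0),
                      make_residence("R1", 15, g, population=50.0),
                      make_residence("R2", 28, g, population=120.0)]
        city = toy_city(parks, residences, g)
        cc = CatchmentConfig(mode="type_specific")
        got = compute_accessibility(city, constant_quality(parks, esv=5.0),
                                    DEFAULT_WEIGHTS, cc)
        want = self.brute_force(city, constant_quality(parks, esv=5.0),
                                DEFAULT_WEIGHTS, cc)
        for rid, val in want.items():
            assert got.loc[rid, "A"] == pytest.approx(val, abs=1e-9)

        # conservation: total person-weighted accessibility = total supply
        total = sum(got.loc[r.residence_id, "A"] * r.population
                    for r in city.residences)
        c_sum = sum(park_supply(q, DEFAULT_WEIGHTS)
                    for q in constant_quality(parks, esv=5.0).values())
        assert total == pytest.approx(c_sum, abs=1e-9)

    def test_classic_unweighted_g2sfca_recovered(self):
        """With area-only weights the composite reduces to S, so the score
        equals the textbook Gaussian 2SFCA regardless of ESV/FCs values."""
        g = line_graph()
        parks = [make_park("P0", 0, g, area_hm2=10.0),
                 make_park("P1", 25, g, area_hm2=4.0)]
        residences = [make_residence(f"R{i}", n, g, population=80.0)
                      for i, n in enumerate((2, 8, 22))]
        city = toy_city(parks, residences, g)
        cc = CatchmentConfig(mode="uniform", d0_uniform=2500.0)
        q_wild = {p.park_id: ParkQuality(park_id=p.park_id, S=p.area_hm2,
                                         ESV=-7.0, FCs=p.area_hm2 * 0.5)
                  for p in parks}
        got = compute_accessibility(city, q_wild, area_only_weights(), cc)
        want = self.brute_force(city, constant_quality(parks),
                                area_only_weights(), cc)
        for rid, val in want.items():
            assert got.loc[rid, "A"] == pytest.approx(val, abs=1e-9)


class TestConservationOnRandomCities:
    @pytest.mark.parametrize("seed", [101, 202])
    def test_population_weighted_total_equals_supply(self, seed):
        city = generate_city(small_scenario(seed=seed))
        qualities = constant_quality(city.parks, esv=20.0)
        cc = CatchmentConfig(mode="type_specific")
        dist = residence_park_distances(city, cc.max_radius)
        ratios = supply_demand_ratios(city, qualities, DEFAULT_WEIGHTS, cc, dist)
        acc = accessibility(city, ratios, dist, cc)
        total = float((acc["A"] * acc["population"]).sum())
        served = ratios[ratios["D_j"] > 0]
        assert total == pytest.approx(float(served["C_j"].sum()), abs=1e-9)

    def test_weighted_accessibility_nondecreasing_in_radius(self):
        """Enlarging the uniform walking distance never lowers the
        population-weighted accessibility total: the total equals the supply
        of parks with positive demand, and the served-park set only grows
        with the radius."""
        for seed in range(31, 41):
            city = generate_city(small_scenario(seed=seed))
            qualities = constant_quality(city.parks, esv=20.0)
            totals = []
            for d0 in (500.0, 1000.0, 2000.0, 3000.0):
                cc = CatchmentConfig(mode="uniform", d0_uniform=d0)
                acc = compute_accessibility(city, qualities, DEFAULT_WEIGHTS, cc)
                totals.append(float((acc["A"] * acc["population"]).sum()))
            assert all(b >= a - 1e-9 for a, b in zip(totals, totals[1:])), \
                (seed, totals)


class TestClassifyGeometric:
    def test_exact_geometric_progression(self):
        labels, breaks, low = classify_geometric(
            np.array([1.0, 10.0, 100.0, 1000.0]), 3)
        assert breaks == pytest.approx([10.0, 100.0])
        assert list(labels) == [1, 1, 2, 3]
        assert low == pytest.approx(10.0)

    def test_zero_scores_form_own_class(self):
        vals = np.array([0.0, 0.0, 1.0, 4.0, 16.0])
        labels, _, _ = classify_geometric(vals, 3)
        assert list(labels[:2]) == [0, 0]
        assert (labels[2:] > 0).all()

    def test_counts_match_independent_binning(self):
        rng = np.random.default_rng(7)
        vals = rng.lognormal(mean=1.0, sigma=1.2, size=200)
        labels, breaks, _ = classify_geometric(vals, 5)
        edges = [0.0] + breaks + [np.inf]
        for m in range(1, 6):
            want = ((vals > edges[m - 1]) & (vals <= edges[m])).sum()
            assert (labels == m).sum() == want

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            labels, breaks, low = classify_geometric(np.zeros(5), 4)
        assert (labels == 0).all()

    def test_too_few_distinct_positive(self):
        with pytest.raises(ValueError, match="distinct positive"):
            classify_geometric(np.array([1.0, 1.0, 2.0]), 3)
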