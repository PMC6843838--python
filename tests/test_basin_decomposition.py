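"""Basin decomposition: minima, steepest-ratio descent, persistence, selection."""

import numpy as np
import pytest

from basinselect.basin_decomposition import (
    Basin,
    assign_basins,
    basin_subgraph_components,
    compute_persistence,
    decompose,
    find_local_minima,
    select_largest_basin,
)
from basinselect.structures_io import DistanceStore
from conftest import make_graph, random_graph_instance
from oracles import (
    closed_neighborhood_minima,
    descent_partition,
    persistence_sweep,
)


class TestLocalMinima:
    def test_path_single_minimum(self):
        g = make_graph(["a", "b", "c"], [("a", "b", 1.0), ("b", "c", 1.0)])
        assert find_local_minima(g, {"a": 3.0, "b": 1.0, "c": 2.0}) == {"b"}

    def test_plateau_tie_break_by_id(self):
        g = make_graph(["a", "b"], [("a", "b", 1.0)])
        assert find_local_minima(g, {"a": 2.0, "b": 2.0}) == {"a"}

    def test_isolated_vertex_is_minimum(self):
        g = make_graph(["a", "b", "c"], [("a", "b", 1.0)])
        assert "c" in find_local_minima(g, {"a": 1.0, "b": 2.0, "c": 9.0})

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            ids, edge_list, energies = random_graph_instance(rng, n_max=50)
            g = make_graph(ids, edge_list)
            expected = closed_neighborhood_minima(
                ids, g.edges, g.edge_dist, energies
            )
            assert find_local_minima(g, energies) == expected


class TestAssignBasins:
    def test_hand_traced_path(self, path_graph_5):
        g, energies = path_graph_5
        basins = {b.focal_id: set(b.members) for b in assign_basins(g, energies)}
        # v3 descends to v4: (4-2)/1 beats (4-3)/1
        assert basins == {"v2": {"v1", "v2"}, "v5": {"v3", "v4", "v5"}}

    def test_single_vertex(self):
        g = make_graph(["a"], [])
        (b,) = assign_basins(g, {"a": 1.5})
        assert b.focal_id == "a" and b.size == 1

    def test_matches_path_following_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            ids, edge_list, energies = random_graph_instance(rng, n_max=60)
            g = make_graph(ids, edge_list)
            expected = descent_partition(ids, g.edges, g.edge_dist, energies)
            got = {}
            for b in assign_basins(g, energies):
                for m in b.members:
                    got[m] = b.focal_id
            assert got == expected

    def test_partition_and_focal_invariants(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            ids, edge_list, energies = random_graph_instance(rng, n_max=40)
            g = make_graph(ids, edge_list)
            basins = assign_basins(g, energies)
            all_members = [m for b in basins for m in b.members]
            assert sorted(all_members) == sorted(ids)  # disjoint cover
            minima = find_local_minima(g, energies)
            assert {b.focal_id for b in basins} == minima
            for b in basins:
                assert b.focal_energy == min(energies[m] for m in b.members)


class TestPersistence:
    def test_hand_traced_path(self, path_graph_5):
        g, energies = path_graph_5
        minima = find_local_minima(g, energies)
        pers = compute_persistence(g, energies, minima)
        assert pers == {"v2": pytest.approx(1.0), "v5": pytest.approx(4.0)}

    def test_single_funnel_survivor_gets_range(self):
        ids = ["a", "b", "c", "d"]
        g = make_graph(ids, [(ids[i], ids[i + 1], 1.0) for i in range(3)])
        energies = {"a": 4.0, "b": 2.0, "c": 1.0, "d": 3.0}
        pers = compute_persistence(g, energies, find_local_minima(g, energies))
        assert pers["c"] == pytest.approx(3.0)  # e_max - e_min

    def test_matches_sweep_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            ids, edge_list, energies = random_graph_instance(rng, n_max=30)
            g = make_graph(ids, edge_list)
            minima = find_local_minima(g, energies)
            got = compute_persistence(g, energies, minima)
            expected = persistence_sweep(ids, g.edges, g.edge_dist, energies)
            assert set(got) == set(expected)
            for m in got:
                assert got[m] == pytest.approx(expected[m], abs=1e-9)

    def test_deepest_minimum_has_max_persistence(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            ids, edge_list, energies = random_graph_instance(rng, n_max=40)
            g = make_graph(ids, edge_list)
            minima = find_local_minima(g, energies)
            pers = compute_persistence(g, energies, minima)
            labels = g.component_labels()
            comp_of = {i: labels[k] for k, i in enumerate(g.ids)}
            for comp in set(comp_of.values()):
                comp_minima = [m for m in minima if comp_of[m] == comp]
                deepest = min(comp_minima, key=lambda m: (energies[m], m))
                assert all(
                    pers[deepest] >= pers[m] - 1e-12 for m in comp_minima
                )


class TestSubgraphComponents:
    def test_singleton_basin(self):
        b = Basin(focal_id="a", members=["a"], focal_energy=0.0, avg_energy=0.0)
        store = DistanceStore(["a"], np.zeros((1, 1)))
        assert basin_subgraph_components(b, store) == 1

    def test_equidistant_clique_is_one_component(self):
        ids = ["a", "b", "c", "d"]
        D = np.full((4, 4), 1.0)
        np.fill_diagonal(D, 0.0)
        b = Basin(focal_id="a", members=ids, focal_energy=0.0, avg_energy=0.0)
        # pdist = 1.0 -> eps = 2.0 -> complete graph
        assert basin_subgraph_components(b, DistanceStore(ids, D)) == 1

    def test_two_separated_clumps(self):
        ids = ["a", "b", "c", "d"]
        D = np.array(
            [
                [0.0, 0.5, 20.0, 20.0],
                [0.5, 0.0, 20.0, 20.0],
                [20.0, 20.0, 0.0, 0.5],
                [20.0, 20.0, 0.5, 0.0],
            ]
        )
        b = Basin(focal_id="a", members=ids, focal_energy=0.0, avg_energy=0.0)
        # pdist ~ 13.5, eps ~ 14.5 << 20 between clumps
        assert basin_subgraph_components(b, DistanceStore(ids, D)) == 2


class TestSelectLargest:
    def make(self, focal, size, energy):
        return Basin(
            focal_id=focal,
            members=[focal] + [f"{focal}_{i}" for i in range(size - 1)],
            focal_energy=energy,
            avg_energy=energy,
        )

    def test_largest_wins(self):
        basins = [self.make("a", 10, 0.0), self.make("b", 3, -5.0), self.make("c", 3, -9.0)]
        assert select_largest_basin(basins).focal_id == "a"

    def test_size_tie_broken_by_energy(self):
        basins = [self.make("a", 5, -2.0), self.make("b", 5, -7.0)]
        assert select_largest_basin(basins).focal_id == "b"

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            basins = [
                self.make(f"f{i}", int(rng.integers(1, 8)), float(rng.normal()))
                for i in range(int(rng.integers(1, 10)))
            ]
            got = select_largest_basin(basins)
            best = sorted(
                basins, key=lambda b: (-b.size, b.focal_energy, b.focal_id)
            )[0]
            assert got is best

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_largest_basin([])


def test_decompose_fills_features(path_graph_5, store_from_points):
    g, energies = path_graph_5
    points = np.arange(5, dtype=float)[:, None]
    store = store_from_points(points, ids=g.ids)
    basins = decompose(g, energies, distances=store)
    for b in basins:
        assert b.persistence is not None and b.persistence >= 0
        assert b.n_components >= 1


def test_export_basins(tmp_path, path_graph_5):
    import json

    from basinselect.basin_decomposition import export_basins

    g, energies = path_graph_5
    basins = assign_basins(g, energies)
    json_path, tsv_path = export_basins(basins, tmp_path)
    report = json.loads(json_path.read_text())
    assert {r["focal_id"] for r in report} == {"v2", "v5"}
    lines = tsv_path.read_text().strip().splitlines()
    assert len(lines) == 6  # header + 5 vertices
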