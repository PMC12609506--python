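"""Maximum matching, driver sets, node classifications, control capacity and
centrality, checked against toy enumerations and a numeric Kalman-rank oracle."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tepcontrol.controllability import (
    classify_mds_membership,
    classify_node_removal,
    compare_classes,
    control_capacity,
    control_centrality,
    driver_count_and_set,
    maximum_matching,
    minimum_steering_set,
    node_control_profiles,
    topology_metrics,
)
from tepcontrol.errors import UsageError
from tests.conftest import brute_min_drivers, kalman_generic_rank, random_digraph


class TestMaximumMatching:
    @pytest.mark.parametrize("name,size", [("chain3", 2), ("star4", 1), ("cycle3", 3)])
    def test_toy_matching_sizes(self, toys, name, size):
        assert maximum_matching(toys[name]).size == size

    def test_star_maximum_is_one_by_enumeration(self, toys):
        # all matchings of the star's bipartite representation have size <= 1
        links = [("h", v) for v in "abc"]
        best = 0
        for k in range(1, len(links) + 1):
            for combo in itertools.combinations(links, k):
                outs = [u for u, _ in combo]
                ins = [v for _, v in combo]
                if len(set(outs)) == k and len(set(ins)) == k:
                    best = max(best, k)
        assert best == maximum_matching(toys["star4"]).size == 1

    def test_canonical_matching_is_deterministic(self, toys):
        a = maximum_matching(toys["star4"])
        b = maximum_matching(toys["star4"])
        assert a.pairs == b.pairs == frozenset({("h", "a")})

    def test_adding_an_edge_never_decreases_matching_size(self):
        for seed in range(10):
            net = random_digraph(8, 0.15, seed)
            base = maximum_matching(net).size
            bigger = net.copy()
            candidates = [
                (u, v)
                for u in net
                for v in net
                if u != v and not net.has_edge(u, v)
            ]
            if candidates:
                bigger.add_edge(*candidates[seed % len(candidates)])
                assert maximum_matching(bigger).size >= base


class TestDriverSets:
    def test_chain_single_driver(self, toys):
        net = toys["chain3"]
        n_d, drivers = driver_count_and_set(net, maximum_matching(net))
        assert (n_d, drivers) == (1, frozenset({"a"}))

    def test_star_three_drivers(self, toys):
        net = toys["star4"]
        n_d, drivers = driver_count_and_set(net, maximum_matching(net))
        assert n_d == 3 and drivers == frozenset({"h", "b", "c"})

    def test_cycle_perfect_matching_convention(self, toys):
        net = toys["cycle3"]
        n_d, drivers = driver_count_and_set(net, maximum_matching(net))
        assert (n_d, drivers) == (1, frozenset({"a"}))

    def test_driver_count_matches_kalman_oracle_exhaustively_n3(self):
        # every labelled 3-node digraph, self-loops included
        labels = ["a", "b", "c"]
        arcs = [(u, v) for u in labels for v in labels]
        for mask in range(2 ** len(arcs)):
            net = nx.DiGraph()
            net.add_nodes_from(labels)
            for i, arc in enumerate(arcs):
                if mask >> i & 1:
                    net.add_edge(*arc)
            n_d, _ = driver_count_and_set(net, maximum_matching(net))
            assert n_d == brute_min_drivers(net, draws=3, seed=mask), nx.to_dict_of_lists(net)

    @pytest.mark.parametrize("seed", range(30))
    def test_driver_count_matches_kalman_oracle_on_random_graphs(self, seed):
        n = 4 + seed % 3  # N in {4, 5, 6}
        net = random_digraph(n, 0.25, seed, self_loops=seed % 2 == 0)
        n_d, _ = driver_count_and_set(net, maximum_matching(net))
        assert n_d == brute_min_drivers(net, seed=seed)


class TestMdsClassification:
    def test_star_classes(self, toys):
        assert classify_mds_membership(toys["star4"]) == {
            "h": "critical",
            "a": "intermittent",
            "b": "intermittent",
            "c": "intermittent",
        }

    def test_chain_classes(self, toys):
        assert classify_mds_membership(toys["chain3"]) == {
            "a": "critical",
            "b": "redundant",
            "c": "redundant",
        }

    def test_perfect_matching_makes_all_nodes_intermittent(self, toys):
        classes = classify_mds_membership(toys["cycle3"])
        assert set(classes.values()) == {"intermittent"}

    @pytest.mark.parametrize("seed", range(20))
    def test_zero_in_degree_implies_critical_and_classes_partition(self, seed):
        net = random_digraph(12, 0.12, seed)
        classes = classify_mds_membership(net)
        assert set(classes) == set(net.nodes())
        matching = maximum_matching(net)
        if matching.size < net.number_of_nodes():  # non-perfect case
            for v in net:
                if net.in_degree(v) == 0:
                    assert classes[v] == "critical"

    @pytest.mark.parametrize("seed", range(10))
    def test_classes_agree_with_mds_enumeration(self, seed):
        net = random_digraph(7, 0.2, seed)
        matching = maximum_matching(net)
        if matching.size == net.number_of_nodes():
            return
        n_d = net.number_of_nodes() - matching.size
        # enumerate MDSs independently: subsets whose complement in-copies
        # can all be matched simultaneously
        all_mds = []
        for combo in itertools.combinations(sorted(net.nodes()), n_d):
            rest = set(net.nodes()) - set(combo)
            bip = nx.DiGraph()
            for u, v in net.edges():
                if v in rest:
                    bip.add_edge(("out", u), ("in", v))
            match = nx.bipartite.maximum_matching(
                nx.Graph(bip), top_nodes=[n for n in bip if n[0] == "out"]
            )
            if len(match) // 2 == len(rest):
                all_mds.append(set(combo))
        classes = classify_mds_membership(net)
        for v in net:
            appearances = sum(v in d for d in all_mds)
            expected = (
                "critical"
                if appearances == len(all_mds)
                else "redundant"
                if appearances == 0
                else "intermittent"
            )
            assert classes[v] == expected


class TestRemovalClassification:
    def test_chain_middle_is_indispensable(self, toys):
        assert classify_node_removal(toys["chain3"]) == {
            "a": "neutral",
            "b": "indispensable",
            "c": "neutral",
        }

    def test_star_leaves_are_dispensable_hub_neutral(self, toys):
        classes = classify_node_removal(toys["star4"])
        assert classes["h"] == "neutral"
        assert all(classes[v] == "dispensable" for v in "abc")

    def test_single_edge_source_removal_is_neutral(self):
        net = nx.DiGraph([("a", "b")])
        assert classify_node_removal(net)["a"] == "neutral"

    @pytest.mark.parametrize("seed", range(20))
    def test_classes_partition_the_node_set(self, seed):
        net = random_digraph(12, 0.12, seed)
        classes = classify_node_removal(net)
        assert set(classes) == set(net.nodes())
        assert set(classes.values()) <= {"indispensable", "neutral", "dispensable"}


class TestControlCapacity:
    def test_star_exact_capacities(self, toys):
        cap = control_capacity(toys["star4"])
        assert cap["h"] == 1.0
        assert cap["a"] == pytest.approx(2 / 3)

    def test_chain_unique_matching_capacities(self, toys):
        cap = control_capacity(toys["chain3"])
        assert cap == {"a": 1.0, "b": 0.0, "c": 0.0}

    def test_sampled_estimate_converges_on_star(self, toys):
        cap = control_capacity(toys["star4"], n_samples=1000, seed=11, exact_below=0)
        assert cap["a"] == pytest.approx(2 / 3, abs=0.05)
        assert cap["h"] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_sampled_matches_enumerated_on_small_graphs(self, seed):
        net = random_digraph(9, 0.15, seed)
        exact = control_capacity(net)
        sampled = control_capacity(net, n_samples=2000, seed=seed, exact_below=0)
        classes = classify_mds_membership(net)
        for v in net:
            if classes[v] == "critical":
                assert exact[v] == sampled[v] == 1.0
            elif classes[v] == "redundant":
                assert exact[v] == sampled[v] == 0.0
            else:
                assert sampled[v] == pytest.approx(exact[v], abs=0.05)


class TestControlCentrality:
    def test_chain_head_controls_everything(self, toys):
        assert control_centrality(toys["chain3"], "a") == 3

    def test_star_hub_controls_two_dimensions(self, toys):
        assert control_centrality(toys["star4"], "h") == 2

    def test_isolated_node_controls_itself(self):
        net = nx.DiGraph()
        net.add_node("solo")
        assert control_centrality(net, "solo") == 1

    def test_unknown_node_is_an_error(self, toys):
        with pytest.raises(UsageError):
            control_centrality(toys["chain3"], "zz")

    @pytest.mark.parametrize("seed", range(100))
    def test_equals_numeric_kalman_generic_rank(self, seed):
        n = 4 + seed % 7  # N in 4..10
        net = random_digraph(n, 0.2, seed, self_loops=seed % 3 == 0)
        node = sorted(net.nodes())[seed % n]
        assert control_centrality(net, node) == kalman_generic_rank(
            net, [node], draws=5, seed=seed
        )


class TestMinimumSteeringSet:
    def test_chain_and_star(self, toys):
        assert minimum_steering_set(toys["chain3"]) == frozenset({"a"})
        assert minimum_steering_set(toys["star4"]) == frozenset({"h", "b", "c"})

    @pytest.mark.parametrize("seed", range(50))
    def test_contains_all_critical_nodes_and_has_driver_size(self, seed):
        net = random_digraph(10, 0.15, seed)
        mss = minimum_steering_set(net)
        n_d, _ = driver_count_and_set(net, maximum_matching(net))
        assert len(mss) == n_d
        classes = classify_mds_membership(net)
        critical = {v for v, c in classes.items() if c == "critical"}
        if maximum_matching(net).size < net.number_of_nodes():
            assert critical <= mss


class TestTopologyMetrics:
    def test_chain_middle_betweenness_and_stress(self, toys):
        metrics = topology_metrics(toys["chain3"])
        assert metrics.loc["b", "betweenness"] == 1.0
        assert metrics.loc["b", "stress"] == 2.0  # both orderings of the a-c pair
        assert metrics.loc["a", "clustering_coefficient"] == 0.0

    def test_triangle_clustering_is_one(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        metrics = topology_metrics(net)
        assert (metrics["clustering_coefficient"] == 1.0).all()

    def test_reciprocal_edges_counted_as_multi_edge_partners(self):
        net = nx.DiGraph([("a", "b"), ("b", "a"), ("b", "c")])
        metrics = topology_metrics(net)
        assert metrics.loc["a", "multi_edge_partner_count"] == 1
        assert metrics.loc["c", "multi_edge_partner_count"] == 0

    def test_values_are_finite(self):
        net = random_digraph(9, 0.3, 3)
        metrics = topology_metrics(net)
        assert np.isfinite(metrics.to_numpy(dtype=float)).all()


class TestCompareClasses:
    def frame(self, values):
        return pd.DataFrame({"metric": values})

    def test_fully_separated_small_groups_exact_p(self):
        metrics = self.frame({"a": 1, "b": 2, "c": 3, "d": 4, "e": 5, "f": 6})
        labels = {"a": "lo", "b": "lo", "c": "lo", "d": "hi", "e": "hi", "f": "hi"}
        u, p = compare_classes(metrics, labels, "metric", "lo", "hi")
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        metrics = self.frame(
            {"a": 1, "b": 2, "c": 3, "d": 1, "e": 2, "f": 3}
        )
        labels = {"a": "x", "b": "x", "c": "x", "d": "y", "e": "y", "f": "y"}
        _, p = compare_classes(metrics, labels, "metric", "x", "y")
        assert p == pytest.approx(1.0)

    def test_planted_location_shift_is_detected(self):
        rng = np.random.default_rng(5)
        values = {}
        labels = {}
        for i in range(50):
            values[f"a{i}"] = rng.normal(0, 1)
            labels[f"a{i}"] = "ctrl"
            values[f"b{i}"] = rng.normal(1.5, 1)
            labels[f"b{i}"] = "shift"
        _, p = compare_classes(self.frame(values), labels, "metric", "ctrl", "shift")
        assert p < 0.01

    def test_empty_class_is_an_error(self):
        metrics = self.frame({"a": 1})
        with pytest.raises(UsageError):
            compare_classes(metrics, {"a": "x"}, "metric", "x", "y")


class TestProfiles:
    def test_profile_table_is_consistent(self, toys):
        profiles = node_control_profiles(toys["star4"], seed=1, n_samples=50)
        assert list(profiles.index) == ["a", "b", "c", "h"]
        assert profiles["mds_class"].value_counts().sum() == 4
        assert profiles["removal_class"].value_counts().sum() == 4
        assert profiles.loc["h", "is_driver_canonical"]
        assert profiles.loc["h", "in_mss"]
        assert "betweenness" in profiles.columns
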