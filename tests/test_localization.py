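import numpy as np
import pytest
from scipy import stats as sps

import oracles
from phenonet import (
    InteractionNetwork,
    build_module,
    is_localized,
    localization_stats,
    mean_shortest_distance,
    module_size,
    sample_localization_null,
    sample_random_module,
)
from phenonet.fixtures import generate_network, plant_module
from conftest import random_graph_cases


class TestBuildModule:
    def test_intersection_and_induced_edges(self, path_graph):
        mod = build_module(path_graph, "p", {"a", "b", "x"})
        assert mod.members == {"a", "b"}
        assert mod.induced_edges == {frozenset({"a", "b"})}

    def test_disjoint_genes_give_empty_module(self, path_graph):
        assert build_module(path_graph, "p", {"x", "y"}).members == frozenset()

    def test_all_nodes(self, path_graph):
        mod = build_module(path_graph, "p", set("abcd"))
        assert mod.members == path_graph.nodes
        assert len(mod.induced_edges) == path_graph.number_of_edges


class TestModuleStatistics:
    def test_split_module_largest_component(self, path_graph, path_modules):
        assert module_size(path_graph, path_modules["abd"]) == 2

    def test_single_edge_and_isolated(self, path_graph, path_modules):
        assert module_size(path_graph, path_modules["ab"]) == 2
        assert module_size(path_graph, path_modules["ad"]) == 1

    def test_empty_module_rejected(self, path_graph):
        with pytest.raises(ValueError):
            module_size(path_graph, build_module(path_graph, "p", set()))

    def test_distance_through_nonmembers(self, path_graph, path_modules):
        # members a, d: the path runs through non-members b, c
        assert mean_shortest_distance(path_graph, path_modules["ad"]) == 3.0

    def test_distance_mixed(self, path_graph, path_modules):
        assert mean_shortest_distance(path_graph, path_modules["abd"]) == pytest.approx(4 / 3)

    def test_clique_distance_is_one(self):
        net = InteractionNetwork.from_edges(
            [("a", "b"), ("a", "c"), ("b", "c")]
        )
        mod = build_module(net, "p", {"a", "b", "c"})
        assert mean_shortest_distance(net, mod) == 1.0

    def test_fewer_than_two_members_rejected(self, path_graph):
        with pytest.raises(ValueError):
            mean_shortest_distance(path_graph, build_module(path_graph, "p", {"a"}))

    def test_all_unreachable_rejected(self):
        net = InteractionNetwork.from_edges([], nodes=["a", "b"])
        mod = build_module(net, "p", {"a", "b"})
        with pytest.raises(ValueError, match="unreachable"):
            mean_shortest_distance(net, mod)

    @pytest.mark.parametrize("case", random_graph_cases(40, seed=11), ids=lambda c: "")
    def test_agrees_with_brute_force(self, case):
        nodes, edges, mem_a, _ = case
        net = InteractionNetwork.from_edges(edges, nodes)
        dist = oracles.all_pairs(oracles.adjacency(nodes, edges))
        mod = build_module(net, "p", mem_a)
        assert module_size(net, mod) == oracles.module_size(dist, mem_a)
        expected, _ = oracles.mean_shortest_distance(dist, mem_a)
        if expected is None:
            with pytest.raises(ValueError):
                mean_shortest_distance(net, mod)
        else:
            assert mean_shortest_distance(net, mod) == pytest.approx(expected, abs=1e-12)

    def test_adding_member_edge_monotone(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            nodes, edges, mem, _ = random_graph_cases(1, seed=int(rng.integers(1 << 30)))[0]
            net = InteractionNetwork.from_edges(edges, nodes)
            mod = build_module(net, "p", mem)
            members = sorted(mod.members)
            if len(members) < 2:
                continue
            s0 = module_size(net, mod)
            try:
                d0 = mean_shortest_distance(net, mod)
            except ValueError:
                d0 = None
            net.graph.add_edge(members[0], members[1])
            mod2 = build_module(net, "p", mem)
            assert module_size(net, mod2) >= s0
            if d0 is not None:
                assert mean_shortest_distance(net, mod2) <= d0 + 1e-12


class TestRandomModuleSampling:
    def test_full_and_oversized(self, path_graph):
        assert sample_random_module(path_graph, 4, 0) == set("abcd")
        with pytest.raises(ValueError):
            sample_random_module(path_graph, 5, 0)

    def test_determinism(self, path_graph):
        a = sample_random_module(path_graph, 2, 42)
        b = sample_random_module(path_graph, 2, 42)
        assert a == b

    def test_uniformity_chi_square(self):
        net = generate_network(20, 0.2, seed=3)
        nodes = net.node_list()
        rng = np.random.default_rng(7)
        counts = {v: 0 for v in nodes}
        n_draws = 10_000
        for _ in range(n_draws):
            (v,) = sample_random_module(net, 1, rng)
            counts[v] += 1
        chi2 = sps.chisquare([counts[v] for v in nodes])
        assert chi2.pvalue > 0.01


@pytest.fixture(scope="module")
def er_net():
    return generate_network(300, 0.02, seed=1)


class TestLocalizationStats:
    def test_null_self_consistency(self, er_net):
        """A uniformly random module should sit inside the null's bulk."""
        rng = np.random.default_rng(2)
        members = sample_random_module(er_net, 15, rng)
        mod = build_module(er_net, "rand", members)
        st = localization_stats(er_net, mod, n_perm=500, rng=rng)
        assert abs(st.z_size) < 4
        assert abs(st.z_dist) < 4
        assert 0 < st.p_size <= 1
        assert 0 < st.p_dist <= 1

    def test_planted_module_detected(self):
        net = generate_network(500, 0.01, seed=10)
        members = plant_module(net, 20, 0.5, seed=11)
        mod = build_module(net, "planted", set(members))
        st = localization_stats(net, mod, n_perm=1000, rng=12)
        assert st.z_size >= 1.6
        assert st.z_dist <= -1.6
        assert is_localized(st) == (True, True)

    def test_pseudocount_floor(self, er_net):
        """p-values can never reach 0: the best case is 1/(n_perm+1)."""
        members = plant_module(er_net, 12, 1.0, seed=4)  # an induced clique
        mod = build_module(er_net, "clique", set(members))
        st = localization_stats(er_net, mod, n_perm=200, rng=5)
        assert st.p_size >= 1 / 201
        assert st.p_dist >= 1 / 201

    def test_shared_null_matches_size(self, er_net):
        null = sample_localization_null(er_net, 10, 100, rng=6)
        mod = build_module(er_net, "p", sample_random_module(er_net, 9, 8))
        with pytest.raises(ValueError, match="size"):
            localization_stats(er_net, mod, null=null)

    def test_degree_binned_variant_runs(self, er_net):
        members = sample_random_module(er_net, 10, 13)
        mod = build_module(er_net, "p", members)
        st = localization_stats(er_net, mod, n_perm=100, rng=14, degree_binned=True)
        assert st.n_perm == 100

    def test_z_scale_invariance_of_distance_ranks(self, er_net):
        """Rescaling d_A and the null together leaves the z-score unchanged."""
        rng = np.random.default_rng(9)
        mod = build_module(er_net, "p", sample_random_module(er_net, 12, rng))
        st = localization_stats(er_net, mod, n_perm=300, rng=rng)
        scale = 7.3
        z_scaled = (st.mean_distance * scale - st.null_mean_dist * scale) / (
            st.null_sd_dist * scale
        )
        assert z_scaled == pytest.approx(st.z_dist, rel=1e-12)


class TestIsLocalized:
    def test_strongly_localized_example(self):
        st = _stats_stub(z_size=2.0, z_dist=-5.51)
        assert is_localized(st) == (True, True)

    def test_null_case(self):
        assert is_localized(_stats_stub(z_size=0.0, z_dist=0.0)) == (False, False)

    def test_threshold_inclusive(self):
        assert is_localized(_stats_stub(z_size=1.6, z_dist=-1.6)) == (True, True)
        assert is_localized(_stats_stub(z_size=1.59, z_dist=-1.59)) == (False, False)


def _stats_stub(z_size, z_dist):
    from phenonet.localization import LocalizationStats

    return LocalizationStats(
        phenotype_id="p", n_members=5, module_size=3, mean_distance=1.5,
        null_mean_size=2.0, null_sd_size=1.0, null_mean_dist=2.0, null_sd_dist=0.5,
        z_size=z_size, z_dist=z_dist, p_size=0.5, p_dist=0.5, n_perm=10, n_isolated=0,
    )
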