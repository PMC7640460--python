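import math

import networkx as nx
import numpy as np
import pytest

from salign.aligner import (
    CandidateSet,
    Params,
    alignment_scores,
    greedy_align,
    mc_align,
    mc_probabilities,
    normalize_topn,
    topn_candidates,
)
from salign.biosim import SimMatrix


def sim(entries):
    return SimMatrix(role="alignment", entries=entries, normalized=True)


class TestParams:
    def test_defaults(self):
        p = Params()
        assert (p.alpha, p.beta, p.d, p.n_top, p.kT) == (0.1, 0.7, 10, 10, 0.1)

    def test_low_structure_preset(self):
        assert Params.low_structure().beta == 0.9

    @pytest.mark.parametrize(
        "kwargs",
        [dict(alpha=1.5), dict(beta=-0.1), dict(d=0), dict(n_top=0), dict(kT=0.0)],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Params(**kwargs)


class TestAlignmentScores:
    def test_biology_contributes_ninety_percent_at_alpha_point_one(self):
        T = sim({("a", "x"): 0.0})
        B = SimMatrix("biological", {("a", "x"): 1.0}, normalized=True)
        assert alignment_scores(T, B, 0.1).entries[("a", "x")] == pytest.approx(0.9)

    def test_alpha_one_returns_topology_exactly(self):
        T = sim({("a", "x"): 0.3, ("b", "y"): 0.8})
        B = SimMatrix("biological", {("a", "x"): 0.9}, normalized=True)
        out = alignment_scores(T, B, 1.0)
        assert out.entries == pytest.approx(T.entries)

    def test_halfway_blend(self):
        T = sim({("a", "x"): 0.2})
        B = SimMatrix("biological", {("a", "x"): 0.6}, normalized=True)
        assert alignment_scores(T, B, 0.5).entries[("a", "x")] == pytest.approx(0.4)

    def test_union_of_supports_with_missing_as_zero(self):
        T = sim({("a", "x"): 0.4})
        B = SimMatrix("biological", {("b", "y"): 0.6}, normalized=True)
        out = alignment_scores(T, B, 0.5)
        assert out.entries[("a", "x")] == pytest.approx(0.2)
        assert out.entries[("b", "y")] == pytest.approx(0.3)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            alignment_scores(sim({}), SimMatrix("biological", {}, True), -0.2)

    def test_monotone_in_both_components(self):
        B = SimMatrix("biological", {("a", "x"): 0.5}, normalized=True)
        lo = alignment_scores(sim({("a", "x"): 0.1}), B, 0.3)
        hi = alignment_scores(sim({("a", "x"): 0.9}), B, 0.3)
        assert hi.entries[("a", "x")] > lo.entries[("a", "x")]


class TestCandidates:
    A = sim({("u", "x"): 0.9, ("u", "y"): 0.5, ("u", "z"): 0.1})

    def test_top_k_selection(self):
        cs = topn_candidates(self.A, "u", {"x", "y", "z"}, 2)
        assert cs.candidates == [("x", 0.9), ("y", 0.5)]

    def test_n_top_larger_than_pool_returns_all(self):
        cs = topn_candidates(self.A, "u", {"x", "y", "z"}, 10)
        assert len(cs) == 3

    def test_aligned_partners_excluded(self):
        cs = topn_candidates(self.A, "u", {"y", "z"}, 2)
        assert cs.candidates == [("y", 0.5), ("z", 0.1)]

    def test_no_candidates_yields_empty_set(self):
        assert len(topn_candidates(self.A, "v", {"x"}, 3)) == 0

    def test_matches_brute_force_sort_and_slice(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            entries = {
                ("u", f"v{i:02d}"): float(rng.integers(0, 5)) / 4 for i in range(12)
            }
            A = sim(entries)
            pool = {f"v{i:02d}" for i in range(12)}
            expect = sorted(
                ((v, s) for (_, v), s in entries.items()), key=lambda t: (-t[1], t[0])
            )[:4]
            assert topn_candidates(A, "u", pool, 4).candidates == expect


class TestNormalizeTopn:
    def test_proportional_normalization(self):
        cs = normalize_topn(CandidateSet([("x", 0.9), ("y", 0.5), ("z", 0.1)]))
        assert cs.normalized == pytest.approx([0.6, 1 / 3, 1 / 15])
        assert sum(cs.normalized) == pytest.approx(1.0, abs=1e-9)

    def test_single_candidate(self):
        assert normalize_topn(CandidateSet([("x", 0.7)])).normalized == [1.0]

    def test_equal_scores_are_uniform(self):
        cs = normalize_topn(CandidateSet([("x", 0.4), ("y", 0.4), ("z", 0.4)]))
        assert cs.normalized == pytest.approx([1 / 3] * 3)

    def test_all_zero_scores_fall_back_to_uniform(self):
        cs = normalize_topn(CandidateSet([("x", 0.0), ("y", 0.0)]))
        assert cs.normalized == pytest.approx([0.5, 0.5])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            normalize_topn(CandidateSet([]))


class TestMcProbabilities:
    def test_equal_normalized_scores_give_uniform(self):
        cs = CandidateSet([("x", 1.0)] * 4, normalized=[0.25] * 4)
        probs = mc_probabilities(cs, kT=0.1).probabilities
        assert probs == pytest.approx([0.25] * 4)

    def test_worked_boltzmann_case(self):
        # NS=[0.6, 0.4], kT=0.1: weights e^0 and e^-2
        cs = CandidateSet([("x", 0.6), ("y", 0.4)], normalized=[0.6, 0.4])
        probs = mc_probabilities(cs, kT=0.1).probabilities
        e0, e2 = 1.0, math.exp(-2.0)
        assert probs == pytest.approx([e0 / (e0 + e2), e2 / (e0 + e2)])
        assert probs == pytest.approx([0.8808, 0.1192], abs=1e-4)

    def test_low_temperature_collapses_onto_best(self):
        cs = CandidateSet([("x", 0.6), ("y", 0.4)], normalized=[0.6, 0.4])
        probs = mc_probabilities(cs, kT=1e-6).probabilities
        assert probs[0] == pytest.approx(1.0)

    def test_sum_to_one_and_best_is_mode(self):
        cs = CandidateSet(
            [("w", 1)] * 4, normalized=[0.1, 0.45, 0.25, 0.2]
        )
        probs = mc_probabilities(cs, kT=0.1).probabilities
        assert sum(probs) == pytest.approx(1.0, abs=1e-9)
        assert max(range(4), key=lambda i: probs[i]) == 1

    def test_shift_invariance(self):
        base = CandidateSet([("w", 1)] * 3, normalized=[0.5, 0.3, 0.2])
        shifted = CandidateSet([("w", 1)] * 3, normalized=[1.5, 1.3, 1.2])
        assert mc_probabilities(base, 0.1).probabilities == pytest.approx(
            mc_probabilities(shifted, 0.1).probabilities
        )


def two_edge_networks():
    net1 = nx.Graph([("a", "b"), ("c", "d")])
    net2 = nx.Graph([("x", "y"), ("z", "w")])
    return net1, net2


class TestGreedyAlign:
    def test_single_entry_matrix(self):
        net1 = nx.Graph()
        net1.add_node("a")
        net2 = nx.Graph()
        net2.add_node("x")
        aln = greedy_align(sim({("a", "x"): 0.5}), net1, net2)
        assert aln.pairs == [("a", "x", 0.5)]

    def test_frontier_prioritizes_neighbors_of_aligned_pairs(self):
        # seed (a,x); the frontier then holds only (b,y); (b,y) wins despite
        # lower global rank than nothing else
        net1, net2 = two_edge_networks()
        A = sim({("a", "x"): 0.9, ("b", "y"): 0.8, ("a", "y"): 0.1, ("b", "x"): 0.1})
        aln = greedy_align(A, net1, net2)
        assert aln.mapping["a"] == "x" and aln.mapping["b"] == "y"

    def test_frontier_beats_globally_better_non_neighbor(self):
        # after seeding (a,x), pair (c,z) scores higher than frontier pair
        # (b,y) but c is not a neighbor of an aligned node: frontier wins first
        net1 = nx.Graph([("a", "b")])
        net1.add_node("c")
        net2 = nx.Graph([("x", "y")])
        net2.add_node("z")
        A = sim(
            {("a", "x"): 1.0, ("b", "y"): 0.5, ("c", "z"): 0.8, ("b", "z"): 0.6}
        )
        aln = greedy_align(A, net1, net2)
        assert [(u, v) for u, v, _ in aln.pairs] == [("a", "x"), ("b", "y"), ("c", "z")]

    def test_identity_recovery_on_self_alignment(self, noisy_bundle):
        net = noisy_bundle.net1
        twin = nx.relabel_nodes(net, lambda n: "t" + n)
        entries = {}
        rng = np.random.default_rng(0)
        for u in net.nodes:
            for v in twin.nodes:
                entries[(u, v)] = 1.0 if v == "t" + u else float(rng.uniform(0, 0.9))
        aln = greedy_align(sim(entries), net, twin)
        assert all(v == "t" + u for u, v, _ in aln.pairs)
        assert len(aln) == net.number_of_nodes()

    def test_injective_and_full_size_on_dense_positive_scores(self, noisy_bundle):
        b = noisy_bundle
        entries = {
            (u, v): 0.01 + 0.99 * abs(hash((u, v)) % 997) / 997
            for u in b.net1.nodes
            for v in b.net2.nodes
        }
        aln = greedy_align(sim(entries), b.net1, b.net2)
        aln.validate(b.net1, b.net2)
        assert len(aln) == min(b.net1.number_of_nodes(), b.net2.number_of_nodes())

    def test_auto_swap_puts_smaller_network_first(self):
        small = nx.Graph()
        small.add_node("a")
        large = nx.Graph([("x", "y")])
        A = sim({("a", "x"): 0.9, ("a", "y"): 0.2})
        swapped = SimMatrix("alignment", {(v, u): s for (u, v), s in A.entries.items()}, True)
        aln = greedy_align(swapped, large, small)
        assert aln.mapping == {"a": "x"}

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        net1 = nx.relabel_nodes(nx.gnp_random_graph(11, 0.3, seed=1), lambda i: f"a{i}")
        net2 = nx.relabel_nodes(nx.gnp_random_graph(13, 0.3, seed=2), lambda i: f"x{i}")
        entries = {
            (u, v): float(rng.uniform(0.01, 1.0)) for u in net1.nodes for v in net2.nodes
        }
        aln = greedy_align(sim(entries), net1, net2)
        rel1 = {u: f"R{u}" for u in net1.nodes}
        rel2 = {v: f"S{v}" for v in net2.nodes}
        entries_r = {(rel1[u], rel2[v]): s for (u, v), s in entries.items()}
        aln_r = greedy_align(
            sim(entries_r), nx.relabel_nodes(net1, rel1), nx.relabel_nodes(net2, rel2)
        )
        assert {(rel1[u], rel2[v]) for u, v, _ in aln.pairs} == {
            (u, v) for u, v, _ in aln_r.pairs
        }


class TestMcAlign:
    def make_case(self, seed):
        rng = np.random.default_rng(seed)
        net1 = nx.relabel_nodes(nx.gnp_random_graph(15, 0.25, seed=seed), lambda i: f"a{i:02d}")
        net2 = nx.relabel_nodes(nx.gnp_random_graph(15, 0.25, seed=seed + 100), lambda i: f"x{i:02d}")
        entries = {
            (u, v): float(rng.uniform(0.01, 1.0)) for u in net1.nodes for v in net2.nodes
        }
        return sim(entries), net1, net2

    def test_n_top_one_is_bitwise_greedy(self):
        for seed in range(20):
            A, net1, net2 = self.make_case(seed)
            greedy = greedy_align(A, net1, net2)
            mc = mc_align(A, net1, net2, Params(n_top=1, seed=seed))
            assert mc.pairs == greedy.pairs

    def test_fixed_seed_reproducible(self, noisy_bundle):
        A, net1, net2 = self.make_case(42)
        p = Params(seed=9)
        assert mc_align(A, net1, net2, p).pairs == mc_align(A, net1, net2, p).pairs

    def test_distinct_seeds_explore_alternatives(self):
        A, net1, net2 = self.make_case(7)
        outs = {tuple(mc_align(A, net1, net2, Params(seed=s)).pairs) for s in range(6)}
        assert len(outs) > 1

    def test_first_pick_frequencies_match_boltzmann(self):
        # single source node, three candidates: the first (seed) selection
        # must follow Eq.-style Boltzmann probabilities over normalized scores
        net1 = nx.Graph()
        net1.add_node("u")
        net2 = nx.Graph()
        net2.add_nodes_from(["x", "y", "z"])
        A = sim({("u", "x"): 0.9, ("u", "y"): 0.5, ("u", "z"): 0.1})
        cs = mc_probabilities(
            normalize_topn(topn_candidates(A, "u", {"x", "y", "z"}, 3)), kT=0.1
        )
        expected = dict(zip([v for v, _ in cs.candidates], cs.probabilities))
        n = 10_000
        counts = {"x": 0, "y": 0, "z": 0}
        for s in range(n):
            aln = mc_align(A, net1, net2, Params(n_top=3, seed=s))
            counts[aln.pairs[0][1]] += 1
        for v, p in expected.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[v] / n - p) <= 3 * se
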