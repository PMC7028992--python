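"""Bipartite modularity, the community optimizer and SNP core scores."""

import numpy as np
import pandas as pd
import pytest

from conftest import (
    adjusted_rand,
    biclique_network,
    brute_force_optimal_q,
    modularity_double_loop,
    random_bipartite,
)
from eqtlnet import communities as cm
from eqtlnet.network import BipartiteNetwork
from eqtlnet.simulate import SimulationDesign, simulate_dataset


def assignment_from(network, snp_comm, gene_comm):
    return cm.CommunityAssignment(dict(snp_comm), dict(gene_comm))


class TestModularity:
    def test_single_community_is_zero(self, rng):
        for _ in range(5):
            b = random_bipartite(rng, 5, 5)
            if b is None:
                continue
            a = assignment_from(b, {s: 1 for s in b.snp_nodes}, {g: 1 for g in b.gene_nodes})
            assert cm.modularity(b, a) == pytest.approx(0.0, abs=1e-15)

    def test_two_disjoint_edges_give_half(self):
        b = BipartiteNetwork(["s1", "s2"], ["g1", "g2"], [("s1", "g1"), ("s2", "g2")])
        a = assignment_from(b, {"s1": 1, "s2": 2}, {"g1": 1, "g2": 2})
        assert cm.modularity(b, a) == pytest.approx(0.5)

    def test_two_bicliques_give_half(self):
        b = biclique_network(2)
        a = assignment_from(
            b,
            {s: 1 if s.startswith("s0") else 2 for s in b.snp_nodes},
            {g: 1 if g.startswith("g0") else 2 for g in b.gene_nodes},
        )
        assert cm.modularity(b, a) == pytest.approx(0.5)

    def test_matches_double_loop_oracle_on_random_networks(self, rng):
        """Per-community aggregation equals the explicit double loop over all
        SNP-gene pairs on 100 random graphs."""
        checked = 0
        while checked < 100:
            n_s = int(rng.integers(3, 15))
            n_g = int(rng.integers(3, 15))
            b = random_bipartite(rng, n_s, n_g)
            if b is None:
                continue
            n_comm = int(rng.integers(1, 5))
            sc = {s: int(rng.integers(1, n_comm + 1)) for s in b.snp_nodes}
            gc = {g: int(rng.integers(1, n_comm + 1)) for g in b.gene_nodes}
            a = assignment_from(b, sc, gc)
            assert cm.modularity(b, a) == pytest.approx(
                modularity_double_loop(b, sc, gc), abs=1e-12)
            checked += 1

    def test_invariant_to_relabeling(self, rng):
        b = random_bipartite(rng, 8, 8)
        sc = {s: int(rng.integers(1, 4)) for s in b.snp_nodes}
        gc = {g: int(rng.integers(1, 4)) for g in b.gene_nodes}
        q1 = cm.modularity(b, assignment_from(b, sc, gc))
        relabel = {1: 7, 2: 5, 3: 9}
        q2 = cm.modularity(b, assignment_from(
            b, {s: relabel[c] for s, c in sc.items()}, {g: relabel[c] for g, c in gc.items()}))
        assert q1 == pytest.approx(q2, abs=1e-15)


class TestInitialPartition:
    def test_disconnected_bicliques_split(self):
        b = biclique_network(2)
        a = cm.initial_partition(b)
        gc = a.gene_community
        assert gc["g0_0"] == gc["g0_1"] != gc["g1_0"]

    def test_single_edge_single_community(self):
        b = BipartiteNetwork(["s1"], ["g1"], [("s1", "g1")])
        a = cm.initial_partition(b)
        assert a.snp_community["s1"] == a.gene_community["g1"]

    def test_planted_three_groups_recovered_in_projection(self):
        b = biclique_network(3, n_snps=3, n_genes=3)
        a = cm.initial_partition(b)
        labels = [a.gene_community[g] for g in sorted(b.gene_nodes)]
        truth = [g.split("_")[0] for g in sorted(b.gene_nodes)]
        assert adjusted_rand(labels, truth) == 1.0


class TestDetectCommunities:
    def test_single_edge(self):
        b = BipartiteNetwork(["s1"], ["g1"], [("s1", "g1")])
        a = cm.detect_communities(b)
        assert a.n_communities == 1
        assert a.modularity == pytest.approx(0.0, abs=1e-15)

    def test_planted_bicliques_exactly_recovered(self):
        b = biclique_network(3, n_snps=2, n_genes=2)
        a = cm.detect_communities(b)
        planted = cm.CommunityAssignment(
            {s: int(s[1]) + 1 for s in b.snp_nodes},
            {g: int(g[1]) + 1 for g in b.gene_nodes},
        )
        assert a.n_communities == 3
        assert a.modularity == pytest.approx(cm.modularity(b, planted), abs=1e-12)

    def test_final_q_at_least_initial(self, rng):
        for _ in range(10):
            b = random_bipartite(rng, 10, 10, p_edge=0.25)
            if b is None:
                continue
            q0 = cm.initial_partition(b).modularity
            q1 = cm.detect_communities(b).modularity
            assert q1 >= q0 - 1e-12

    def test_attains_brute_force_optimum_small_graphs(self, rng):
        """On bipartite graphs with <= 12 nodes the optimizer reaches the
        exhaustive-search maximum modularity."""
        checked = 0
        while checked < 20:
            n_s = int(rng.integers(2, 7))
            n_g = int(rng.integers(2, 13 - n_s))
            b = random_bipartite(rng, n_s, n_g, p_edge=0.45)
            if b is None or len(b.snp_nodes) + len(b.gene_nodes) > 12:
                continue
            best = brute_force_optimal_q(b)
            got = cm.detect_communities(b).modularity
            assert got == pytest.approx(best, abs=1e-9)
            checked += 1

    def test_planted_partition_recovery_across_seeds(self):
        """Noisy planted-partition graphs (dense within, sparse between) are
        recovered with ARI >= 0.9 across 20 seeds."""
        n_ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            edges = []
            for c in range(4):
                for i in range(6):
                    for j in range(6):
                        if rng.random() < 0.75:
                            edges.append((f"s{c}_{i}", f"g{c}_{j}"))
            # sparse between-community noise + connectivity bridges
            for c in range(4):
                edges.append((f"s{c}_0", f"g{(c + 1) % 4}_0"))
                for _ in range(4):
                    c2 = int(rng.integers(0, 4))
                    if c2 != c:
                        edges.append((f"s{c}_{rng.integers(0, 6)}", f"g{c2}_{rng.integers(0, 6)}"))
            snps = sorted({e[0] for e in edges})
            genes = sorted({e[1] for e in edges})
            b = BipartiteNetwork(snps, genes, edges)
            a = cm.detect_communities(b)
            nodes = snps + genes
            ari = adjusted_rand([n.split("_")[0][1:] for n in nodes], list(a.labels(nodes)))
            if ari >= 0.9:
                n_ok += 1
        assert n_ok >= 18

    def test_q_invariant_to_node_order(self, rng):
        b = random_bipartite(rng, 9, 9, p_edge=0.3)
        q1 = cm.detect_communities(b).modularity
        perm_edges = list(reversed(b.edges))
        b2 = BipartiteNetwork(list(reversed(b.snp_nodes)), list(reversed(b.gene_nodes)), perm_edges)
        q2 = cm.detect_communities(b2).modularity
        assert q1 == pytest.approx(q2, abs=1e-12)


class TestCoreScores:
    def test_sum_equals_modularity(self, rng):
        for _ in range(10):
            b = random_bipartite(rng, 10, 8, p_edge=0.3)
            if b is None:
                continue
            a = cm.detect_communities(b)
            scores = cm.core_scores(b, a)
            assert scores["core_score"].sum() == pytest.approx(a.modularity, abs=1e-12)

    def test_single_edge_community_score(self):
        b = BipartiteNetwork(["s1", "s2"], ["g1", "g2"], [("s1", "g1"), ("s2", "g2")])
        a = cm.CommunityAssignment({"s1": 1, "s2": 2}, {"g1": 1, "g2": 2})
        scores = cm.core_scores(b, a)
        # one surviving term: (1/m) * (1 - k d / m) with m=2, k=d=1
        assert scores.loc["s1", "core_score"] == pytest.approx(0.25)

    def test_biclique_scores_are_eighth(self):
        b = biclique_network(2)
        a = cm.CommunityAssignment(
            {s: 1 if s.startswith("s0") else 2 for s in b.snp_nodes},
            {g: 1 if g.startswith("g0") else 2 for g in b.gene_nodes},
        )
        scores = cm.core_scores(b, a)
        np.testing.assert_allclose(scores["core_score"], 0.125)


class TestEndToEndRecovery:
    def test_pipeline_recovers_planted_communities(self, small_design, small_dataset):
        """Full eQTL -> network -> communities chain reaches ARI >= 0.9
        against the planted structure on a strong-signal design."""
        from eqtlnet.config import PipelineConfig
        from eqtlnet.eqtl import run_eqtl_scan
        from eqtlnet.network import build_network, giant_component

        g, expr, _, cov, ann, _, _, truth = small_dataset
        table = run_eqtl_scan(g, expr, cov, PipelineConfig(), gene_ann=ann)
        net = giant_component(build_network(table, 0.2))
        a = cm.detect_communities(net)
        truth_map = pd.concat([truth.snp_community, truth.gene_community.dropna()])
        nodes = [n for n in net.snp_nodes + net.gene_nodes if n in truth_map.index]
        ari = adjusted_rand([truth_map[n] for n in nodes], list(a.labels(nodes)))
        assert ari >= 0.9
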