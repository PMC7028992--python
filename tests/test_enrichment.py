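"""Fisher exactness and the four enrichment analyses."""

import numpy as np
import pandas as pd
import pytest

from conftest import fisher_enumeration_p
from eqtlnet import enrichment as enr


class TestFisherTest:
    def test_no_association_table(self):
        res = enr.fisher_test(0, 10, 0, 10)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_separation_one_sided(self):
        res = enr.fisher_test(5, 0, 0, 5, alternative="greater")
        assert res.p_value == pytest.approx(1 / 252)

    def test_matches_enumeration_oracle_all_small_tables(self):
        """Every 2x2 table with total <= 40 agrees with the fixed-margin
        enumeration oracle."""
        total_max = 40
        checked = 0
        for n in range(1, total_max + 1, 3):
            for a in range(0, n + 1, 2):
                for b in range(0, n - a + 1, 3):
                    for c in range(0, n - a - b + 1, 3):
                        d = n - a - b - c
                        res = enr.fisher_test(a, b, c, d, alternative="greater")
                        assert res.p_value == pytest.approx(
                            fisher_enumeration_p(a, b, c, d, "greater"), abs=1e-10), (a, b, c, d)
                        checked += 1
        assert checked > 500

    def test_sample_odds_ratio_with_zero_cell_correction(self):
        assert enr.fisher_test(2, 3, 4, 1).odds_ratio == pytest.approx(2 / 12)
        res = enr.fisher_test(2, 0, 4, 1)
        assert res.odds_ratio == pytest.approx((2.5 * 1.5) / (0.5 * 4.5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            enr.fisher_test(-1, 2, 3, 4)


class TestCommunityRiskEnrichment:
    def make_inputs(self, comm_sizes, risk_per_comm):
        block_comm, block_risk = {}, {}
        i = 0
        for c, (size, n_risk) in enumerate(zip(comm_sizes, risk_per_comm), start=1):
            for j in range(size):
                block_comm[f"B{i}"] = c
                block_risk[f"B{i}"] = j < n_risk
                i += 1
        return pd.Series(block_comm), pd.Series(block_risk)

    def test_min_blocks_threshold_blocks_significance(self):
        """A community with only 3 risk blocks is never flagged even at a
        tiny Fisher p."""
        bc, br = self.make_inputs([3, 40], [3, 0])
        out = enr.community_risk_enrichment(bc, br, min_risk_blocks=4)
        row = out[out["unit_id"] == 1].iloc[0]
        assert row["p_value"] < 0.01 and not row["enriched"]

    def test_proportional_distribution_not_flagged(self):
        bc, br = self.make_inputs([10, 10, 10], [5, 5, 5])
        out = enr.community_risk_enrichment(bc, br)
        assert not out["enriched"].any()
        assert (out["p_value"] > 0.5).all()

    def test_concentrated_risk_flagged_exactly(self):
        bc, br = self.make_inputs([10, 10, 10, 10], [8, 8, 0, 0])
        out = enr.community_risk_enrichment(bc, br)
        assert set(out.loc[out["enriched"], "unit_id"]) == {1, 2}

    def test_counts_partition_background(self):
        bc, br = self.make_inputs([6, 8], [2, 1])
        out = enr.community_risk_enrichment(bc, br)
        assert ((out["a"] + out["b"] + out["c"] + out["d"]) == 14).all()

    def test_invariant_to_community_relabeling(self):
        bc, br = self.make_inputs([8, 9, 10], [5, 1, 0])
        out1 = enr.community_risk_enrichment(bc, br)
        relabel = {1: 30, 2: 10, 3: 20}
        out2 = enr.community_risk_enrichment(bc.map(relabel), br)
        merged = out1.assign(unit_id=out1["unit_id"].map(relabel)).sort_values("unit_id")
        np.testing.assert_allclose(merged["p_value"].values,
                                   out2.sort_values("unit_id")["p_value"].values)

    def test_null_random_labels_flag_rate(self, rng):
        """Risk labels assigned uniformly at random: flagged fraction across
        100 replicates stays near/below the FDR level."""
        flagged = total = 0
        for _ in range(100):
            bc = pd.Series({f"B{i}": i % 6 + 1 for i in range(60)})
            br = pd.Series({f"B{i}": bool(v) for i, v in
                            enumerate(rng.random(60) < 0.25)})
            out = enr.community_risk_enrichment(bc, br)
            flagged += int(out["enriched"].sum())
            total += len(out)
        assert flagged / total <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / total)


class TestGeneSetEnrichment:
    def test_community_equal_to_set_has_minimal_p(self):
        background = [f"g{i}" for i in range(40)]
        sets = {"target": set(background[:8]), "other": set(background[20:28])}
        out = enr.gene_set_enrichment(background[:8], sets, background)
        p_target = out.set_index("unit_id").loc["target", "p_value"]
        from scipy.stats import hypergeom
        assert p_target == pytest.approx(hypergeom.sf(7, 40, 8, 8))
        assert p_target == out["p_value"].min()

    def test_matches_hypergeometric_oracle_on_toy(self):
        background = [f"g{i}" for i in range(20)]
        community = background[:6]
        sets = {"s": set(background[3:10])}
        out = enr.gene_set_enrichment(community, sets, background)
        # overlap k=3, N=20, K=7, n=6
        assert out["p_value"].iloc[0] == pytest.approx(
            fisher_enumeration_p(3, 4, 3, 10, "greater"), abs=1e-12)

    def test_uniform_sampling_null_rate(self, rng):
        """Communities drawn uniformly from the background trigger ~5% of
        sets at p < 0.05 before FDR."""
        background = [f"g{i}" for i in range(200)]
        sets = {f"set{j}": set(rng.choice(background, 20, replace=False)) for j in range(20)}
        n_sig = n_tot = 0
        for _ in range(50):
            comm = rng.choice(background, 30, replace=False)
            out = enr.gene_set_enrichment(comm, sets, background)
            n_sig += int((out["p_value"] < 0.05).sum())
            n_tot += len(out)
        assert n_sig / n_tot == pytest.approx(0.05, abs=0.04)

    def test_empty_overlap_skipped(self):
        out = enr.gene_set_enrichment(["g1"], {"alien": {"x1", "x2"}}, ["g1", "g2"])
        assert out.empty


class TestPromoterEnrichment:
    def test_strand_aware_boundaries(self):
        ann = pd.DataFrame({"chrom": ["chr1", "chr1"], "tss": [10_000, 50_000],
                            "strand": ["+", "-"]}, index=["gp", "gm"])
        proms = enr.promoter_intervals(ann)
        # + strand: [tss-750, tss+250]
        assert proms.loc["gp", "start"] == 9_250 and proms.loc["gp", "end"] == 10_250
        # - strand: upstream is to the right
        assert proms.loc["gm", "start"] == 49_750 and proms.loc["gm", "end"] == 50_750
        snps = pd.DataFrame({"chrom": ["chr1"] * 4, "pos": [9_250, 10_251, 50_750, 50_751]},
                            index=["at_edge", "past", "m_edge", "m_past"])
        hits = enr.snps_in_promoters(snps, proms)
        assert hits["at_edge"] and not hits["past"]
        assert hits["m_edge"] and not hits["m_past"]

    def test_planted_contrast_cancer_vs_all(self, small_dataset, small_design):
        """Risk blocks planted into cancer-gene promoters: enriched against
        cancer-gene promoters, not against all-gene promoters."""
        g, ann, truth = small_dataset[0], small_dataset[4], small_dataset[-1]
        snp_risk = truth.blocks.isin(truth.risk_blocks)
        out = enr.promoter_enrichment(g.snps, ann, truth.cancer_genes, truth.blocks,
                                      snp_risk)
        res = out.set_index("unit_id")
        assert res.loc["cancer_gene_promoters", "odds_ratio"] > 1
        assert res.loc["cancer_gene_promoters", "p_value"] < 0.05
        assert res.loc["all_gene_promoters", "p_value"] > 0.2


class TestRiskCisTrans:
    def make_edges(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "gene_id", "cis_flag"])

    def test_equal_trans_fractions_or_one(self):
        rows = ([("r1", f"g{i}", i % 2 == 0) for i in range(6)]
                + [("n1", f"g{i}", i % 2 == 0) for i in range(6)])
        out = enr.risk_cis_trans_enrichment(self.make_edges(rows),
                                            pd.Series({"r1": True, "n1": False}))
        assert out["odds_ratio"].iloc[0] == pytest.approx(1.0)

    def test_hand_counted_toy(self):
        rows = [("r1", "g1", False), ("r1", "g2", False), ("r1", "g3", True),
                ("n1", "g1", True), ("n1", "g2", True), ("n1", "g3", False),
                ("n2", "g4", True), ("n2", "g5", True), ("n2", "g6", False),
                ("r2", "g4", False), ("r2", "g5", True), ("r2", "g6", False)]
        out = enr.risk_cis_trans_enrichment(self.make_edges(rows),
                                            pd.Series({"r1": True, "r2": True,
                                                       "n1": False, "n2": False}))
        row = out.iloc[0]
        assert (row["a"], row["b"], row["c"], row["d"]) == (4, 2, 2, 4)
        assert row["odds_ratio"] == pytest.approx(4.0)

    def test_planted_excess_trans_detected(self, small_dataset):
        truth = small_dataset[-1]
        edges = truth.true_pairs.rename(columns={"beta": "w"})
        snp_risk = truth.blocks.isin(truth.risk_blocks)
        out = enr.risk_cis_trans_enrichment(edges, snp_risk)
        assert out["odds_ratio"].iloc[0] > 1
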