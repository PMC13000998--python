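"""Internode tip-to-root rate estimation: pruning, monophyly filtering,
normalization identities and recovery of a planted rate contrast."""

import math

import numpy as np
import pytest

from morffokit.io_formats import PhyloTree
from morffokit.rates import (
    enumerate_internodes,
    gene_rates,
    monophyly_consistent,
    prune_taxa,
    summarize_rates,
    tip_to_root_sum,
)
from morffokit.seqsim import SimConfig, simulate_gene_set


class TestPrune:
    def test_empty_drop_is_identity(self, balanced_tree):
        out = prune_taxa(balanced_tree, set())
        assert sorted(out.leaf_labels()) == ["A", "B", "C", "D"]

    def test_metric_preserved_among_survivors(self, caterpillar_tree):
        before = caterpillar_tree.path_length_matrix()
        out = prune_taxa(caterpillar_tree, {"C"})
        after = out.path_length_matrix()
        keep = ["A", "B", "D"]
        assert np.allclose(before.loc[keep, keep].to_numpy(), after.loc[keep, keep].to_numpy())

    def test_too_few_survivors_rejected(self, balanced_tree):
        with pytest.raises(ValueError):
            prune_taxa(balanced_tree, {"A", "B", "C"})

    def test_unknown_taxon_rejected(self, balanced_tree):
        with pytest.raises(ValueError, match="Z"):
            prune_taxa(balanced_tree, {"Z"})


class TestInternodes:
    def test_balanced_enumeration(self, balanced_tree):
        sets = {frozenset(ls) for _, ls in enumerate_internodes(balanced_tree)}
        assert sets == {frozenset("AB"), frozenset("CD"), frozenset("ABCD")}

    def test_caterpillar_enumeration(self, caterpillar_tree):
        sets = {frozenset(ls) for _, ls in enumerate_internodes(caterpillar_tree)}
        assert sets == {frozenset("AB"), frozenset("ABC"), frozenset("ABCD")}

    def test_two_taxon_tree_has_root_only(self):
        t = PhyloTree.from_newick("(A:1,B:2);")
        assert [sorted(ls) for _, ls in enumerate_internodes(t)] == [["A", "B"]]


class TestTipToRootSum:
    def test_cherry(self, balanced_tree):
        assert tip_to_root_sum(balanced_tree, {"A", "B"}) == pytest.approx(2.0)

    def test_root_internode_excludes_stem(self, balanced_tree):
        # 4 leaves, each 2 from the root
        assert tip_to_root_sum(balanced_tree, {"A", "B", "C", "D"}) == pytest.approx(8.0)

    def test_ultrametric_identity(self):
        t = PhyloTree.from_newick("((A:5,B:5):10,(C:15,D:15):0);")
        # clade of n tips at age 15 from the root: sum = n * 15
        assert tip_to_root_sum(t, {"A", "B", "C", "D"}) == pytest.approx(4 * 15)

    def test_non_clade_rejected(self, balanced_tree):
        with pytest.raises(ValueError, match="not a clade"):
            tip_to_root_sum(balanced_tree, {"A", "C"})


class TestMonophyly:
    def test_clade_true(self, balanced_tree):
        assert monophyly_consistent({"A", "B"}, balanced_tree)

    def test_non_clade_false(self, balanced_tree):
        assert not monophyly_consistent({"A", "C"}, balanced_tree)

    def test_full_leaf_set_true(self, balanced_tree):
        assert monophyly_consistent({"A", "B", "C", "D"}, balanced_tree)

    def test_foreign_taxon_rejected(self, balanced_tree):
        with pytest.raises(ValueError):
            monophyly_consistent({"A", "Z"}, balanced_tree)


class TestGeneRates:
    def _chrono(self):
        return PhyloTree.from_newick("((A:10,B:10):5,(C:12,D:12):3);")

    def _phylo(self):
        return PhyloTree.from_newick("((A:0.1,B:0.1):0.05,(C:0.12,D:0.12):0.03);")

    def test_self_normalization(self):
        phylo = self._phylo()
        for est in gene_rates(phylo, phylo, self._chrono()):
            assert est.included and est.rel_rate == pytest.approx(1.0)

    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_scaling_equivariance(self, c):
        phylo, chrono = self._phylo(), self._chrono()
        base = {e.internode_id: e for e in gene_rates(phylo, phylo, chrono)}
        for est in gene_rates(phylo.scale(c), phylo, chrono):
            ref = base[est.internode_id]
            assert est.rel_rate == pytest.approx(c * ref.rel_rate)
            assert est.abs_rate == pytest.approx(c * ref.abs_rate)

    def test_absolute_rate_hand_example(self):
        # gene tree: 4 tips, root tip-to-root sum 0.6 subs/site;
        # chronogram balanced, each tip 15 Myr from root (sum 60)
        gene = PhyloTree.from_newick("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")
        chrono = PhyloTree.from_newick("((A:5,B:5):10,(C:15,D:15):0);")
        phylo = chrono.scale(0.001)
        [root_est] = [e for e in gene_rates(gene, phylo, chrono) if e.n_tips == 4]
        assert root_est.abs_rate == pytest.approx(0.6 / 60.0)

    def test_monophyly_filter_excludes_discordant_internode(self):
        # gene tree groups A+C, which is not a clade of the references
        gene = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        ests = {e.internode_id: e for e in gene_rates(gene, self._phylo(), self._chrono())}
        assert not ests["A|C"].included
        assert ests["A|C"].reason == "not_monophyletic_in_reference"
        assert math.isnan(ests["A|C"].rel_rate)
        assert ests["A|B|C|D"].included

    def test_pseudogene_tips_dropped(self):
        phylo, chrono = self._phylo(), self._chrono()
        flags = {"A": 2, "B": 0}
        ests = gene_rates(phylo, phylo, chrono, flags=flags, exclude_pseudogenes=True)
        leafsets = {e.internode_id for e in ests}
        assert all("A" not in key.split("|") for key in leafsets)
        # without the exclusion flag the tip stays
        ests2 = gene_rates(phylo, phylo, chrono, flags=flags, exclude_pseudogenes=False)
        assert any("A" in e.internode_id.split("|") for e in ests2)

    def test_pruning_consistency(self):
        # dropping a taxon outside an internode leaves that internode's rates unchanged
        phylo, chrono = self._phylo(), self._chrono()
        gene = phylo.scale(2.0)
        full = {e.internode_id: e for e in gene_rates(gene, phylo, chrono)}
        dropped = {e.internode_id: e for e in gene_rates(gene, phylo, chrono, drop={"D"})}
        assert dropped["A|B"].rel_rate == pytest.approx(full["A|B"].rel_rate)

    def test_label_harmonization(self):
        gene = PhyloTree.from_newick("(('A x':0.1,B:0.1):0.05,(C:0.12,D:0.12):0.03);")
        phylo = PhyloTree.from_newick("((A_x:0.1,B:0.1):0.05,(C:0.12,D:0.12):0.03);")
        chrono = PhyloTree.from_newick("((A_x:10,B:10):5,(C:12,D:12):3);")
        ests = gene_rates(gene, phylo, chrono)
        assert all(e.included for e in ests)

    def test_unmatched_label_is_hard_error(self):
        gene = PhyloTree.from_newick("((Q:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError, match="Q"):
            gene_rates(gene, self._phylo(), self._chrono())


class TestSummaries:
    def _est(self, gene, value):
        from morffokit.rates import RateEstimate

        return RateEstimate(gene, "x", 2, value, value, True)

    def test_single_estimate(self):
        df = summarize_rates([self._est("g", 5.0)])
        row = df.iloc[0]
        assert row["median"] == 5.0 and row["q1"] == row["q3"] == 5.0

    def test_outlier_detection_hand_example(self):
        df = summarize_rates([self._est("g", v) for v in [1, 2, 3, 4, 100]])
        row = df.iloc[0]
        assert row["median"] == 3 and row["q1"] == 2 and row["q3"] == 4
        assert row["outliers"] == "100"
        assert row["whisker_high"] == 4

    def test_all_equal_no_outliers(self):
        df = summarize_rates([self._est("g", 2.0)] * 5)
        assert df.iloc[0]["outliers"] == ""

    def test_excluded_estimates_never_contribute(self):
        from morffokit.rates import RateEstimate

        ests = [self._est("g", 1.0), RateEstimate("g", "y", 2, 99.0, 99.0, False, "not_monophyletic_in_reference")]
        df = summarize_rates(ests)
        assert df.iloc[0]["n"] == 1 and df.iloc[0]["median"] == 1.0

    def test_empty_gene_flagged(self):
        from morffokit.rates import RateEstimate

        df = summarize_rates([RateEstimate("g", "y", 2, math.nan, math.nan, False, "zero_reference_sum")])
        assert df.iloc[0]["flag"] == "empty"


class TestRecovery:
    def test_mobile_class_rate_multiplier_recovered(self):
        """Planted 12.5x contrast between mobile and canonical gene classes."""
        cfg = SimConfig(seed=42)
        _, gene_trees, truth = simulate_gene_set(cfg, with_alignments=False)
        per_class: dict[str, list[float]] = {"canonical": [], "mobile": []}
        for gene_id, tree in gene_trees.items():
            for est in gene_rates(tree, truth.phylogram, truth.chronogram, gene_id=gene_id):
                if est.included:
                    per_class[truth.gene_class[gene_id]].append(est.rel_rate)
        ratio = np.median(per_class["mobile"]) / np.median(per_class["canonical"])
        assert abs(ratio - 12.5) / 12.5 < 0.2
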