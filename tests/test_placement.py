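"""Constrained placement: grafting, per-edge optimization, bootstrap
tallies, and the rogue-aware support summaries."""

import json

import numpy as np
import pytest

from phylotier.likelihood import TreeLikelihood
from phylotier.placement import (
    PlacementError,
    PlacementModel,
    PlacementTally,
    ReplicateRecord,
    bootstrap_placements,
    effective_support,
    graft,
    place_multiple,
    place_query,
    prune_taxa,
    region_support,
    select_subset,
    write_jplace,
)
from phylotier.seqdata import PartitionedAlignment
from phylotier.substmodels import SubstitutionModel
from phylotier.synthetic import (
    default_study_config,
    make_placement_study,
    random_tree,
    simulate_alignment,
)
from phylotier.trees import Tree
from tests.conftest import random_trees


def study_models(cfg):
    from dataclasses import replace

    return {s.name: replace(s.model, rate_scale=s.rate_multiplier)
            for s in cfg.partitions}


def split_key(sides):
    return set(map(frozenset, sides))


class TestGraft:
    def test_graft_then_prune_restores_tree(self):
        t = Tree.from_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.07);")
        g = graft(t, frozenset({"C", "D"}), "Q", 0.4, 0.2)
        assert "Q" in g.leaves
        back = prune_taxa(g, ["Q"])
        assert back.splits() == t.splits()
        assert back.total_length() == pytest.approx(t.total_length())

    def test_graft_adds_exactly_one_nontrivial_split(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        g = graft(t, frozenset({"C", "D"}), "Q")
        new = g.splits() - {
            s | ({"Q"} if any(x in s for x in ("C", "D")) else set())
            for s in t.splits()
        }
        assert g.is_clade({"C", "D", "Q"})

    def test_split_count_on_random_trees(self):
        for t in random_trees(20, 7, seed=3):
            edge = sorted(t.splits(), key=lambda s: tuple(sorted(s)))[0]
            g = graft(t, edge, "Q")
            # grafting onto an internal edge adds exactly one internal split
            assert len(g.splits()) == len(t.splits()) + 1

    def test_duplicate_query_rejected(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(PlacementError, match="already"):
            graft(t, frozenset({"C", "D"}), "A")

    def test_bad_fraction_rejected(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(PlacementError):
            graft(t, frozenset({"C", "D"}), "Q", attach_fraction=1.5)


class TestPlaceQuery:
    def test_two_leaf_backbone_forced_placement(self, jc):
        backbone = Tree.from_newick("(A:0.1,B:0.1);")
        aln = PartitionedAlignment(["A", "B", "Q"], ["ACGTAC", "ACGTGG", "ACGTAC"])
        res = place_query(backbone, aln, jc, "Q")
        assert len(res.edges) >= 1
        assert res.best.loglik == max(e.loglik for e in res.edges)

    def test_engine_agrees_with_direct_grafted_tree_likelihood(self, jc):
        rng = np.random.default_rng(17)
        backbone = random_tree(6, rng, (0.05, 0.2))
        full = graft(backbone, sorted(backbone.splits(), key=lambda s: tuple(sorted(s)))[0], "Q", 0.5, 0.08)
        aln = simulate_alignment(full, jc, 400, 18)
        res = place_query(backbone, aln, jc, "Q")
        for e in res.edges[:3]:
            direct_tree = graft(backbone, e.split, "Q", 0.5, e.pendant)
            for leaf in direct_tree.dendropy_tree.leaf_node_iter():
                if leaf.taxon.label == "Q":
                    w = leaf.parent_node
                    w.edge.length = e.t_parent
                    for c in w.child_nodes():
                        if c is not leaf:
                            c.edge.length = e.t_child
            direct = TreeLikelihood(direct_tree, aln, jc).total_loglik()
            assert direct == pytest.approx(e.loglik, abs=1e-6)

    def test_three_leaf_backbone_matches_quartet_oracle(self):
        """Best placement edge equals the ML quartet found by exhaustively
        optimizing all three quartet topologies."""
        from phylotier.likelihood import optimize_branch_lengths

        model = SubstitutionModel.jc(gamma_shape=1.0)
        rng = np.random.default_rng(23)
        for rep in range(3):
            backbone = random_tree(3, rng, (0.08, 0.25))
            leaves = backbone.leaves
            edge = frozenset({leaves[rep % 3]})
            full = graft(backbone, edge, "Q", 0.5, 0.15)
            aln = simulate_alignment(full, model, 800, 100 + rep)
            res = place_query(backbone, aln, model, "Q")
            best_leaf = next(iter(min(res.best.split, key=len)))
            # oracle: optimize each quartet ((X,Q),(Y,Z)) from scratch
            scores = {}
            for x in leaves:
                y, z = [l for l in leaves if l != x]
                qt = Tree.from_newick(
                    f"(({x}:0.1,Q:0.1):0.05,({y}:0.1,{z}:0.1):0.05);"
                )
                _, ll = optimize_branch_lengths(qt, aln, model)
                scores[x] = ll
            oracle_leaf = max(scores, key=scores.get)
            assert best_leaf == oracle_leaf

    def test_strong_signal_recovers_planted_edge_with_margin(self):
        cfg = default_study_config(31)
        backbone, aln, truth = make_placement_study(cfg)
        res = place_query(backbone, aln, study_models(cfg), "query", xatol=1e-4)
        assert split_key(res.best.split) == split_key(truth.true_edge)
        assert res.margin > 10.0

    def test_all_missing_query_rejected(self, jc):
        backbone = Tree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        aln = PartitionedAlignment(
            ["A", "B", "C", "D", "Q"],
            ["ACGTA", "ACGTC", "AGGTA", "AGGTC", "?????"],
        )
        with pytest.raises(PlacementError, match="determinate"):
            place_query(backbone, aln, jc, "Q")


class TestPlaceMultiple:
    def test_single_query_matches_place_query(self, jc):
        rng = np.random.default_rng(41)
        backbone = random_tree(5, rng, (0.05, 0.2))
        full = graft(backbone, sorted(backbone.splits(), key=lambda s: tuple(sorted(s)))[0], "Q", 0.5, 0.1)
        aln = simulate_alignment(full, jc, 500, 42)
        single = place_query(backbone, aln, jc, "Q", xatol=1e-5)
        multi = place_multiple(backbone, aln, jc, ["Q"])
        assert split_key(multi["Q"].best.split) == split_key(single.best.split)

    def test_two_distant_queries_recovered(self, jc):
        rng = np.random.default_rng(43)
        backbone = random_tree(8, rng, (0.05, 0.15))
        splits = sorted(backbone.splits(), key=lambda s: tuple(sorted(s)))
        e1, e2 = splits[0], splits[-1]
        full = graft(graft(backbone, e1, "Q1", 0.5, 0.08), e2, "Q2", 0.5, 0.08)
        aln = simulate_alignment(full, jc, 2000, 44)
        res = place_multiple(backbone, aln, jc, ["Q1", "Q2"])
        s1 = min(res["Q1"].best.split, key=len)
        s2 = min(res["Q2"].best.split, key=len)
        assert (s1 - {"Q2"}) in (e1, frozenset(backbone.leaves) - e1)
        assert (s2 - {"Q1"}) in (e2, frozenset(backbone.leaves) - e2)


class TestBootstrap:
    def test_counts_sum_to_B_and_seed_determinism(self, jc):
        rng = np.random.default_rng(51)
        backbone = random_tree(5, rng, (0.05, 0.2))
        full = graft(backbone, sorted(backbone.splits(), key=lambda s: tuple(sorted(s)))[0], "Q", 0.5, 0.1)
        aln = simulate_alignment(full, jc, 300, 52)
        t1 = bootstrap_placements(backbone, aln, jc, "Q", B=12, seed=7)
        t2 = bootstrap_placements(backbone, aln, jc, "Q", B=12, seed=7)
        t3 = bootstrap_placements(backbone, aln, jc, "Q", B=12, seed=8)
        assert sum(t1.edge_counts().values()) == 12
        assert t1.edge_counts() == t2.edge_counts()
        assert sum(t3.edge_counts().values()) == 12  # may or may not differ

    def test_rogue_bootstrap_records_rogue_positions(self):
        cfg = default_study_config(53)
        backbone, aln, truth = make_placement_study(cfg)
        rogue = sorted(min(truth.true_edge, key=len))[0]
        tally = bootstrap_placements(
            backbone, aln, study_models(cfg), "query", B=3, seed=9, rogues=[rogue]
        )
        assert tally.B == 3
        for rec in tally.records:
            assert rogue in rec.rogue_sides
            assert rec.newick is not None


class TestSupportArithmetic:
    @staticmethod
    def constructed_tally():
        """59 replicates sister to the full clade, 6 sister to the clade
        minus the rogue (rogue elsewhere), 35 elsewhere."""
        clade = frozenset({"a1", "a2", "a3", "rogue1"})
        others = frozenset({f"o{i}" for i in range(1, 8)})
        leaves = clade | others
        records = []
        for _ in range(59):
            records.append(
                ReplicateRecord((clade, others),
                                {"rogue1": (frozenset({"a1", "a2", "a3"}),
                                             others)})
            )
        for _ in range(6):
            records.append(
                ReplicateRecord(
                    (clade - {"rogue1"}, others | {"rogue1"}),
                    {"rogue1": (others - {"o1"}, frozenset())},
                )
            )
        for _ in range(35):
            records.append(
                ReplicateRecord((frozenset({"o1"}), leaves - {"o1"}),
                                {"rogue1": (clade - {"rogue1"}, others)})
            )
        return PlacementTally("q", leaves, records, rogues=("rogue1",)), clade

    def test_plain_59_effective_65(self):
        tally, clade = self.constructed_tally()
        assert effective_support(tally, clade) == pytest.approx(59.0)
        assert effective_support(tally, clade, rogues=["rogue1"]) == pytest.approx(65.0)

    def test_all_replicates_in_clade_no_rogues(self):
        clade = frozenset({"a", "b"})
        leaves = clade | {"c", "d", "e"}
        recs = [ReplicateRecord((clade, leaves - clade)) for _ in range(10)]
        tally = PlacementTally("q", leaves, recs)
        assert effective_support(tally, clade) == 100.0

    def test_effective_support_monotone_in_rogues(self):
        tally, clade = self.constructed_tally()
        plain = effective_support(tally, clade)
        with_rogue = effective_support(tally, clade, rogues=["rogue1"])
        assert with_rogue >= plain

    def test_unknown_focal_taxon_errors(self):
        tally, _clade = self.constructed_tally()
        with pytest.raises(PlacementError, match="not in backbone"):
            effective_support(tally, {"nosuch"})

    def test_region_support_full_region_is_100(self):
        tally, _clade = self.constructed_tally()
        assert region_support(tally, tally.backbone_leaves) == 100.0

    def test_region_support_constructed_99(self):
        leaves = frozenset(f"t{i}" for i in range(8))
        region = frozenset({"t0", "t1", "t2"})
        inside = ReplicateRecord((frozenset({"t0"}), leaves - {"t0"}))
        outside = ReplicateRecord((frozenset({"t6"}), leaves - {"t6"}))
        recs = [inside] * 99 + [outside]
        assert region_support(PlacementTally("q", leaves, recs), region) == 99.0

    def test_empty_region_errors(self):
        tally, _clade = self.constructed_tally()
        with pytest.raises(PlacementError, match="empty"):
            region_support(tally, [])


class TestSelectSubset:
    def test_concentrated_tally_selects_clade_plus_outgroups(self, jc):
        backbone = Tree.from_newick(
            "(((a1:1,a2:1):1,(b1:1,b2:1):1):1,((c1:1,c2:1):1,(d1:1,d2:1):1):1);"
        )
        leaves = frozenset(backbone.leaves)
        clade = frozenset({"a1", "a2"})
        recs = [ReplicateRecord((clade, leaves - clade))] * 20
        tally = PlacementTally("q", leaves, recs)
        aln = PartitionedAlignment(
            sorted(leaves), ["ACGTAC"] * len(leaves)
        )
        subset = select_subset(
            backbone, tally, aln, region_threshold=95.0,
            outgroup_clades={"cs": ["c1", "c2"], "ds": ["d1", "d2"]}, k=1,
        )
        assert set(subset) >= clade
        assert len(set(subset) & {"c1", "c2"}) == 1
        assert len(set(subset) & {"d1", "d2"}) == 1

    def test_outgroup_representatives_minimise_missing_data(self):
        backbone = Tree.from_newick("((a:1,b:1):1,(c:1,(d:1,e:1):1):1);")
        leaves = frozenset(backbone.leaves)
        recs = [ReplicateRecord((frozenset({"a"}), leaves - {"a"}))] * 10
        tally = PlacementTally("q", leaves, recs)
        aln = PartitionedAlignment(
            ["a", "b", "c", "d", "e"],
            ["ACGTACGTAC", "ACGTACGTAC", "AC??????AC", "ACGTA?????", "ACGTACGTA?"],
        )
        # candidates c, d, e have missing fractions 0.6, 0.5, 0.1
        subset = select_subset(
            backbone, tally, aln, region_threshold=95.0,
            outgroup_clades={"og": ["c", "d", "e"]}, k=2,
        )
        assert {"e", "d"} <= set(subset) and "c" not in subset

    def test_unattainable_threshold_reports_maximum(self):
        backbone = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        leaves = frozenset(backbone.leaves)
        recs = [ReplicateRecord((frozenset({"a"}), leaves - {"a"}))] * 10
        tally = PlacementTally("q", frozenset({"a", "b", "c", "d", "x"}), recs)
        aln = PartitionedAlignment(sorted(leaves), ["ACGT"] * 4)
        with pytest.raises(PlacementError):
            select_subset(backbone, tally, aln, region_threshold=200.0)


class TestJplace:
    def test_jplace_structure(self, jc):
        backbone = Tree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        aln = PartitionedAlignment(
            ["A", "B", "C", "D", "Q"],
            ["ACGTAC", "ACGTAA", "AGGTAC", "AGGTTT", "ACGTAC"],
        )
        res = place_query(backbone, aln, jc, "Q")
        doc = json.loads(write_jplace(res))
        assert doc["version"] == 3
        assert doc["fields"][0] == "edge_num"
        assert "{" in doc["tree"] and doc["tree"].endswith(";")
        rows = doc["placements"][0]["p"]
        assert doc["placements"][0]["n"] == ["Q"]
        edge_nums = [r[0] for r in rows]
        assert len(edge_nums) == len(set(edge_nums))
        lwr = [r[2] for r in rows]
        assert sum(lwr) == pytest.approx(1.0, abs=1e-3)


class TestPlacementModelResults:
    def test_summary_and_placements_frame(self):
        cfg = default_study_config(61)
        backbone, aln, truth = make_placement_study(cfg)
        res = PlacementModel(aln, backbone, study_models(cfg), "query").fit(
            bootstrap=5, seed=3, xatol=1e-4
        )
        df = res.placements()
        assert df["lwr"].sum() == pytest.approx(1.0, abs=1e-6)
        assert (df["loglik"].values == sorted(df["loglik"].values)[::-1]).all()
        text = res.summary()
        assert "best edge" in text and "bootstrap" in text
        assert res.tally.B == 5
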