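"""Substitution models, pairwise distances, and pruning likelihoods.

The pruning implementation is checked against an independent brute-force
oracle that sums over all internal-node state assignments, and against the
two-sequence closed forms of the JC family.
"""

import itertools

import numpy as np
import pytest

from phylotier.likelihood import (
    PhyloArrays,
    TreeLikelihood,
    optimize_branch_lengths,
    site_loglik,
)
from phylotier.seqdata import Partition, PartitionedAlignment
from phylotier.substmodels import (
    ModelError,
    SubstitutionModel,
    empirical_frequencies,
    fit_model,
    ml_pairwise_distance,
    p_distance,
)
from phylotier.synthetic import random_tree, simulate_alignment
from phylotier.trees import Tree

JC_T = 0.30409883108112323  # -(3/4) ln(1 - 4*0.25/3)
JCG_T = 0.46875  # (3/4)*0.5*((1 - 4*0.25/3)^(-2) - 1)


def brute_force_site_loglik(tree, pattern, model):
    """Independent oracle: likelihood by explicit summation over every
    internal-node state assignment, averaged over Gamma categories."""
    arr = PhyloArrays(tree)
    internal = [v for v in arr.postorder if arr.children[v]]
    rates = model.category_rates()
    pi = np.asarray(model.freqs)
    total = 0.0
    for r in rates:
        P = {
            v: _pmat(model, arr.blen[v] * r)
            for v in range(arr.n_nodes)
            if v != arr.root
        }
        lik = 0.0
        for assign in itertools.product(range(4), repeat=len(internal)):
            states = dict(zip(internal, assign))
            for label, v in arr.leaf_nodes.items():
                states[v] = pattern[label]
            term = pi[states[arr.root]]
            for v in range(arr.n_nodes):
                if v == arr.root:
                    continue
                term *= P[v][states[arr.parent[v]], states[v]]
            lik += term
        total += lik / rates.size
    return np.log(total)


def _pmat(model, t):
    w, left, right = model._eigensystem()
    return np.clip(left @ np.diag(np.exp(w * t)) @ right, 0.0, None)


class TestModel:
    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ModelError):
            SubstitutionModel(freqs=(0.5, 0.5, 0.5, 0.5))

    def test_rate_matrix_scaled_to_unit_mean_rate(self):
        m = SubstitutionModel.hky(4.0, (0.3, 0.2, 0.2, 0.3))
        Q = m._q_matrix()
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert -(np.asarray(m.freqs) * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_transition_matrices_are_stochastic(self):
        m = SubstitutionModel.hky(3.0, (0.4, 0.1, 0.2, 0.3), gamma_shape=0.7)
        P = m.transition_matrices(0.42)
        assert P.shape == (4, 4, 4)
        assert np.allclose(P.sum(axis=2), 1.0, atol=1e-10)
        assert (P >= 0).all()

    def test_single_category_equals_no_heterogeneity(self):
        with_g = SubstitutionModel.jc(gamma_shape=0.5, n_categories=1)
        without = SubstitutionModel.jc()
        assert np.allclose(
            with_g.transition_matrices(0.3), without.transition_matrices(0.3)
        )

    def test_category_rates_mean_one(self):
        m = SubstitutionModel.jc(gamma_shape=0.3, n_categories=8)
        assert m.category_rates().mean() == pytest.approx(1.0)
        assert (np.diff(m.category_rates()) > 0).all()


class TestPairwiseDistances:
    def test_p_distance_examples(self):
        assert p_distance("ACGT", "ACGA") == 0.25
        assert p_distance("ACGT", "ACGT") == 0.0
        assert p_distance("AC?T", "ACGA") == pytest.approx(1 / 3)

    def test_p_distance_no_comparable_sites(self):
        assert p_distance("??", "AC") is None

    def test_p_distance_length_mismatch(self):
        with pytest.raises(ModelError):
            p_distance("AC", "ACG")

    def test_identical_sequences_distance_zero(self, jc):
        assert ml_pairwise_distance("ACGTACGT", "ACGTACGT", jc) == 0.0

    def test_jc_closed_form(self, jc):
        assert ml_pairwise_distance("ACGT", "ACGA", jc) == pytest.approx(
            JC_T, abs=1e-6
        )

    def test_jc_gamma_closed_form(self):
        jcg = SubstitutionModel.jc(gamma_shape=0.5)
        assert ml_pairwise_distance("ACGT", "ACGA", jcg) == pytest.approx(
            JCG_T, abs=1e-6
        )

    def test_monotone_in_p(self, jc):
        # sequences realising p = 1/8, 2/8, 3/8 exactly
        base = "ACGTACGT"
        seqs = ["ACGTACGA", "ACGTACAA", "ACGTAAAA"]
        dists = [ml_pairwise_distance(base, s, jc) for s in seqs]
        assert dists == sorted(dists) and dists[0] < dists[-1]


class TestPruning:
    def test_identical_site_zero_distance(self, jc):
        tree = Tree.from_newick("(A:0.00000001,B:0.00000001);")
        aln = PartitionedAlignment(["A", "B"], ["A", "A"])
        assert TreeLikelihood(tree, aln, jc).total_loglik() == pytest.approx(
            np.log(0.25), abs=1e-6
        )

    def test_two_taxa_differing_site_closed_form(self, jc):
        t = 0.37
        tree = Tree.from_newick(f"(A:{t / 2},B:{t / 2});")
        aln = PartitionedAlignment(["A", "B"], ["A", "C"])
        expect = np.log(0.25 * (0.25 - 0.25 * np.exp(-4 * t / 3)))
        assert TreeLikelihood(tree, aln, jc).total_loglik() == pytest.approx(expect)

    @pytest.mark.parametrize("n_leaves", [3, 4, 5])
    def test_pruning_matches_exhaustive_state_sum(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        tree = random_tree(n_leaves, rng, (0.05, 0.4))
        model = SubstitutionModel.hky(3.0, (0.35, 0.15, 0.2, 0.3), gamma_shape=0.6)
        aln = simulate_alignment(tree, model, 6, rng)
        lk = TreeLikelihood(tree, aln, model)
        vals, sites, _ = lk.site_logliks()
        for j, site in enumerate(sites):
            pattern = {
                t: "ACGT".index(aln.matrix[aln.taxa.index(t), site])
                for t in tree.leaves
            }
            oracle = brute_force_site_loglik(tree, pattern, model)
            assert vals[j] == pytest.approx(oracle, abs=1e-8)

    @pytest.mark.parametrize("n_leaves", [3, 4])
    def test_pattern_likelihoods_sum_to_one(self, n_leaves):
        rng = np.random.default_rng(10 + n_leaves)
        tree = random_tree(n_leaves, rng, (0.05, 0.5))
        model = SubstitutionModel.hky(2.0, (0.3, 0.2, 0.25, 0.25), gamma_shape=0.9)
        taxa = sorted(tree.leaves)
        patterns = list(itertools.product("ACGT", repeat=n_leaves))
        rows = ["".join(p[i] for p in patterns) for i in range(n_leaves)]
        aln = PartitionedAlignment(taxa, rows)
        lk = TreeLikelihood(tree, aln, model)
        vals, _, _ = lk.site_logliks()
        assert np.exp(vals).sum() == pytest.approx(1.0, abs=1e-10)

    def test_missing_data_contributes_one(self, jc):
        tree = Tree.from_newick("(A:0.1,(B:0.1,C:0.1):0.1);")
        full = PartitionedAlignment(["A", "B", "C"], ["A", "C", "?"])
        two = PartitionedAlignment(["A", "B", "C"], ["A", "C", "N"])
        l1 = TreeLikelihood(tree, full, jc).total_loglik()
        l2 = TreeLikelihood(tree, two, jc).total_loglik()
        assert l1 == pytest.approx(l2)

    def test_taxon_missing_from_alignment_errors(self, jc):
        tree = Tree.from_newick("(A:0.1,B:0.1);")
        aln = PartitionedAlignment(["A", "X"], ["AC", "GT"])
        with pytest.raises(ModelError, match="absent"):
            TreeLikelihood(tree, aln, jc)

    def test_site_loglik_rows_sum_to_total(self, quartet_tree, quartet_aln, jc):
        sw = site_loglik(quartet_tree, quartet_aln, jc)
        total = TreeLikelihood(quartet_tree, quartet_aln, jc).total_loglik()
        assert sw.totals[0] == pytest.approx(total)


class TestBranchOptimization:
    def test_two_taxa_recovers_jc_distance(self, jc):
        aln = PartitionedAlignment(["A", "B"], ["ACGT", "ACGA"])
        tree = Tree.from_newick("(A:0.05,B:0.05);")
        opt, _ = optimize_branch_lengths(tree, aln, jc)
        assert opt.total_length() == pytest.approx(JC_T, abs=1e-4)

    def test_identical_sequences_collapse_to_bound(self, jc):
        aln = PartitionedAlignment(["A", "B"], ["ACGTACGT", "ACGTACGT"])
        tree = Tree.from_newick("(A:0.2,B:0.2);")
        opt, _ = optimize_branch_lengths(tree, aln, jc)
        assert opt.total_length() < 1e-6

    def test_reoptimizing_is_a_fixed_point(self, quartet_tree, quartet_aln, jc):
        once, ll1 = optimize_branch_lengths(quartet_tree, quartet_aln, jc)
        twice, ll2 = optimize_branch_lengths(once, quartet_aln, jc)
        assert ll2 >= ll1 - 1e-6
        assert ll2 - ll1 < 1e-3


class TestModelFitting:
    def test_empirical_frequencies_pseudocount_guard(self):
        aln = PartitionedAlignment(["A", "B"], ["AAAA", "AAAA"])
        f = empirical_frequencies(aln.matrix)
        assert f[0] == pytest.approx(1.0, abs=1e-4)
        assert (f > 0).all()

    def test_degenerate_alignment_warns_and_returns_jc_like(self, quartet_tree):
        aln = PartitionedAlignment(["A", "B", "C", "D"], ["AA"] * 4)
        with pytest.warns(UserWarning, match="no variable"):
            m = fit_model(aln, quartet_tree, "GTR+G")
        assert len(set(m.rates)) == 1

    def test_hky_parameter_recovery(self):
        rng = np.random.default_rng(77)
        tree = random_tree(6, rng, (0.05, 0.15))
        true = SubstitutionModel.hky(4.0, (0.3, 0.2, 0.2, 0.3), gamma_shape=0.5)
        aln = simulate_alignment(tree, true, 20000, 7)
        m = fit_model(aln, tree, "HKY+G")
        assert 3.2 <= m.kappa <= 4.8
        assert 0.35 <= m.gamma_shape <= 0.7

    def test_gtr_on_jc_data_is_near_equal_rates(self):
        rng = np.random.default_rng(78)
        tree = random_tree(6, rng, (0.05, 0.15))
        aln = simulate_alignment(tree, SubstitutionModel.jc(), 8000, 8)
        m = fit_model(aln, tree, "GTR+G")
        r = np.array(m.rates)
        r = r / r.mean()
        assert np.allclose(r, 1.0, atol=0.25)
        assert m.gamma_shape > 5.0
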