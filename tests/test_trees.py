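import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from domainrates import errors
from domainrates.io import Alignment, DomainMap, SequenceRecord, CladeGroupTable, CladeGroupEntry
from domainrates.simulate import SimulationConfig, clade_structured_tree, simulate_alignment
from domainrates.substitution import DistanceMatrix, pairwise_ml_distance
from domainrates.trees import (
    is_rooted,
    midpoint_root,
    neighbor_joining,
    optimize_branch_lengths,
    patristic_matrix,
    robinson_foulds,
    root_to_tip,
    tree_log_likelihood,
)

from conftest import simulate_pair


def _newick(tree):
    return tree.as_string(schema="newick")


def _aligned_patristic(dmat_ref, tree):
    pm = patristic_matrix(tree)
    idx = [pm.taxa.index(t) for t in dmat_ref.taxa]
    return pm.values[np.ix_(idx, idx)]


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # D from the tree ((A:1,B:2):1,(C:3,D:4))
        taxa = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(taxa, D))
        assert np.abs(_aligned_patristic(DistanceMatrix(taxa, D), tree) - D).max() < 1e-12
        # split AB|CD recovered: patristic d(A,B) uses only their cherry
        truth = dendropy.Tree.get(data="((A:1,B:2):1,(C:3,D:4):0);", schema="newick")
        assert robinson_foulds(tree, truth) == 0

    def test_three_taxa_closed_form(self):
        taxa = ["A", "B", "C"]
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(taxa, D))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_ultrametric_additivity(self):
        taxa = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
        )
        dm = DistanceMatrix(taxa, D)
        tree = neighbor_joining(dm)
        assert np.abs(_aligned_patristic(dm, tree) - D).max() < 1e-10

    def test_too_few_taxa(self):
        with pytest.raises(errors.ValidationError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    def test_saturated_rejected_by_default(self):
        taxa = ["A", "B", "C"]
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        sat = np.zeros((3, 3), dtype=bool)
        sat[0, 1] = sat[1, 0] = True
        dm = DistanceMatrix(taxa, D, saturated=sat)
        with pytest.raises(errors.ValidationError, match="saturated"):
            neighbor_joining(dm)
        neighbor_joining(dm, allow_saturated=True)  # explicit override works

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n_taxa=st.integers(5, 8))
    def test_nj_exact_on_additive_matrices(self, seed, n_taxa):
        # property: NJ run on patristic distances of a random tree with
        # lengths in [0.05, 1] reproduces those distances exactly
        taxa = [f"t{i}" for i in range(n_taxa)]
        tree = clade_structured_tree({1: taxa}, seed=seed, length_range=(0.05, 1.0))
        dm = patristic_matrix(tree)
        rebuilt = neighbor_joining(dm)
        assert np.abs(_aligned_patristic(dm, rebuilt) - dm.values).max() < 1e-10
        assert robinson_foulds(tree, rebuilt) == 0


def _pair_alignment(model, t, n, seed):
    a, b = simulate_pair(model, t, n, seed)
    return Alignment([SequenceRecord("A", a), SequenceRecord("B", b)])


class TestTreeLikelihood:
    def test_two_taxon_equals_pairwise(self, jtt):
        aln = _pair_alignment(jtt, 0.4, 300, seed=2)
        pw = pairwise_ml_distance(aln["A"].residues, aln["B"].residues, jtt)
        tree = dendropy.Tree.get(
            data=f"(A:{pw.t_hat / 2},B:{pw.t_hat / 2});", schema="newick"
        )
        ll = tree_log_likelihood(tree, aln, jtt)
        assert ll == pytest.approx(pw.log_likelihood, abs=1e-6)

    def test_reroot_invariance(self, jtt):
        taxa = [f"t{i}" for i in range(4)]
        tree = clade_structured_tree({1: taxa}, seed=9)
        table = CladeGroupTable({t: CladeGroupEntry(1, "g", "s") for t in taxa})
        cfg = SimulationConfig(
            tree=tree,
            seq_length=200,
            domain_map=DomainMap("t0", 200, {}),
            clade_groups=table,
            seed=9,
        )
        ds = simulate_alignment(cfg, jtt)
        ll = tree_log_likelihood(tree, ds.alignment, jtt)
        rr = tree.clone(depth=1)
        rr.reroot_at_node(
            rr.find_node_with_taxon_label("t0").parent_node, update_bipartitions=False
        )
        assert abs(tree_log_likelihood(rr, ds.alignment, jtt) - ll) < 1e-8

    def test_single_column_limit(self, jtt):
        aln = Alignment([SequenceRecord("A", "W"), SequenceRecord("B", "W")])
        tree = dendropy.Tree.get(data="(A:1e-9,B:1e-9);", schema="newick")
        ll = tree_log_likelihood(tree, aln, jtt)
        w = jtt.alphabet.index("W")
        assert ll == pytest.approx(float(np.log(jtt.pi[w])), abs=1e-6)

    def test_taxa_mismatch_named(self, jtt, toy_alignment):
        tree = dendropy.Tree.get(data="(a:1,b:1,x:1);", schema="newick")
        with pytest.raises(errors.TreeError, match="x"):
            tree_log_likelihood(tree, toy_alignment, jtt)


class TestBranchOptimization:
    def test_two_taxon_reduction(self, jtt):
        aln = _pair_alignment(jtt, 0.5, 500, seed=7)
        pw = pairwise_ml_distance(aln["A"].residues, aln["B"].residues, jtt)
        tree = dendropy.Tree.get(data="(A:0.05,B:0.05);", schema="newick")
        opt = optimize_branch_lengths(tree, aln, jtt)
        total = sum(
            nd.edge.length for nd in opt.preorder_node_iter() if nd.parent_node
        )
        assert abs(total - pw.t_hat) < 1e-5

    def test_monotone_and_nondecreasing(self, jtt):
        taxa = [f"t{i}" for i in range(6)]
        tree = clade_structured_tree({1: taxa}, seed=13)
        table = CladeGroupTable({t: CladeGroupEntry(1, "g", "s") for t in taxa})
        cfg = SimulationConfig(
            tree=tree,
            seq_length=300,
            domain_map=DomainMap("t0", 300, {}),
            clade_groups=table,
            seed=13,
        )
        ds = simulate_alignment(cfg, jtt)
        ll_before = tree_log_likelihood(tree, ds.alignment, jtt)
        opt = optimize_branch_lengths(tree, ds.alignment, jtt)
        assert opt.log_likelihood >= ll_before
        assert opt.converged
        # one more pass from the optimum cannot decrease the likelihood
        # one more pass cannot decrease the likelihood beyond the 1e-6
        # convergence tolerance (branch-local vs global summation jitter)
        opt2 = optimize_branch_lengths(opt, ds.alignment, jtt, max_sweeps=1)
        assert opt2.log_likelihood >= opt.log_likelihood - 1e-6

    def test_eight_taxon_length_recovery(self, jtt):
        taxa = [f"t{i}" for i in range(8)]
        tree = clade_structured_tree({1: taxa}, seed=7, length_range=(0.05, 0.3))
        table = CladeGroupTable({t: CladeGroupEntry(1, "g", "s") for t in taxa})
        cfg = SimulationConfig(
            tree=tree,
            seq_length=1000,
            domain_map=DomainMap("t0", 1000, {}),
            clade_groups=table,
            seed=7,
        )
        ds = simulate_alignment(cfg, jtt)
        start = tree.clone(depth=1)
        for nd in start.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = 0.1
        opt = optimize_branch_lengths(start, ds.alignment, jtt)
        true_bl, est_bl = {}, {}
        for src, dst in ((tree, true_bl), (opt, est_bl)):
            for nd in src.preorder_node_iter():
                if nd.parent_node is not None and nd.is_leaf():
                    dst[nd.taxon.label] = nd.edge.length
        rel = [
            abs(est_bl[t] - true_bl[t]) / true_bl[t] for t in true_bl
        ]
        assert np.median(rel) < 0.15


class TestTreeDistances:
    def test_star_tree_patristic(self):
        tree = dendropy.Tree.get(data="(A:1,B:2,C:3);", schema="newick")
        pm = patristic_matrix(tree)
        assert pm.get("A", "B") == pytest.approx(3.0)
        assert pm.get("A", "C") == pytest.approx(4.0)
        assert pm.get("B", "C") == pytest.approx(5.0)

    def test_midpoint_two_taxa(self):
        tree = dendropy.Tree.get(data="(A:1,B:3);", schema="newick")
        rooted = midpoint_root(tree)
        assert is_rooted(rooted)
        rtt = root_to_tip(rooted)
        assert rtt == pytest.approx({"A": 2.0, "B": 2.0})

    def test_root_to_tip_requires_rooted(self):
        tree = dendropy.Tree.get(data="(A:1,B:2,C:3);", schema="newick")
        with pytest.raises(errors.TreeError, match="midpoint"):
            root_to_tip(tree)

    def test_joint_recovery_rate(self, jtt):
        # simulate on known 10-taxon trees; distance -> NJ recovers the
        # topology (RF = 0) in at least 90% of seeded replicates
        taxa = [f"t{i}" for i in range(1, 11)]
        table = CladeGroupTable({t: CladeGroupEntry(1, "g", "s") for t in taxa})
        hits = 0
        for seed in range(1, 21):
            tree = clade_structured_tree({1: taxa}, seed=seed)
            cfg = SimulationConfig(
                tree=tree,
                seq_length=800,
                domain_map=DomainMap("t1", 800, {}),
                clade_groups=table,
                seed=seed,
            )
            ds = simulate_alignment(cfg, jtt)
            from domainrates.substitution import distance_matrix

            nj = neighbor_joining(distance_matrix(ds.alignment, jtt))
            hits += robinson_foulds(tree, nj) == 0
        assert hits >= 18
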