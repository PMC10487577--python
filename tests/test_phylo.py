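import math

import dendropy
import numpy as np
import pytest

from maldiclust import (
    Alignment,
    DistanceMatrix,
    bootstrap_support,
    neighbor_joining,
    pairwise_distance,
    robinson_foulds,
)
from maldiclust.phylo import tree_bipartitions


def random_tree_and_distances(rng, n_taxa):
    """Random unrooted binary tree with branch lengths, plus its additive
    leaf-to-leaf distance matrix (the oracle for NJ consistency)."""
    labels = [f"T{i:02d}" for i in range(n_taxa)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(members):
        if len(members) == 1:
            return dendropy.Node(taxon=taxa.get_taxon(members[0]))
        split = int(rng.integers(1, len(members)))
        order = rng.permutation(len(members))
        node = dendropy.Node()
        for part in ([members[i] for i in order[:split]], [members[i] for i in order[split:]]):
            child = build(part)
            child.edge.length = float(rng.uniform(0.05, 1.0))
            node.add_child(child)
        return node

    tree.seed_node = build(labels)
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    lookup = {t.label: t for t in taxa}
    D = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                D[i, j] = D[j, i] = pdm.distance(lookup[a], lookup[b])
    return tree, DistanceMatrix(labels, D)


def patristic(tree: dendropy.Tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.distance(lookup[labels[i]], lookup[labels[j]])
    return D


class TestPairwiseDistance:
    def test_identical_sequences_zero_for_all_models(self):
        a = Alignment(["x", "y"], ["ACGTACGT", "ACGTACGT"])
        for model in ("p", "jc69", "k2p"):
            assert pairwise_distance(a, model).values[0, 1] == 0.0

    def test_p_distance_counts_mismatch_fraction(self):
        a = Alignment(["x", "y"], ["ACGT", "ACGA"])
        assert pairwise_distance(a, "p").values[0, 1] == pytest.approx(0.25)

    def test_jc69_closed_form(self):
        a = Alignment(["x", "y"], ["ACGT", "ACGA"])
        want = -0.75 * math.log(1 - 4 * 0.25 / 3)
        assert pairwise_distance(a, "jc69").values[0, 1] == pytest.approx(want, abs=1e-4)
        assert want == pytest.approx(0.3041, abs=1e-4)

    def test_k2p_separates_transitions(self):
        # 1 transition (A<->G) and 1 transversion (A<->C) in 8 sites.
        a = Alignment(["x", "y"], ["AAAAAAAA", "GCAAAAAA"])
        P, Q = 1 / 8, 1 / 8
        want = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert pairwise_distance(a, "k2p").values[0, 1] == pytest.approx(want, abs=1e-12)

    def test_pairwise_deletion_ignores_gaps_and_n(self):
        a = Alignment(["x", "y"], ["ACG-N", "ACGTA"])
        assert pairwise_distance(a, "p").values[0, 1] == 0.0

    def test_saturated_pair_named_in_error(self):
        a = Alignment(["x", "y"], ["AAAA", "CCCC"])
        with pytest.raises(ValueError, match="'x' and 'y'"):
            pairwise_distance(a, "jc69")

    def test_no_comparable_sites_errors(self):
        a = Alignment(["x", "y"], ["AC--", "--GT"])
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distance(a, "p")


class TestNeighborJoining:
    def test_four_taxon_worked_example(self):
        # Additive tree: leaves A,B,C,D with branches 1,2,3,4 and internal 1.
        D = DistanceMatrix(
            list("ABCD"),
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        )
        tree = neighbor_joining(D)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        np.testing.assert_allclose(
            patristic(tree.tree, list("ABCD")), D.values, atol=1e-12
        )
        assert tree.total_length() == pytest.approx(11.0)

    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(DistanceMatrix(["A", "B"], [[0, 0.3], [0.3, 0]]))
        assert patristic(tree.tree, ["A", "B"])[0, 1] == pytest.approx(0.3)

    def test_consistent_on_random_additive_matrices(self, rng):
        for _ in range(25):
            true_tree, D = random_tree_and_distances(rng, int(rng.integers(5, 11)))
            est = neighbor_joining(D)
            assert robinson_foulds(est, true_tree) == 0
            np.testing.assert_allclose(
                patristic(est.tree, D.labels), D.values, atol=1e-9
            )

    def test_matches_skbio_topology(self, rng):
        skbio = pytest.importorskip("skbio")
        _, D = random_tree_and_distances(rng, 8)
        noisy = D.values + rng.uniform(0, 0.01, D.values.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        mine = neighbor_joining(DistanceMatrix(D.labels, noisy))
        ref = skbio.tree.nj(skbio.DistanceMatrix(noisy, D.labels))
        ref_tree = dendropy.Tree.get(data=str(ref), schema="newick")
        assert robinson_foulds(mine, ref_tree) == 0

    def test_fully_resolved_and_length_sum(self, rng):
        _, D = random_tree_and_distances(rng, 7)
        tree = neighbor_joining(D)
        internal = [
            n
            for n in tree.tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ]
        assert len(internal) == 7 - 3  # unrooted binary: n-2 internal incl. the root node
        assert tree.total_length() == pytest.approx(
            sum(e.length for e in tree.tree.edges() if e.length), abs=1e-12
        )

    def test_negative_branch_clamped(self):
        # Strongly non-additive matrix forces a negative NJ estimate.
        D = DistanceMatrix(
            list("ABCD"),
            [[0, 2, 2, 0.1], [2, 0, 0.1, 2], [2, 0.1, 0, 2], [0.1, 2, 2, 0]],
        )
        tree = neighbor_joining(D)
        assert all((e.length or 0) >= 0 for e in tree.tree.edges())


class TestBootstrap:
    def _alignment(self, rng, n=6, L=300):
        _, D = random_tree_and_distances(rng, n)
        # quick-and-dirty sequences: evolve from distances via JC simulation
        from maldiclust.synthetic import _evolve

        root = rng.integers(0, 4, L)
        seqs = []
        for i in range(n):
            seqs.append(_evolve(root, 0.05 * (i + 1), rng))
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        return Alignment(D.labels, [bases[s].tobytes().decode() for s in seqs])

    def test_deterministic_under_seed(self, rng):
        a = self._alignment(rng)
        t1 = bootstrap_support(a, n_reps=10, seed=3)
        t2 = bootstrap_support(a, n_reps=10, seed=3)
        assert t1.supports == t2.supports
        assert t1.to_newick() == t2.to_newick()

    def test_supports_are_fractions(self, rng):
        a = self._alignment(rng)
        tree = bootstrap_support(a, n_reps=20, seed=1)
        assert all(0.0 <= v <= 1.0 for v in tree.supports.values())

    def test_duplicated_signal_gives_full_support(self, rng):
        # Two identical blocks of a clean phylogenetic signal: resampling
        # columns cannot erase any split.
        from maldiclust import SimConfig, simulate_hierarchy, simulate_sequences

        cfg = SimConfig(
            n_genera=2,
            species_per_genus=3,
            strains_per_species=1,
            replicates=1,
            sequence_length=2000,
            strain_branch_length=0.01,
            seed=11,
        )
        h = simulate_hierarchy(cfg)
        aln, _ = simulate_sequences(h, cfg)
        doubled = Alignment(aln.ids, [s + s for s in aln.sequences])
        tree = bootstrap_support(doubled, n_reps=50, seed=2)
        assert tree.supports and all(v == 1.0 for v in tree.supports.values())


class TestBipartitions:
    def test_rf_identical_tree_is_zero(self, rng):
        tree, _ = random_tree_and_distances(rng, 6)
        assert robinson_foulds(tree, tree) == 0

    def test_distinct_quartets_differ_by_two(self):
        t1 = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
        t2 = dendropy.Tree.get(data="((A:1,C:1):1,(B:1,D:1):1);", schema="newick")
        assert robinson_foulds(t1, t2) == 2

    def test_max_value_bound(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            t1, _ = random_tree_and_distances(rng, n)
            t2, _ = random_tree_and_distances(rng, n)
            assert robinson_foulds(t1, t2) <= 2 * (n - 3)

    def test_leaf_mismatch_rejected(self, rng):
        t1, _ = random_tree_and_distances(rng, 5)
        t2, _ = random_tree_and_distances(rng, 6)
        with pytest.raises(ValueError, match="leaf sets differ"):
            robinson_foulds(t1, t2)

    def test_matches_dendropy_reference(self, rng):
        import dendropy.calculate.treecompare as tc

        for _ in range(10):
            n = int(rng.integers(5, 10))
            t1, _ = random_tree_and_distances(rng, n)
            t2, _ = random_tree_and_distances(rng, n)
            taxa = dendropy.TaxonNamespace()
            a = dendropy.Tree.get(
                data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=taxa
            )
            b = dendropy.Tree.get(
                data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=taxa
            )
            a.encode_bipartitions()
            b.encode_bipartitions()
            assert robinson_foulds(t1, t2) == tc.symmetric_difference(a, b)
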