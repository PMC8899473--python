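import itertools
from fractions import Fraction

import numpy as np
import pytest
import sympy

from conftest import tree_distance_matrix
from test_trees import dendropy_bipartitions
from turriphylo import simulate
from turriphylo.io_formats import SequenceRecord
from turriphylo.phylo import (
    Bipartition,
    DistanceMatrix,
    PhyloError,
    bipartitions,
    consensus_with_support,
    jc_correct,
    midpoint_root,
    neighbor_joining,
    p_distance,
    robinson_foulds,
)
from turriphylo.trees import Node, Tree, parse_newick, write_newick


# ---------------------------------------------------------------------------
# enumeration oracle: all unrooted topologies by leaf insertion


def all_unrooted_topologies(labels):
    """Every unrooted topology on ``labels`` (trifurcating root form)."""

    def _copy(tree):
        return tree.copy()

    base = Tree(Node())
    for lab in labels[:3]:
        base.root.add(Node(name=lab))
    trees = [base]
    for lab in labels[3:]:
        new_trees = []
        for tree in trees:
            edges = [n for n in tree.preorder() if n is not tree.root]
            for k in range(len(edges)):
                clone = _copy(tree)
                target = [n for n in clone.preorder() if n is not clone.root][k]
                parent = target.parent
                idx = parent.children.index(target)
                mid = Node()
                parent.children[idx] = mid
                mid.parent = parent
                mid.add(target)
                mid.add(Node(name=lab))
                new_trees.append(clone)
        trees = new_trees
    return trees


def topologies_fitting_additive(dm: DistanceMatrix):
    """All topologies whose path lengths can exactly reproduce ``dm`` —
    a least-squares fit per topology, independent of neighbor joining."""
    fits = []
    labels = dm.labels
    index = {lab: i for i, lab in enumerate(labels)}
    for tree in all_unrooted_topologies(labels):
        edges = [n for n in tree.preorder() if n is not tree.root]
        leafsets = {}
        for node in tree.postorder():
            if node.is_leaf:
                leafsets[id(node)] = frozenset([node.name])
            else:
                leafsets[id(node)] = frozenset().union(
                    *(leafsets[id(c)] for c in node.children)
                )
        pairs = list(itertools.combinations(labels, 2))
        A = np.zeros((len(pairs), len(edges)))
        b = np.zeros(len(pairs))
        for r, (x, y) in enumerate(pairs):
            b[r] = dm.values[index[x], index[y]]
            for c, edge in enumerate(edges):
                side = leafsets[id(edge)]
                if (x in side) != (y in side):
                    A[r, c] = 1.0
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.allclose(A @ sol, b, atol=1e-8) and np.all(sol >= -1e-6):
            fits.append(tree)
    return fits


# ---------------------------------------------------------------------------
# p-distance


class TestPDistance:
    def test_identical_sequences(self):
        recs = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGT")]
        assert p_distance(recs)[("a", "b")] == 0.0

    def test_one_of_four(self):
        recs = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGA")]
        assert p_distance(recs)[("a", "b")] == 0.25

    def test_pairwise_deletion(self):
        recs = [SequenceRecord("a", "ACXT"), SequenceRecord("b", "ACGT")]
        # sanitizer strips '-', so missing data is X here; 3 comparable sites
        dm = p_distance(recs, missing_chars=frozenset("X"))
        assert dm[("a", "b")] == 0.0

    def test_no_comparable_sites_errors(self):
        recs = [SequenceRecord("a", "NNNN"), SequenceRecord("b", "ACGT")]
        with pytest.raises(PhyloError, match="a"):
            p_distance(recs)

    def test_unaligned_rejected(self):
        recs = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACG")]
        with pytest.raises(PhyloError, match="aligned"):
            p_distance(recs)


class TestJukesCantor:
    def test_zero(self):
        assert jc_correct(0.0) == 0.0

    def test_closed_form_p03(self):
        # arbitrary-precision oracle for -(3/4) ln(1 - 0.4) = -(3/4) ln(3/5)
        expected = float(-sympy.Rational(3, 4) * sympy.log(sympy.Rational(3, 5)))
        assert jc_correct(0.3) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.3831, abs=5e-5)

    def test_saturation_error_and_cap(self):
        with pytest.raises(PhyloError, match="saturated"):
            jc_correct(0.75)
        assert np.isfinite(jc_correct(0.8, cap=True))

    def test_simulation_round_trip(self):
        # JC estimate within 3 SE of the true distance at L=1e5
        d, L = 0.1, 100_000
        tree = parse_newick(f"(a:{d / 2},b:{d / 2});")
        recs = simulate.evolve_sequences(tree, L, seed=11)
        p = p_distance(recs)[("a", "b")]
        d_hat = jc_correct(p)
        p_true = 0.75 * (1 - np.exp(-4 * d / 3))
        se_p = np.sqrt(p_true * (1 - p_true) / L)
        se_d = se_p / (1 - 4 * p_true / 3)  # delta method
        assert abs(d_hat - d) < 3 * se_d


# ---------------------------------------------------------------------------
# neighbor joining


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        mat = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels=["A", "B", "C"], values=mat))
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (8, 4)])
    def test_additive_recovery(self, n, seed, random_tree_factory):
        tree = random_tree_factory(n, seed)
        dm = tree_distance_matrix(tree)
        recovered = neighbor_joining(dm)
        assert robinson_foulds(recovered, tree) == 0

    def test_additive_branch_lengths_recovered(self, random_tree_factory):
        tree = random_tree_factory(5, 7)
        dm = tree_distance_matrix(tree)
        recovered = neighbor_joining(dm)
        back = tree_distance_matrix(recovered)
        assert np.allclose(back.values, dm.values, atol=1e-9)

    @pytest.mark.parametrize("n,seed", [(4, 10), (5, 11), (6, 12)])
    def test_enumeration_oracle_unique_fit(self, n, seed, random_tree_factory):
        # brute force: the generating topology is the unique additive fit,
        # and NJ finds it
        tree = random_tree_factory(n, seed)
        dm = tree_distance_matrix(tree)
        fits = topologies_fitting_additive(dm)
        assert len(fits) == 1
        assert robinson_foulds(fits[0], tree) == 0
        assert robinson_foulds(neighbor_joining(dm), tree) == 0

    def test_equal_distances_deterministic(self):
        mat = np.ones((5, 5)) - np.eye(5)
        labels = list("abcde")
        t1 = neighbor_joining(DistanceMatrix(labels=labels, values=mat.copy()))
        t2 = neighbor_joining(DistanceMatrix(labels=labels, values=mat.copy()))
        assert write_newick(t1) == write_newick(t2)
        assert len(bipartitions(t1)) == 2  # resolved

    def test_asymmetric_matrix_rejected(self):
        mat = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(PhyloError, match="symmetric"):
            DistanceMatrix(labels=["a", "b", "c"], values=mat)

    def test_too_few_taxa(self):
        mat = np.array([[0, 1], [1, 0]], dtype=float)
        with pytest.raises(PhyloError, match="at least 3"):
            neighbor_joining(DistanceMatrix(labels=["a", "b"], values=mat))


# ---------------------------------------------------------------------------
# midpoint rooting


def _root_depths(tree):
    """Max root-to-leaf distance within each root-adjacent subtree."""
    depths = []
    for child in tree.root.children:
        best = 0.0
        stack = [(child, child.length)]
        while stack:
            node, acc = stack.pop()
            if node.is_leaf:
                best = max(best, acc)
            for c in node.children:
                stack.append((c, acc + c.length))
        depths.append(best)
    return depths


def _diameter_brute_force(tree):
    from turriphylo.phylo import _path_length, leaf_path_between

    names = tree.leaf_names()
    return max(
        _path_length(leaf_path_between(tree, a, b))
        for a, b in itertools.combinations(names, 2)
    )


class TestMidpointRoot:
    def test_two_leaves_splits_path(self):
        t = midpoint_root(parse_newick("(a:1,b:3);"))
        depths = sorted(_root_depths(t))
        assert depths == pytest.approx([2.0, 2.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_root_depths_equal_half_diameter(self, seed, random_tree_factory):
        tree = random_tree_factory(10, seed)
        diameter = _diameter_brute_force(tree)
        rooted = midpoint_root(tree)
        depths = _root_depths(rooted)
        assert max(depths) == pytest.approx(diameter / 2)
        top_two = sorted(depths)[-2:]
        assert top_two[0] == pytest.approx(top_two[1])

    @pytest.mark.parametrize("seed", range(3))
    def test_invariant_to_leaf_order(self, seed, random_tree_factory):
        tree = random_tree_factory(10, seed + 50)
        flipped = tree.copy()
        for node in flipped.preorder():
            node.children.reverse()
        r1 = midpoint_root(tree)
        r2 = midpoint_root(flipped)
        assert bipartitions(r1) == bipartitions(r2)
        assert sorted(_root_depths(r1)) == pytest.approx(sorted(_root_depths(r2)))

    def test_missing_branch_length_errors(self):
        with pytest.raises(PhyloError, match="branch length"):
            midpoint_root(parse_newick("((a,b),c);"))


# ---------------------------------------------------------------------------
# bipartitions


class TestBipartitions:
    def test_four_leaf_resolved(self):
        t = parse_newick("((a,b),(c,d));")
        assert len(bipartitions(t)) == 1

    def test_star_tree_empty(self):
        t = parse_newick("(a,b,c,d,e);")
        assert bipartitions(t) == set()

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_count_identity_all_topologies(self, n):
        labels = [f"t{i}" for i in range(n)]
        for tree in all_unrooted_topologies(labels):
            assert len(bipartitions(tree)) == n - 3

    @pytest.mark.parametrize("n,seed", [(7, 0), (8, 1)])
    def test_count_identity_random(self, n, seed, random_tree_factory):
        assert len(bipartitions(random_tree_factory(n, seed))) == n - 3


class TestRobinsonFoulds:
    def test_identical_zero(self, random_tree_factory):
        t = random_tree_factory(8, 3)
        assert robinson_foulds(t, t.copy()) == 0

    def test_distinct_four_leaf(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,c),(b,d));")
        assert robinson_foulds(t1, t2) == 2

    def test_maximum_brute_force_five_leaves(self):
        trees = all_unrooted_topologies(list("abcde"))
        assert len(trees) == 15
        max_rf = max(
            robinson_foulds(x, y) for x, y in itertools.combinations(trees, 2)
        )
        assert max_rf == 2 * (5 - 3)

    def test_leaf_set_mismatch(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,b),(c,e));")
        with pytest.raises(PhyloError, match="d"):
            robinson_foulds(t1, t2)


# ---------------------------------------------------------------------------
# consensus


class TestConsensus:
    def test_identical_gene_trees(self, random_tree_factory):
        t = random_tree_factory(7, 9)
        result = consensus_with_support([t.copy() for _ in range(5)])
        assert robinson_foulds(result.tree, t) == 0
        assert set(result.frequencies.values()) == {Fraction(1)}

    def test_hand_counted_two_thirds(self):
        trees = [
            parse_newick("((a,b),(d,e),c);"),
            parse_newick("((a,b),(c,d),e);"),
            parse_newick("((a,c),(b,d),e);"),
        ]
        result = consensus_with_support(trees, min_frequency=0.5, greedy=False)
        taxa = frozenset("abcde")
        ab = Bipartition.make({"a", "b"}, taxa)
        assert result.frequencies == {ab: Fraction(2, 3)}
        node_supports = [
            n.support
            for n in result.tree.preorder()
            if not n.is_leaf and n.support is not None
        ]
        assert node_supports == pytest.approx([2 / 3])

    def test_greedy_adds_compatible_by_tie_rule(self):
        trees = [
            parse_newick("((a,b),(d,e),c);"),
            parse_newick("((a,b),(c,d),e);"),
            parse_newick("((a,c),(b,d),e);"),
        ]
        result = consensus_with_support(trees, min_frequency=0.5, greedy=True)
        taxa = frozenset("abcde")
        sides = {bp.side for bp in result.frequencies}
        # {c,d} beats {d,e} lexicographically at equal frequency; {b,d}
        # conflicts with the majority split
        assert sides == {frozenset({"c", "d", "e"}), frozenset({"c", "d"})}

    @pytest.mark.parametrize("seed", range(4))
    def test_majority_rule_matches_brute_force_counting(self, seed):
        # independent oracle: count bipartitions of each gene tree with
        # dendropy's encoding, take splits with frequency > 1/2
        rng_trees = [
            simulate.simulate_species_tree(6, seed=seed * 10 + k) for k in range(5)
        ]
        counts = {}
        for t in rng_trees:
            for side in dendropy_bipartitions(write_newick(t)):
                counts[side] = counts.get(side, 0) + 1
        expected = {
            side: Fraction(c, 5) for side, c in counts.items() if c / 5 > 0.5
        }
        result = consensus_with_support(rng_trees, min_frequency=0.5, greedy=False)
        got = {bp.side: f for bp, f in result.frequencies.items()}
        assert got == expected

    def test_differing_leaf_sets_error_lists_difference(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,b),(c,e));")
        with pytest.raises(PhyloError) as err:
            consensus_with_support([t1, t2])
        assert "d" in str(err.value) and "e" in str(err.value)

    def test_support_decreases_with_discordance(self):
        # pipeline property at fixed seeds: mean support non-increasing
        species = simulate.simulate_species_tree(10, seed=77)
        means = []
        for rate in (0.0, 0.5, 1.0):
            supports = []
            for rep in range(10):
                gts = simulate.simulate_gene_trees(
                    species, 20, rate, seed=1000 + rep, branch_jitter_sd=0.0
                )
                res = consensus_with_support(gts)
                supports.extend(res.support_values())
            means.append(np.mean(supports))
        assert means[0] >= means[1] >= means[2]
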