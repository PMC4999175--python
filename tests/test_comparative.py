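"""Alignment identity, p-distance, neighbour joining and bootstrap."""

import itertools

import numpy as np
import pytest

from chemomine.comparative import (
    AlignParams,
    DistanceMatrix,
    align_pair,
    bipartitions,
    bootstrap_supports,
    center_star_align,
    identity_matrix,
    nj_build,
    p_distance_matrix,
    pairwise_identity,
    tree_to_newick,
    write_newick,
)
from chemomine.errors import ValidationError
from chemomine.synthetic_data import TreePlan, sim_alignment_on_tree

from conftest import random_additive_tree, random_protein, tree_distance_matrix


def enumerate_alignments(a: str, b: str):
    """Every global alignment of a and b as (row_a, row_b) pairs."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def affine_score(ra: str, rb: str, p: AlignParams) -> float:
    score = 0.0
    for row_self, row_other in ((ra, rb), (rb, ra)):
        run = 0
        for c_self in row_self:
            if c_self == "-":
                run += 1
            else:
                if run:
                    score -= p.gap_open + p.gap_extend * run
                run = 0
        if run:
            score -= p.gap_open + p.gap_extend * run
    for x, y in zip(ra, rb):
        if x != "-" and y != "-":
            score += p.match_score if x == y else p.mismatch_score
    return score


def identity_of(ra: str, rb: str) -> float:
    same = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    return 100.0 * same / len(ra)


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACDE", "ACDE", 100.0),
            ("ACDE", "ACDF", 75.0),
            ("ACDE", "ACD", 75.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_symmetry(self, rng):
        for _ in range(15):
            a = random_protein(rng, int(rng.integers(5, 40)))
            b = random_protein(rng, int(rng.integers(5, 40)))
            assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_identity("", "ACD")

    def test_optimal_vs_exhaustive_enumeration(self, rng):
        """DP score equals the exhaustively enumerated optimum for short
        sequences, and the DP identity is achieved by some optimal alignment."""
        params = AlignParams()
        for _ in range(25):
            a = random_protein(rng, int(rng.integers(1, 7)))
            b = random_protein(rng, int(rng.integers(1, 7)))
            ra, rb, score = align_pair(a, b, params)
            alns = [
                (x, y)
                for x, y in enumerate_alignments(a, b)
                if not any(cx == cy == "-" for cx, cy in zip(x, y))
            ]
            best = max(affine_score(x, y, params) for x, y in alns)
            assert score == pytest.approx(best)
            assert affine_score(ra, rb, params) == pytest.approx(best)
            optimal_ids = {
                round(identity_of(x, y), 9)
                for x, y in alns
                if affine_score(x, y, params) == pytest.approx(best)
            }
            assert round(identity_of(ra, rb), 9) in optimal_ids


class TestIdentityMatrix:
    def test_identical_pair(self):
        labels, mat, summary = identity_matrix({"a": "ACDE", "b": "ACDE"})
        assert np.allclose(mat, 100.0) and summary == (100.0, 100.0)

    def test_summary_excludes_diagonal(self):
        labels, mat, (lo, hi) = identity_matrix(
            {"a": "ACDEFGH", "b": "ACDEFGH", "c": "WWYYKKR"}
        )
        assert hi == 100.0 and lo < 100.0

    def test_consistent_with_pairwise(self, rng):
        prots = {f"p{i}": random_protein(rng, 25) for i in range(5)}
        labels, mat, _ = identity_matrix(prots)
        for i, j in itertools.combinations(range(len(labels)), 2):
            expected = pairwise_identity(prots[labels[i]], prots[labels[j]])
            assert mat[i, j] == pytest.approx(expected)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError):
            identity_matrix([("a", "ACD"), ("a", "ACE")])


class TestPDistance:
    def test_identical_rows_zero(self):
        d = p_distance_matrix({"a": "AAAA", "b": "AAAA"})
        assert d.d[0, 1] == 0.0

    def test_simple_fraction(self):
        d = p_distance_matrix({"a": "AAAAAAAAAA", "b": "AAAAAAAAAC"})
        assert d.d[0, 1] == pytest.approx(0.1)

    def test_gap_columns_excluded_from_denominator(self):
        d = p_distance_matrix({"a": "AA-A", "b": "AACC"})
        # comparable columns: 1,2,4 -> one difference
        assert d.d[0, 1] == pytest.approx(1 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            p_distance_matrix({"a": "AAA", "b": "AAAA"})

    def test_all_gap_overlap_rejected(self):
        with pytest.raises(ValidationError):
            p_distance_matrix({"a": "AA--", "b": "--AA"})


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        # distances from the tree ((A:1,B:2):1,(C:3,D:4))
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_build(DistanceMatrix(labels=labels, d=d))
        splits = set(bipartitions(tree))
        assert splits == {frozenset({"A", "B"})}
        assert np.allclose(tree_distance_matrix(tree, labels), d, atol=1e-12)

    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = nj_build(DistanceMatrix(labels=labels, d=d))
        lengths = {c.label: c.length for c in tree.children}
        assert lengths == pytest.approx({"A": 0.0, "B": 2.0, "C": 3.0})

    def test_equal_distance_ties_are_deterministic(self):
        labels = ["A", "B", "C", "D"]
        d = np.ones((4, 4)) - np.eye(4)
        t1 = tree_to_newick(nj_build(DistanceMatrix(labels=labels, d=d.copy())))
        t2 = tree_to_newick(nj_build(DistanceMatrix(labels=labels, d=d.copy())))
        assert t1 == t2

    def test_recovers_random_additive_trees(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            labels, D, true_splits = random_additive_tree(n, rng)
            tree = nj_build(DistanceMatrix(labels=labels, d=D))
            assert set(bipartitions(tree)) == true_splits
            assert np.allclose(tree_distance_matrix(tree, labels), D, atol=1e-9)

    def test_matches_scikit_bio_topology(self, rng):
        skbio = pytest.importorskip("skbio")
        for _ in range(5):
            n = 6
            labels, D, _ = random_additive_tree(n, rng)
            noise = rng.uniform(0, 0.05, size=(n, n))
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            Dn = D + noise
            Dn = (Dn + Dn.T) / 2  # exact float symmetry
            ours = nj_build(DistanceMatrix(labels=labels, d=Dn))
            ref = skbio.tree.nj(skbio.DistanceMatrix(Dn, ids=labels))
            ref_splits = set()
            all_l = frozenset(labels)
            for node in ref.non_tips():
                below = frozenset(t.name for t in node.tips())
                other = all_l - below
                if 1 < len(below) < n - 1:
                    ref_splits.add(
                        below if sorted(below) <= sorted(other) else other
                    )
            assert set(bipartitions(ours)) == ref_splits

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValidationError):
            nj_build(DistanceMatrix(labels=["a", "b", "c"], d=d))

    def test_triangle_violations_do_not_crash(self):
        d = np.array(
            [[0, 10, 0.1, 9], [10, 0, 9, 0.1], [0.1, 9, 0, 10], [9, 0.1, 10, 0]],
            float,
        )
        tree = nj_build(DistanceMatrix(labels=list("ABCD"), d=d))
        assert sorted(tree.leaf_labels()) == list("ABCD")
        # negative estimates clamped
        def all_lengths(node):
            yield node.length
            for c in node.children:
                yield from all_lengths(c)
        assert all(l >= 0 for l in all_lengths(tree))


class TestBootstrap:
    def test_identical_distant_pair_fully_supported(self):
        plan = TreePlan(
            newick="((A:0.0,B:0.0):1.0,(C:0.4,D:0.4):1.0);", root_length=100, rate=1.0
        )
        aln = sim_alignment_on_tree(plan, seed=3)
        assert aln["A"] == aln["B"]
        tree, skipped = bootstrap_supports(aln, n_reps=50, seed=9)
        (node,) = bipartitions(tree).values()
        assert skipped == 0 and node.support == 100
        assert set(bipartitions(tree)) == {frozenset({"A", "B"})}

    def test_single_replicate_support_is_0_or_100(self, rng):
        plan = TreePlan(newick="((A:0.1,B:0.1):0.3,(C:0.1,D:0.1):0.3);", root_length=60)
        aln = sim_alignment_on_tree(plan, seed=5)
        tree, _ = bootstrap_supports(aln, n_reps=1, seed=1)
        supports = [n.support for n in bipartitions(tree).values()]
        assert all(s in (0, 100) for s in supports)

    def test_same_seed_reproducible(self):
        plan = TreePlan(newick="((A:0.1,B:0.1):0.3,(C:0.1,D:0.1):0.3);", root_length=60)
        aln = sim_alignment_on_tree(plan, seed=5)
        n1 = tree_to_newick(bootstrap_supports(aln, n_reps=25, seed=42)[0])
        n2 = tree_to_newick(bootstrap_supports(aln, n_reps=25, seed=42)[0])
        assert n1 == n2

    def test_supports_invariant_to_leaf_order(self):
        plan = TreePlan(newick="((A:0.1,B:0.1):0.5,(C:0.2,D:0.2):0.5);", root_length=80)
        aln = sim_alignment_on_tree(plan, seed=6)
        fwd = dict(sorted(aln.items()))
        rev = dict(sorted(aln.items(), reverse=True))
        s1 = {k: v.support for k, v in bipartitions(bootstrap_supports(fwd, 30, 7)[0]).items()}
        s2 = {k: v.support for k, v in bipartitions(bootstrap_supports(rev, 30, 7)[0]).items()}
        assert s1 == s2


class TestNewick:
    def test_three_leaf_star_shape(self, tmp_path):
        from chemomine.comparative import TreeNode

        tree = TreeNode(
            children=[
                TreeNode(label="A", length=1.0),
                TreeNode(label="B", length=2.0),
                TreeNode(label="C", length=0.5),
            ]
        )
        assert tree_to_newick(tree) == "(A:1,B:2,C:0.5);"

    def test_round_trip_through_dendropy(self, tmp_path):
        import dendropy

        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_build(DistanceMatrix(labels=labels, d=d))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == labels
        # the AB split survives the round trip
        parsed.encode_bipartitions()
        split_sets = {
            frozenset(t.label for t in bip.leafset_taxa(parsed.taxon_namespace))
            for bip in parsed.bipartition_encoding
        }
        assert frozenset({"A", "B"}) in split_sets or frozenset({"C", "D"}) in split_sets

    def test_metacharacter_labels_quoted(self):
        from chemomine.comparative import TreeNode

        tree = TreeNode(
            children=[
                TreeNode(label="x y", length=1.0),
                TreeNode(label="b", length=1.0),
                TreeNode(label="c", length=1.0),
            ]
        )
        assert "'x y'" in tree_to_newick(tree)


class TestCenterStar:
    def test_alignment_contains_all_sequences(self, rng):
        prots = {f"s{i}": random_protein(rng, int(rng.integers(20, 35))) for i in range(4)}
        aln = center_star_align(prots)
        width = len(next(iter(aln.values())))
        for lab, seq in prots.items():
            assert len(aln[lab]) == width
            assert aln[lab].replace("-", "") == seq
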