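"""Distances, neighbor joining against oracles, bootstrap, Newick round trips."""

import math

import numpy as np
import pytest

from htr3evo.align import MSAView
from htr3evo.phylo import (
    DistanceMatrix,
    PhyloTree,
    TreeNode,
    bootstrap,
    from_newick,
    mask_columns,
    neighbor_joining,
    pairwise_distance,
    robinson_foulds,
    to_newick,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def tree_distances(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path lengths, computed by direct traversal."""
    paths = {}

    def walk(node, depth, path):
        if node.is_leaf:
            paths[node.name] = (depth, path)
            return
        for idx, (child, bl) in enumerate(node.children):
            walk(child, depth + bl, path + [(id(node), idx)])

    walk(tree.root, 0.0, [])
    labels = sorted(paths)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            di, pi = paths[labels[i]]
            dj, pj = paths[labels[j]]
            shared = 0.0
            node = tree.root
            for a, b in zip(pi, pj):
                if a != b:
                    break
                child, bl = node.children[a[1]]
                shared += bl
                node = child
            d[i, j] = d[j, i] = di + dj - 2 * shared
    return labels, d


def quartet_split(labels, d, quartet):
    """Four-point rule: the pairing with the smallest sum is the split."""
    i, j, k, l = (labels.index(q) for q in quartet)
    sums = {
        frozenset([frozenset(quartet[:2]), frozenset(quartet[2:])]): d[i, j] + d[k, l],
        frozenset(
            [frozenset([quartet[0], quartet[2]]), frozenset([quartet[1], quartet[3]])]
        ): d[i, k] + d[j, l],
        frozenset(
            [frozenset([quartet[0], quartet[3]]), frozenset([quartet[1], quartet[2]])]
        ): d[i, l] + d[j, k],
    }
    return min(sums, key=sums.get)


def random_tree(n, rng):
    nodes = [TreeNode(name=f"T{i}") for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        new = TreeNode(
            children=[
                (nodes[i], 0.1 + rng.exponential(0.5)),
                (nodes[j], 0.1 + rng.exponential(0.5)),
            ]
        )
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [new]
    root = TreeNode(
        children=[(x, 0.1 + rng.exponential(0.5)) for x in nodes]
    )
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# masking and distances
# ---------------------------------------------------------------------------


class TestMaskColumns:
    def test_gapless_msa_unchanged(self):
        msa = MSAView([("a", "WKND"), ("b", "WKNE")])
        assert mask_columns(msa).rows == msa.rows

    def test_column_below_coverage_dropped(self):
        rows = [(f"s{i}", "W" + ("-" if i < 6 else "K")) for i in range(100)]
        masked = mask_columns(MSAView(rows), coverage=0.95)
        assert masked.n_cols == 1  # 94% < 95% -> second column dropped

    def test_zero_coverage_keeps_everything(self):
        msa = MSAView([("a", "W---"), ("b", "-K--")])
        assert mask_columns(msa, coverage=0.0).n_cols == 4


class TestPairwiseDistance:
    def test_identical_rows_have_zero_distance(self):
        dm = pairwise_distance(MSAView([("a", "WKND"), ("b", "WKND")]))
        assert dm.d[0, 1] == 0.0

    def test_p_distance_closed_form(self):
        row_a = "W" * 100
        row_b = "Y" * 10 + "W" * 90
        dm = pairwise_distance(MSAView([("a", row_a), ("b", row_b)]), "p_distance")
        assert dm.d[0, 1] == pytest.approx(0.10)

    def test_poisson_closed_form(self):
        row_a = "W" * 100
        row_b = "Y" * 10 + "W" * 90
        dm = pairwise_distance(MSAView([("a", row_a), ("b", row_b)]), "poisson")
        assert dm.d[0, 1] == pytest.approx(-math.log(0.9))

    def test_poisson_dominates_p_distance(self, clean_family):
        msa = clean_family.msa.subset(clean_family.msa.accessions[1:])
        p = pairwise_distance(msa, "p_distance").d
        q = pairwise_distance(msa, "poisson").d
        assert (q >= p - 1e-12).all()
        iu = np.triu_indices_from(p, 1)
        equal = np.isclose(q[iu], p[iu])
        assert (p[iu][equal] == 0).all()

    def test_disjoint_pair_raises_with_names(self):
        msa = MSAView([("left", "WK--"), ("right", "--ND")])
        with pytest.raises(ValueError, match="left.*right"):
            pairwise_distance(msa)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance(MSAView([("a", "WKND")]))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


class TestNeighborJoining:
    def test_two_taxa_split_the_distance(self):
        t = neighbor_joining(DistanceMatrix(["A", "B"], [[0, 0.4], [0.4, 0]]))
        assert to_newick(t) == "(A:0.200000,B:0.200000);"

    def test_three_taxa_three_point_formulas(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]])
        t = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        lengths = {c.name: bl for c, bl in t.root.children}
        assert lengths["A"] == pytest.approx(0.2)
        assert lengths["B"] == pytest.approx(0.1)
        assert lengths["C"] == pytest.approx(0.3)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:1))
        d = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
        )
        t = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        assert t.bipartitions() == {frozenset({"C", "D"})}
        labels, td = tree_distances(t)
        idx = [labels.index(x) for x in "ABCD"]
        assert np.allclose(td[np.ix_(idx, idx)], d)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], [[0, 1], [2, 0]])

    @pytest.mark.parametrize("seed", range(5))
    def test_additive_matrices_recover_generating_topology(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        true = random_tree(n, rng)
        labels, d = tree_distances(true)
        nj = neighbor_joining(DistanceMatrix(labels, d))
        assert nj.bipartitions() == true.bipartitions()
        # quartet oracle: NJ tree induces the four-point split of the matrix
        nj_labels, nj_d = tree_distances(nj)
        quartets = [labels[:4], labels[-4:], labels[1:5]]
        for q in quartets:
            assert quartet_split(labels, d, q) == quartet_split(nj_labels, nj_d, q)

    def test_negative_branch_clamped_with_warning(self):
        d = np.array(
            [
                [0.0, 0.1, 0.4, 0.4],
                [0.1, 0.0, 0.4, 0.4],
                [0.4, 0.4, 0.0, 0.02],
                [0.4, 0.4, 0.02, 0.0],
            ]
        )
        # slightly non-additive; should not produce negative lengths silently
        t = neighbor_joining(DistanceMatrix(list("ABCD"), d))

        def all_lengths(node):
            for c, bl in node.children:
                yield bl
                yield from all_lengths(c)

        assert all(bl >= 0 for bl in all_lengths(t.root))


# ---------------------------------------------------------------------------
# newick and bootstrap
# ---------------------------------------------------------------------------


class TestNewick:
    def test_two_leaf_rendering(self):
        t = PhyloTree(TreeNode(children=[(TreeNode(name="A"), 0.2), (TreeNode(name="B"), 0.2)]))
        assert to_newick(t) == "(A:0.200000,B:0.200000);"

    @pytest.mark.parametrize("seed", range(4))
    def test_round_trip_preserves_topology(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = random_tree(int(rng.integers(4, 10)), rng)
        again = from_newick(to_newick(t))
        assert again.bipartitions() == t.bipartitions()
        assert sorted(again.labels) == sorted(t.labels)

    def test_supports_rendered_as_integers(self):
        inner = TreeNode(children=[(TreeNode(name="A"), 1.0), (TreeNode(name="B"), 1.0)])
        inner.support = 87.4
        t = PhyloTree(
            TreeNode(children=[(inner, 1.0), (TreeNode(name="C"), 1.0), (TreeNode(name="D"), 1.0)])
        )
        assert ")87:" in to_newick(t)


class TestBootstrap:
    def test_zero_replicates_returns_tree_unchanged(self, clean_family):
        msa = clean_family.msa.subset(clean_family.msa.accessions[1:])
        tree, supports = bootstrap(msa, n_reps=0)
        assert supports == {}
        assert sorted(tree.labels) == sorted(msa.accessions)

    def test_same_seed_reproduces_supports(self, clean_family):
        msa = clean_family.msa.subset(clean_family.msa.accessions[1:])
        _, s1 = bootstrap(msa, n_reps=25, seed=5)
        _, s2 = bootstrap(msa, n_reps=25, seed=5)
        assert s1 == s2

    def test_supports_invariant_under_row_permutation(self, clean_family):
        msa = clean_family.msa.subset(clean_family.msa.accessions[1:])
        permuted = MSAView(msa.rows[::-1])
        _, s1 = bootstrap(msa, n_reps=25, seed=5)
        _, s2 = bootstrap(permuted, n_reps=25, seed=5)
        assert s1 == s2


def test_robinson_foulds_zero_on_self(clean_family):
    assert robinson_foulds(clean_family.true_tree, clean_family.true_tree) == 0
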