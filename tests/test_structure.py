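"""MDS, agglomerative clustering and neighbor joining against oracles."""

import io

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score
from skbio import DistanceMatrix as SkbioDM
from skbio.stats.ordination import pcoa
from skbio.tree import nj as skbio_nj

from conftest import euclidean_matrix, random_distance_matrix
from lexstrat import (
    DistanceMatrix,
    ValidationError,
    agglomerative,
    classical_mds,
    cophenetic_matrix,
    cut_tree,
    neighbor_joining,
    to_newick,
    tree_distance_matrix,
)


def random_tree_matrix(rng: np.random.Generator, n_taxa: int) -> DistanceMatrix:
    """Additive matrix from a random binary tree with positive branch lengths."""
    nodes = [(f"T{i:02d}", {f"T{i:02d}": 0.0}) for i in range(n_taxa)]
    dist = np.zeros((n_taxa, n_taxa))
    names = [name for name, _ in nodes]
    idx = {name: i for i, name in enumerate(names)}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (_, da), (_, db) = nodes[i], nodes[j]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        for leaf_a, xa in da.items():
            for leaf_b, xb in db.items():
                dist[idx[leaf_a], idx[leaf_b]] = dist[idx[leaf_b], idx[leaf_a]] = (
                    xa + la + xb + lb
                )
        merged = {k: v + la for k, v in da.items()}
        merged.update({k: v + lb for k, v in db.items()})
        nodes = [nodes[x] for x in range(len(nodes)) if x not in (i, j)] + [("", merged)]
    return DistanceMatrix(names, dist)


def random_ultrametric(rng: np.random.Generator, n: int) -> DistanceMatrix:
    """Cophenetic matrix of a random dendrogram with increasing merge heights."""
    clusters = [[i] for i in range(n)]
    values = np.zeros((n, n))
    height = 0.0
    while len(clusters) > 1:
        height += rng.uniform(0.1, 1.0)
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                values[a, b] = values[b, a] = height
        merged = clusters[i] + clusters[j]
        clusters = [clusters[x] for x in range(len(clusters)) if x not in (i, j)]
        clusters.append(merged)
    return DistanceMatrix([f"U{i:02d}" for i in range(n)], values)


class TestClassicalMds:
    def test_equilateral_triangle(self):
        d = DistanceMatrix(["A", "B", "C"], np.ones((3, 3)) - np.eye(3))
        e = classical_mds(d, k=2)
        np.testing.assert_allclose(e.distances(), d.values, atol=1e-9)

    def test_collinear_points_recover_1d(self):
        pts = np.array([[0.0], [1.0], [2.0], [4.0]])
        d = euclidean_matrix(np.hstack([pts, np.zeros_like(pts)]))
        e = classical_mds(d, k=2)
        assert e.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(e.distances(), d.values, atol=1e-9)

    @pytest.mark.parametrize("k", [2, 3])
    def test_reproduces_euclidean_inputs(self, k):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(k + 1, 12)
            d = euclidean_matrix(rng.normal(size=(n, k)))
            e = classical_mds(d, k=k)
            np.testing.assert_allclose(e.distances(), d.values, atol=1e-9)
            assert not e.degenerate

    def test_matches_skbio_pcoa(self, reference_ldn):
        e = classical_mds(reference_ldn, k=2)
        ord_res = pcoa(SkbioDM(reference_ldn.values, ids=reference_ldn.labels))
        ref = ord_res.samples.to_numpy()[:, :2]
        # orientation-free comparison: embedded interpoint distances agree
        diff = ref[:, None, :] - ref[None, :, :]
        np.testing.assert_allclose(
            e.distances(), np.sqrt((diff**2).sum(-1)), atol=1e-8
        )

    def test_centered_and_eigenvalues_sorted(self, reference_ldn):
        e = classical_mds(reference_ldn, k=3)
        n = len(e.labels)
        assert np.all(np.abs(e.coords.sum(axis=0)) < 1e-9 * n)
        assert np.all(np.diff(e.all_eigenvalues) <= 1e-12)
        # LDN matrices are non-Euclidean: negative eigenvalues are reported
        assert e.all_eigenvalues[-1] < 0

    def test_deterministic_orientation(self, reference_ldn):
        e1 = classical_mds(reference_ldn, k=2)
        e2 = classical_mds(reference_ldn, k=2)
        np.testing.assert_array_equal(e1.coords, e2.coords)
        anchor = int(np.argmin(np.array(e1.labels, dtype=object)))
        assert np.all(e1.coords[anchor] <= 1e-12)

    def test_too_few_points_rejected(self):
        d = DistanceMatrix(["A", "B", "C"], np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ValidationError):
            classical_mds(d, k=3)


class TestAgglomerative:
    def test_two_clouds_recovered(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 0.05, (5, 2)), rng.normal(10, 0.05, (6, 2))])
        d = euclidean_matrix(pts)
        truth = [0] * 5 + [1] * 6
        for linkage in ("average", "ward"):
            t = agglomerative(d, linkage=linkage)
            part = cut_tree(t, 2)
            found = [part[label] for label in d.labels]
            assert adjusted_rand_score(truth, found) == 1.0

    def test_two_leaves_merge_at_the_distance(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        t = agglomerative(d, linkage="average")
        assert t.root.height == pytest.approx(0.4)
        assert to_newick(t) == "(A:0.4,B:0.4);"

    def test_average_cophenetics_reproduce_ultrametrics(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = random_ultrametric(rng, int(rng.integers(3, 10)))
            t = agglomerative(d, linkage="average")
            coph = cophenetic_matrix(t)
            np.testing.assert_allclose(coph.values, d.values, atol=1e-10)

    def test_merge_heights_monotone(self, reference_ldn):
        for linkage in ("average", "ward"):
            t = agglomerative(reference_ldn, linkage=linkage)
            heights = t.merges[:, 2]
            assert np.all(np.diff(heights) >= -1e-12)

    def test_cophenetic_ultrametric_inequality(self):
        rng = np.random.default_rng(9)
        d = random_distance_matrix(rng, 8)
        c = cophenetic_matrix(agglomerative(d, linkage="average")).values
        n = len(c)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert c[i, j] <= max(c[i, k], c[k, j]) + 1e-12

    def test_label_order_invariance(self, reference_ldn):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(reference_ldn))
        shuffled = DistanceMatrix(
            [reference_ldn.labels[i] for i in perm],
            reference_ldn.values[np.ix_(perm, perm)],
        )
        p1 = cut_tree(agglomerative(reference_ldn), 3)
        p2 = cut_tree(agglomerative(shuffled), 3)
        v1 = [p1[x] for x in reference_ldn.labels]
        v2 = [p2[x] for x in reference_ldn.labels]
        assert adjusted_rand_score(v1, v2) == 1.0


class TestCutTree:
    def test_extremes(self, reference_ldn):
        t = agglomerative(reference_ldn)
        n = len(reference_ldn)
        assert len(set(cut_tree(t, n).values())) == n
        assert set(cut_tree(t, 1).values()) == {0}
        with pytest.raises(ValueError):
            cut_tree(t, n + 1)

    def test_three_family_cut_matches_truth(self, reference_sim, reference_ldn):
        _, _, _, partition = reference_sim
        t = agglomerative(reference_ldn, linkage="average")
        found = cut_tree(t, 3)
        labels = reference_ldn.labels
        truth = [partition[x] for x in labels]
        assert adjusted_rand_score(truth, [found[x] for x in labels]) == 1.0


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        vals = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        t = neighbor_joining(DistanceMatrix(["A", "B", "C"], vals))
        lengths = {leaf.name: leaf.length for leaf in t.root.leaves()}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_exact_on_additive_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            d = random_tree_matrix(rng, int(rng.integers(4, 11)))
            t = neighbor_joining(d)
            paths = tree_distance_matrix(t).submatrix(d.labels)
            np.testing.assert_allclose(paths.values, d.values, atol=1e-9)
            assert not t.has_clamped_branches()

    def test_ultrametric_input_additive(self):
        rng = np.random.default_rng(21)
        d = random_ultrametric(rng, 8)
        t = neighbor_joining(d)
        paths = tree_distance_matrix(t).submatrix(d.labels)
        np.testing.assert_allclose(paths.values, d.values, atol=1e-9)

    def test_topology_matches_skbio(self):
        rng = np.random.default_rng(33)
        d = random_tree_matrix(rng, 7)
        ours = dendropy.Tree.get(
            data=to_newick(neighbor_joining(d)), schema="newick"
        )
        theirs = dendropy.Tree.get(
            data=str(skbio_nj(SkbioDM(d.values, ids=d.labels))), schema="newick"
        )
        tns = dendropy.TaxonNamespace()
        ours.migrate_taxon_namespace(tns)
        theirs.migrate_taxon_namespace(tns)
        ours.encode_bipartitions()
        theirs.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(ours, theirs) == 0

    def test_needs_three_taxa(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValidationError):
            neighbor_joining(d)

    def test_negative_branches_clamped_and_flagged(self):
        # violates the triangle inequality: the closed form gives B length -0.1
        vals = np.array([[0, 0.2, 0.9], [0.2, 0, 0.5], [0.9, 0.5, 0]])
        t = neighbor_joining(DistanceMatrix(list("ABC"), vals))
        def all_lengths(node):
            yield node.length
            for c in node.children:
                yield from all_lengths(c)
        assert min(all_lengths(t.root)) >= 0.0
        assert t.has_clamped_branches()


class TestNewick:
    def test_roundtrip_preserves_topology_and_lengths(self, reference_ldn):
        t = neighbor_joining(reference_ldn)
        parsed = dendropy.Tree.get(
            data=to_newick(t), schema="newick", preserve_underscores=True
        )
        pdm = parsed.phylogenetic_distance_matrix()
        ours = tree_distance_matrix(t)
        for ta in pdm.taxon_iter():
            for tb in pdm.taxon_iter():
                if ta is tb:
                    continue
                i, j = ours.index(ta.label), ours.index(tb.label)
                assert pdm.distance(ta, tb) == pytest.approx(ours.values[i, j], abs=1e-9)

    def test_metacharacter_labels_quoted(self):
        d = DistanceMatrix(
            ["a b", "c:d", "plain"],
            np.array([[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]]),
        )
        nwk = to_newick(neighbor_joining(d))
        assert "'a b'" in nwk and "'c:d'" in nwk
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {x.taxon.label for x in parsed.leaf_node_iter()} == {"a b", "c:d", "plain"}
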