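"""Supermatrix concatenation, distances, NJ reconstruction, Newick I/O."""

import math

import dendropy
import numpy as np
import pytest

from mitochar.phylo import (
    PCG_ORDER,
    DistanceMatrix,
    PhyloTree,
    TreeNode,
    concatenate_pcgs,
    distance_matrix,
    neighbor_joining,
    pairwise_distance,
    parse_newick,
    write_newick,
)


def _random_genes(rng, taxa, genes, length=30):
    return {
        t: {g: "".join(rng.choice(list("ACGT"), size=length)) for g in genes} for t in taxa
    }


class TestConcatenation:
    def test_row_lengths_and_partitions(self):
        rng = np.random.default_rng(0)
        data = _random_genes(rng, ["tax1", "tax2"], PCG_ORDER)
        rows = concatenate_pcgs(data)
        assert len(rows) == 2
        for row in rows:
            assert len(row.partition_map) == 13
            assert len(row.sequence) == sum(e - s + 1 for _, s, e in row.partition_map)
            # partitions tile the row exactly, in order
            assert row.partition_map[0][1] == 1
            for (g1, s1, e1), (g2, s2, e2) in zip(row.partition_map, row.partition_map[1:]):
                assert s2 == e1 + 1
            assert row.partition_map[-1][2] == len(row.sequence)
            assert [g for g, _, _ in row.partition_map] == list(PCG_ORDER)

    def test_missing_gene_names_taxon_and_gene(self):
        rng = np.random.default_rng(1)
        data = _random_genes(rng, ["tax1", "tax2"], PCG_ORDER)
        del data["tax2"]["atp8"]
        with pytest.raises(ValueError, match="tax2 missing gene atp8"):
            concatenate_pcgs(data)

    def test_unequal_gene_lengths_rejected(self):
        data = {"a": {"x": "ACGT"}, "b": {"x": "ACG"}}
        with pytest.raises(ValueError, match="unequal lengths"):
            concatenate_pcgs(data, order=["x"])

    def test_order_permutation_preserves_composition(self):
        rng = np.random.default_rng(2)
        data = _random_genes(rng, ["tax1"], PCG_ORDER)
        row1 = concatenate_pcgs(data)[0]
        row2 = concatenate_pcgs(data, order=tuple(reversed(PCG_ORDER)))[0]
        assert sorted(row1.sequence) == sorted(row2.sequence)
        assert [g for g, _, _ in row2.partition_map] == list(reversed(PCG_ORDER))


class TestDistances:
    def test_identical_sequences_zero(self):
        for model in ("p", "JC69", "K2P"):
            assert pairwise_distance("ACGTACGT", "ACGTACGT", model) == 0.0

    def test_p_distance_fraction(self):
        assert pairwise_distance("AAAAAAAAAA", "AAAAAAAAAC", "p") == pytest.approx(0.1)

    def test_jc69_closed_form(self):
        # p = 0.1 -> -(3/4) ln(1 - 4*0.1/3) = 0.10732
        d = pairwise_distance("AAAAAAAAAA", "AAAAAAAAAC", "JC69")
        assert d == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-12)
        assert d == pytest.approx(0.10732, abs=1e-5)

    def test_jc69_saturation(self):
        with pytest.raises(ValueError, match="saturated"):
            pairwise_distance("AAAA", "CCCC", "JC69")

    def test_jc69_first_order_agreement_with_p(self):
        a = "A" * 1000
        b = "C" * 5 + "A" * 995  # p = 0.005
        p = pairwise_distance(a, b, "p")
        assert abs(pairwise_distance(a, b, "JC69") - p) < 1e-3

    def test_pairwise_deletion(self):
        assert pairwise_distance("ACGTN", "ACGAN", "p") == pytest.approx(0.25)
        with pytest.raises(ValueError, match="no comparable sites"):
            pairwise_distance("NNN", "ACG")

    def test_k2p_separates_transitions(self):
        # one transition (A<->G) over 10 sites vs one transversion
        ts = pairwise_distance("A" + "C" * 9, "G" + "C" * 9, "K2P")
        tv = pairwise_distance("A" + "C" * 9, "T" + "C" * 9, "K2P")
        assert ts != pytest.approx(tv)


def _random_tree(rng, n_leaves):
    """Random bifurcating topology with random strictly positive lengths."""
    nodes = [TreeNode(label=f"t{i}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        parent.children.append((nodes[i], float(rng.uniform(0.05, 1.0))))
        parent.children.append((nodes[j], float(rng.uniform(0.05, 1.0))))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = TreeNode()
    for child in nodes:
        root.children.append((child, float(rng.uniform(0.05, 1.0))))
    return PhyloTree(root=root)


class TestNeighborJoining:
    def test_three_taxa_exact_fit(self):
        d = DistanceMatrix(["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = neighbor_joining(d)
        pl = tree.path_lengths()
        for a, b in (("A", "B"), ("A", "C"), ("B", "C")):
            assert pl.get(a, b) == pytest.approx(d.get(a, b), abs=1e-12)

    def test_four_taxon_additive_matrix_recovered(self):
        # known tree: ((A:1,B:2):1,(C:3,D:4)); distances by path summation
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            float,
        )
        tree = neighbor_joining(DistanceMatrix(labels, d))
        pl = tree.path_lengths()
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert pl.get(a, b) == pytest.approx(d[i, j], abs=1e-9)

    def test_identical_taxa_zero_cherry(self):
        d = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array([[0, 0, 2, 2], [0, 0, 2, 2], [2, 2, 0, 2], [2, 2, 2, 0]], float),
        )
        pl = neighbor_joining(d).path_lengths()
        assert pl.get("A", "B") == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_leaves", range(4, 11))
    def test_additive_recovery(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        true_tree = _random_tree(rng, n_leaves)
        d = true_tree.path_lengths()
        recovered = neighbor_joining(d).path_lengths()
        assert recovered.labels == d.labels
        assert np.allclose(recovered.values, d.values, atol=1e-9)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["A", "B", "C"], np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))


class TestNewick:
    def test_three_leaf_shape(self):
        d = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float))
        text = write_newick(neighbor_joining(d))
        assert text.startswith("(") and text.endswith(";")
        assert all(label in text for label in "ABC")

    def test_round_trip_preserves_metric(self):
        rng = np.random.default_rng(7)
        tree = _random_tree(rng, 8)
        again = parse_newick(write_newick(tree))
        assert sorted(again.leaf_labels()) == sorted(tree.leaf_labels())
        assert np.allclose(again.path_lengths().values, tree.path_lengths().values, atol=1e-9)

    def test_dendropy_agrees_on_path_lengths(self):
        """Independent cross-check: dendropy's phylogenetic distance
        matrix from our Newick output matches our own path lengths."""
        rng = np.random.default_rng(8)
        tree = _random_tree(rng, 6)
        newick = write_newick(tree)
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = dtree.phylogenetic_distance_matrix()
        ours = tree.path_lengths()
        for t1 in dtree.taxon_namespace:
            for t2 in dtree.taxon_namespace:
                if t1 is t2:
                    continue
                assert pdm.patristic_distance(t1, t2) == pytest.approx(
                    ours.get(t1.label, t2.label), abs=1e-6
                )

    def test_supermatrix_to_tree_pipeline(self):
        rng = np.random.default_rng(9)
        data = _random_genes(rng, [f"t{i}" for i in range(5)], PCG_ORDER, length=60)
        rows = concatenate_pcgs(data)
        dm = distance_matrix(rows, model="p")
        tree = neighbor_joining(dm)
        assert sorted(tree.leaf_labels()) == sorted(dm.labels)
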