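"""p-distances, neighbor joining and reference-guided grouping."""

import itertools
import random

import dendropy
import numpy as np
import pytest

from famscan.genome_io import SeqRecord
from famscan.phylogeny import (
    DistanceMatrix,
    PhylogenyError,
    assign_groups,
    nj_tree,
    pdistance_matrix,
)


def random_additive_tree(seed, n=8):
    """A random binary tree with positive branch lengths (the generating
    truth for additive-recovery checks)."""
    rng = random.Random(seed)
    taxa = [f"T{i}" for i in range(n)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    leaves = []
    for name in taxa[:3]:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(name)
        tree.seed_node.add_child(node)
        node.edge.length = rng.uniform(0.05, 1.0)
        leaves.append(node)
    for name in taxa[3:]:
        host = rng.choice(leaves)
        parent = host.parent_node
        length = host.edge.length
        split = dendropy.Node()
        parent.remove_child(host)
        parent.add_child(split)
        split.edge.length = rng.uniform(0.2, 0.8) * length
        split.add_child(host)
        host.edge.length = length - split.edge.length
        leaf = dendropy.Node()
        leaf.taxon = tns.get_taxon(name)
        split.add_child(leaf)
        leaf.edge.length = rng.uniform(0.05, 1.0)
        leaves.append(leaf)
    return tree, taxa


def tree_distance_matrix(tree, taxa):
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(
            tns.get_taxon(taxa[i]), tns.get_taxon(taxa[j])
        )
    return d


class TestPDistance:
    def test_identical_sequences_zero(self):
        seqs = [SeqRecord(f"s{i}", "MKVLDD") for i in range(3)]
        dm = pdistance_matrix(seqs)
        assert np.allclose(dm.d, 0.0)

    def test_half_mismatch(self):
        seqs = [SeqRecord("a", "AAAA"), SeqRecord("b", "AATT"), SeqRecord("c", "AAAA")]
        dm = pdistance_matrix(seqs)
        assert dm.d[0, 1] == pytest.approx(0.5)

    def test_symmetry_random(self, bundle):
        seqs = [p for p in bundle.proteome if p.id in set(bundle.truth.members)][:6]
        dm = pdistance_matrix(seqs)
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0.0)

    def test_needs_three(self):
        with pytest.raises(PhylogenyError):
            pdistance_matrix([SeqRecord("a", "MK"), SeqRecord("b", "MK")])


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        pdm = tree.phylogenetic_distance_matrix()
        tns = tree.taxon_namespace
        get = lambda x, y: pdm.patristic_distance(
            tns.get_taxon(x), tns.get_taxon(y)
        )
        assert get("a", "b") == pytest.approx(0.3)
        assert get("a", "c") == pytest.approx(0.5)
        assert get("b", "c") == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", range(8))
    def test_additive_recovery(self, seed):
        """NJ on an additive matrix recovers the generating topology and
        branch lengths (within 1e-9 on patristic distances)."""
        truth, taxa = random_additive_tree(seed)
        d = tree_distance_matrix(truth, taxa)
        out = nj_tree(DistanceMatrix(taxa, d))
        out2 = dendropy.Tree.get(
            data=out.as_string(schema="newick"),
            schema="newick",
            taxon_namespace=truth.taxon_namespace,
        )
        out2.encode_bipartitions()
        truth.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(truth, out2)
        assert rf == 0
        d2 = tree_distance_matrix(out2, taxa)
        assert np.max(np.abs(d2 - d)) < 1e-9

    def test_label_permutation_invariance(self):
        truth, taxa = random_additive_tree(123)
        d = tree_distance_matrix(truth, taxa)
        perm = list(range(len(taxa)))
        random.Random(1).shuffle(perm)
        dm1 = DistanceMatrix(taxa, d)
        dm2 = DistanceMatrix([taxa[i] for i in perm], d[np.ix_(perm, perm)])
        t1, t2 = nj_tree(dm1), nj_tree(dm2)
        tns = dendropy.TaxonNamespace(taxa)
        a = dendropy.Tree.get(data=t1.as_string(schema="newick"),
                              schema="newick", taxon_namespace=tns)
        b = dendropy.Tree.get(data=t2.as_string(schema="newick"),
                              schema="newick", taxon_namespace=tns)
        assert dendropy.calculate.treecompare.symmetric_difference(a, b) == 0

    def test_newick_round_trip(self):
        truth, taxa = random_additive_tree(5)
        out = nj_tree(DistanceMatrix(taxa, tree_distance_matrix(truth, taxa)))
        text = out.as_string(schema="newick")
        back = dendropy.Tree.get(data=text, schema="newick",
                                 taxon_namespace=out.taxon_namespace)
        assert {l.taxon.label for l in back.leaf_node_iter()} == set(taxa)
        assert back.as_string(schema="newick") == text

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 0.1, 0.2], [0.3, 0.0, 0.1], [0.2, 0.1, 0.0]])
        with pytest.raises(PhylogenyError):
            DistanceMatrix(["a", "b", "c"], d)


class TestAssignGroups:
    def test_all_references_identity(self):
        truth, taxa = random_additive_tree(2)
        tree = nj_tree(DistanceMatrix(taxa, tree_distance_matrix(truth, taxa)))
        refs = {t: f"g{i % 2}" for i, t in enumerate(taxa)}
        assert assign_groups(tree, refs) == refs

    def test_missing_group_reference_error(self):
        truth, taxa = random_additive_tree(3)
        tree = nj_tree(DistanceMatrix(taxa, tree_distance_matrix(truth, taxa)))
        with pytest.raises(PhylogenyError):
            assign_groups(tree, {"not_in_tree": "g1"})

    def test_planted_groups_recovered(self, bundle):
        """Members cluster by their generating group template: with one
        reference per group, every other member inherits its planted group."""
        members = [p for p in bundle.proteome if p.id in set(bundle.truth.members)]
        tree = nj_tree(pdistance_matrix(members))
        refs = {}
        for gid in sorted(bundle.truth.groups):
            g = bundle.truth.groups[gid]
            if f"group{g}" not in refs.values():
                refs[gid] = f"group{g}"
        got = assign_groups(tree, refs)
        want = {gid: f"group{bundle.truth.groups[gid]}" for gid in got}
        assert got == want
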