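"""Alignment, occupancy trimming, neighbor-joining and Newick round-trips."""

import shutil

import dendropy
import numpy as np
import pytest

from ocgkit.config_io import SequenceRecord, ValidationError
from ocgkit.phylo import (
    Alignment,
    PhyloTree,
    align_ocg,
    infer_tree,
    nj_tree,
    occupancy_trim,
    p_distance_matrix,
    parse_newick,
    write_newick,
)


def rec(name, seq):
    return SequenceRecord(name, seq)


class TestAlignOcg:
    def test_identical_sequences_gap_free(self):
        seq = "MKVLWAALLVTFLAGCQA"
        aln = align_ocg([rec("a", seq), rec("b", seq)])
        assert aln.rows == [seq, seq]

    @pytest.mark.parametrize("method", ["builtin"])
    def test_degap_recovers_inputs(self, method):
        rng = np.random.default_rng(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        base = "".join(rng.choice(list(aas), 80))
        seqs = [base]
        for _ in range(3):  # random indels and substitutions
            s = list(base)
            for _ in range(5):
                pos = rng.integers(len(s))
                op = rng.random()
                if op < 0.4 and len(s) > 10:
                    del s[pos]
                elif op < 0.7:
                    s.insert(pos, aas[rng.integers(20)])
                else:
                    s[pos] = aas[rng.integers(20)]
            seqs.append("".join(s))
        recs = [rec(f"s{i}", s) for i, s in enumerate(seqs)]
        aln = align_ocg(recs, method=method)
        for i, r in enumerate(recs):
            assert aln.degapped(i) == r.sequence

    def test_single_indel_triple_introduces_one_gap_column(self):
        base = "MKVLWAALLVTFLAGCQAKVLWAALLVT"
        dropped = base[:10] + base[11:]
        aln = align_ocg([rec("a", base), rec("b", base), rec("c", dropped)])
        assert aln.length == len(base)
        occ = aln.column_occupancy()
        assert (occ < 1.0).sum() == 1

    def test_single_sequence_rejected(self):
        with pytest.raises(ValidationError):
            align_ocg([rec("a", "MKVL")])

    def test_missing_binary_names_flag(self, monkeypatch):
        monkeypatch.setattr(shutil, "which", lambda b: None)
        with pytest.raises(ValidationError, match="--mafft"):
            align_ocg([rec("a", "MKVL"), rec("b", "MKVL")], method="mafft")

    @pytest.mark.skipif(shutil.which("mafft") is None, reason="mafft not installed")
    def test_mafft_adapter_degap_conservation(self):
        rng = np.random.default_rng(1)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        recs = [
            rec(f"s{i}", "".join(rng.choice(list(aas), int(rng.integers(60, 90)))))
            for i in range(4)
        ]
        aln = align_ocg(recs, method="mafft")
        for i, r in enumerate(recs):
            assert aln.degapped(i) == r.sequence


class TestOccupancyTrim:
    def test_sparse_column_removed_at_default_cutoff(self):
        # 100 rows; one column with 9 residues (9% < 10%)
        rows = ["A" + "C" * 5 for _ in range(9)] + ["-" + "C" * 5 for _ in range(91)]
        aln = Alignment([f"s{i}" for i in range(100)], rows)
        trimmed = occupancy_trim(aln, 10.0)
        assert trimmed.length == 5

    def test_exact_boundary_retained(self):
        # 10 rows; column with exactly 1 residue = 10% occupancy -> kept
        rows = ["A" + "C" * 3] + ["-" + "C" * 3 for _ in range(9)]
        aln = Alignment([f"s{i}" for i in range(10)], rows)
        assert occupancy_trim(aln, 10.0).length == 4

    def test_gap_free_alignment_unchanged(self):
        aln = Alignment(["a", "b"], ["MKVL", "MKIL"])
        assert occupancy_trim(aln, 10.0).rows == aln.rows

    def test_idempotent_and_conservative(self):
        rng = np.random.default_rng(2)
        rows = [
            "".join(rng.choice(list("ACD-"), 60, p=[0.2, 0.2, 0.2, 0.4]))
            for _ in range(12)
        ]
        aln = Alignment([f"s{i}" for i in range(12)], rows)
        once = occupancy_trim(aln, 25.0)
        twice = occupancy_trim(once, 25.0)
        assert twice.rows == once.rows
        assert once.length <= aln.length
        # residue content of kept columns is a subsequence of the original row
        for orig, kept in zip(aln.rows, once.rows):
            assert _is_subsequence(kept.replace("-", ""), orig.replace("-", ""))

    def test_all_columns_removed_is_error(self):
        aln = Alignment(["a", "b", "c", "d"], ["A---", "-C--", "--G-", "---T"])
        with pytest.raises(ValidationError, match="occupancy"):
            occupancy_trim(aln, 90.0)


def _is_subsequence(small, big):
    it = iter(big)
    return all(c in it for c in small)


def random_additive_tree(n_leaves, rng):
    """Random unrooted binary tree with random branch lengths; returns
    (dendropy tree, leaf labels, additive distance matrix)."""
    labels = [f"t{i}" for i in range(n_leaves)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    # start from a 3-leaf star, attach remaining leaves to random edges
    for i in range(3):
        child = tree.seed_node.new_child()
        child.taxon = taxa.get_taxon(labels[i])
        child.edge.length = rng.uniform(0.1, 1.0)
    for i in range(3, n_leaves):
        edges = [
            e for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node and e.length is not None
        ]
        edge = edges[rng.integers(len(edges))]
        head = edge.head_node
        parent = head.parent_node
        split = dendropy.Node()
        parent.remove_child(head)
        parent.add_child(split)
        split.add_child(head)
        frac = rng.uniform(0.2, 0.8)
        split.edge.length = edge.length * frac
        head.edge.length = edge.length * (1 - frac)
        leaf = split.new_child()
        leaf.taxon = taxa.get_taxon(labels[i])
        leaf.edge.length = rng.uniform(0.1, 1.0)
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            d[i, j] = d[j, i] = pdm.distance(
                taxa.get_taxon(labels[i]), taxa.get_taxon(labels[j])
            )
    return tree, labels, d


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=tree_a.as_string(schema="newick"),
                          schema="newick", taxon_namespace=tns,
                          preserve_underscores=True)
    b = dendropy.Tree.get(data=tree_b.as_string(schema="newick"),
                          schema="newick", taxon_namespace=tns,
                          preserve_underscores=True)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)


class TestNeighborJoining:
    def test_three_taxa_three_point_branch_lengths(self):
        # d(AB)=3, d(AC)=5, d(BC)=6 -> a=1, b=2, c=4
        d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        tree = nj_tree(d, ["A", "B", "C"])
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in tree.tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(4.0)

    def test_four_taxon_split_recovered(self):
        # additive matrix with ((A,B),(C,D)) structure
        d = np.array(
            [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]], float
        )
        tree = nj_tree(d, ["A", "B", "C", "D"])
        truth = dendropy.Tree.get(
            data="((A:1,B:1):2.5,(C:1,D:1):2.5);", schema="newick"
        )
        assert rf_distance(tree.tree, truth) == 0

    def test_additive_matrix_topology_recovery(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            truth, labels, d = random_additive_tree(n, rng)
            tree = nj_tree(d, labels)
            assert rf_distance(tree.tree, truth) == 0

    def test_infer_tree_requires_three_sequences(self):
        aln = Alignment(["a", "b"], ["MKVL", "MKIL"])
        with pytest.raises(ValidationError):
            infer_tree(aln)

    def test_zero_shared_columns_fallback(self, caplog):
        aln = Alignment(
            ["a", "b", "c"],
            ["AAAA----", "----CCCC", "AAAACCCC"],
        )
        d = p_distance_matrix(aln)
        assert d[0, 1] == pytest.approx(d.max())
        assert d[0, 1] > max(d[0, 2], d[1, 2])

    def test_p_distance_values(self):
        aln = Alignment(["a", "b"], ["MKVLW", "MKILW"])
        d = p_distance_matrix(aln)
        assert d[0, 1] == pytest.approx(1 / 5)

    @pytest.mark.skipif(shutil.which("fasttree") is None and
                        shutil.which("FastTree") is None,
                        reason="fasttree not installed")
    def test_fasttree_adapter_preserves_leaves(self):
        rng = np.random.default_rng(3)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        base = list("".join(rng.choice(list(aas), 120)))
        recs = []
        for i in range(5):
            s = base.copy()
            for pos in rng.integers(0, len(s), size=12):
                s[pos] = aas[rng.integers(20)]
            recs.append(rec(f"s{i}_coexp" if i < 2 else f"s{i}", "".join(s)))
        aln = align_ocg(recs)
        tree = infer_tree(aln, method="fasttree")
        assert tree.leaf_names == {r.seq_id for r in recs}


class TestNewick:
    def test_four_leaf_parse(self):
        t = PhyloTree.from_newick("(A:1,B:1,(C:1,D:1):1);")
        assert t.leaf_names == {"A", "B", "C", "D"}

    def test_round_trip_preserves_topology_lengths_and_coexp_suffix(self, tmp_path):
        rng = np.random.default_rng(4)
        truth, labels, d = random_additive_tree(6, rng)
        labels_tagged = [f"{l}_coexp" if i % 2 else l for i, l in enumerate(labels)]
        tree = nj_tree(d, labels_tagged)
        path = tmp_path / "0000.tree"
        write_newick(tree, path)
        back = parse_newick(path)
        assert back.leaf_names == set(labels_tagged)
        assert rf_distance(tree.tree, back.tree) == 0
        orig = {l.taxon.label: l.edge.length for l in tree.tree.leaf_node_iter()}
        rt = {l.taxon.label: l.edge.length for l in back.tree.leaf_node_iter()}
        for k in orig:
            assert rt[k] == pytest.approx(orig[k], abs=1e-9)

    def test_unbalanced_parentheses_rejected(self):
        from ocgkit.config_io import ParseError

        with pytest.raises(ParseError):
            PhyloTree.from_newick("((A:1,B:1;")
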