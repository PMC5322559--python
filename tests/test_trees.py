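"""Distance matrices, neighbor joining, and clade-enrichment scanning."""
from __future__ import annotations

import math

import dendropy
import numpy as np
import pytest
from scipy import stats

from selmap.phylostats import (DistanceMatrix, clade_enrichment_scan,
                               neighbor_joining, patristic_distances,
                               protein_distances, read_newick,
                               read_phylip_distances, write_newick,
                               write_phylip_distances)
from selmap.simulate import simulate_tree


def dm(ids, rows):
    return DistanceMatrix(ids=tuple(ids), values=np.array(rows, dtype=float))


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            dm("AB", [[0, 1], [2, 0]])

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            dm("AB", [[0.1, 1], [1, 0]])

    def test_phylip_round_trip(self, tmp_path):
        m = dm(["Alpha", "Beta", "Gamma"], [[0, 1.5, 2.25], [1.5, 0, 3], [2.25, 3, 0]])
        p = tmp_path / "d.phy"
        write_phylip_distances(m, p)
        back = read_phylip_distances(p)
        assert back.ids == m.ids
        np.testing.assert_allclose(back.values, m.values, atol=1e-6)


class TestProteinDistances:
    def test_identical_sequences_distance_zero(self):
        m = protein_distances([("a", "ACDEF"), ("b", "ACDEF")])
        assert m.get("a", "b") == 0.0

    def test_poisson_closed_form(self):
        # 1 mismatch over 10 compared columns: p = 0.1, d = -ln 0.9
        m = protein_distances([("a", "AAAAAAAAAA"), ("b", "AAAAAAAAAC")])
        assert m.get("a", "b") == pytest.approx(-math.log(0.9))
        assert -math.log(0.9) == pytest.approx(0.10536, abs=1e-5)

    def test_gaps_excluded_pairwise(self):
        # column 1 gapped in b -> 4 compared columns, 2 mismatches
        m = protein_distances([("a", "ACDEF"), ("b", "-CDAA")], model="p")
        assert m.get("a", "b") == pytest.approx(2 / 4)

    def test_no_comparable_columns_named(self):
        with pytest.raises(ValueError, match="'a' and 'b'"):
            protein_distances([("a", "AC--"), ("b", "--AC")])

    def test_saturated_pair_capped(self):
        m = protein_distances([("a", "AAAA"), ("b", "CCCC")], max_distance=7.5)
        assert m.get("a", "b") == 7.5

    def test_matches_per_pair_manual_count(self, rng):
        alpha = np.array(list("ACDEF-"))
        seqs = ["".join(rng.choice(alpha, size=30)) for _ in range(5)]
        recs = [(f"s{i}", s) for i, s in enumerate(seqs)]
        m = protein_distances(recs, model="p")
        for i in range(5):
            for j in range(i + 1, 5):
                comp = [(x, y) for x, y in zip(seqs[i], seqs[j])
                        if x != "-" and y != "-"]
                p = sum(x != y for x, y in comp) / len(comp)
                assert m.get(f"s{i}", f"s{j}") == pytest.approx(p)


def leaf_path_length(tree: dendropy.Tree, a: str, b: str) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return pdm.patristic_distance(taxa[a], taxa[b])


class TestNeighborJoining:
    def test_two_taxa_edge_length(self):
        tree = neighbor_joining(dm("AB", [[0, 7], [7, 0]]))
        assert leaf_path_length(tree, "A", "B") == pytest.approx(7.0)

    def test_three_taxon_closed_form(self):
        tree = neighbor_joining(dm("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]]))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_newick_round_trip_six_decimals(self):
        tree = neighbor_joining(dm("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]]))
        text = write_newick(tree)
        back = read_newick(text)
        assert sorted(lf.taxon.label for lf in back.leaf_node_iter()) == ["A", "B", "C"]
        for a, b in (("A", "B"), ("A", "C"), ("B", "C")):
            assert leaf_path_length(back, a, b) == pytest.approx(
                leaf_path_length(tree, a, b), abs=1e-6)

    @pytest.mark.parametrize("n_taxa", [5, 8])
    def test_additive_matrix_recovery(self, n_taxa, rng):
        """NJ must reproduce topology and all path lengths of the generating
        tree for additive (tree-metric) input."""
        for rep in range(5):
            true_tree = simulate_tree(n_taxa, rng)
            true_dm = patristic_distances(true_tree)
            nj_tree = neighbor_joining(true_dm)
            nj_dm = patristic_distances(nj_tree)
            assert nj_dm.ids == true_dm.ids
            np.testing.assert_allclose(nj_dm.values, true_dm.values, atol=1e-9)

    def test_taxon_permutation_invariance(self, rng):
        true_tree = simulate_tree(7, rng)
        d0 = patristic_distances(true_tree)
        perm = rng.permutation(len(d0.ids))
        d1 = DistanceMatrix(ids=tuple(d0.ids[i] for i in perm),
                            values=d0.values[np.ix_(perm, perm)])
        t0, t1 = neighbor_joining(d0), neighbor_joining(d1)
        p0, p1 = patristic_distances(t0), patristic_distances(t1)
        assert p0.ids == p1.ids
        np.testing.assert_allclose(p0.values, p1.values, atol=1e-9)


def exhaustive_best_clade(tree, labels):
    """Independent oracle: enumerate bipartition sides via dendropy and
    score with scipy's Fisher exact."""
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    total_pos = sum(labels[l] for l in leaves)
    sides = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) == len(leaves):
            continue
        for side in (below, frozenset(leaves) - below):
            if len(side) >= 2:
                sides.add(side)
    best = None
    for side in sides:
        ip = sum(labels[l] for l in side)
        inn = len(side) - ip
        _o, p = stats.fisher_exact(
            [[ip, inn], [total_pos - ip, len(leaves) - len(side) - (total_pos - ip)]],
            alternative="greater")
        key = (p, -ip, "|".join(sorted(side)))
        if best is None or key < best[0]:
            best = (key, side, p)
    return best[1], best[2]


class TestCladeEnrichmentScan:
    def planted_tree(self):
        newick = "(((p1:1,p2:1):1,(p3:1,(p4:1,p5:1):1):1):2," \
                 "((n1:1,n2:1):1,(n3:1,n4:1):1):1,((n5:1,n6:1):1,((n7:1,n8:1):1,(n9:1,n10:1):1):1):1);"
        return read_newick(newick)

    def test_planted_all_positive_clade_wins(self):
        tree = self.planted_tree()
        labels = {f"p{i}": True for i in range(1, 6)}
        labels.update({f"n{i}": False for i in range(1, 11)})
        result = clade_enrichment_scan(tree, labels)
        assert set(result.best.leaves) == {"p1", "p2", "p3", "p4", "p5"}
        assert result.best.inside_pos == 5 and result.best.inside_neg == 0
        # p = 1 / C(15,5)
        assert result.best.p == pytest.approx(1 / math.comb(15, 5))
        assert not result.uninformative

    def test_all_same_label_uninformative(self):
        tree = self.planted_tree()
        labels = {lf.taxon.label: True for lf in tree.leaf_node_iter()}
        result = clade_enrichment_scan(tree, labels)
        assert result.uninformative and all(e.p == 1.0 for e in result.ranking)

    def test_unlabeled_leaf_rejected(self):
        tree = self.planted_tree()
        with pytest.raises(KeyError, match="unlabeled"):
            clade_enrichment_scan(tree, {"p1": True})

    def test_random_labels_match_exhaustive_scan(self, rng):
        for n_leaves in (8, 12):
            for _ in range(5):
                tree = simulate_tree(n_leaves, rng)
                leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
                labels = {l: bool(rng.random() < 0.5) for l in leaves}
                if len(set(labels.values())) < 2:
                    labels[leaves[0]] = not labels[leaves[0]]
                result = clade_enrichment_scan(tree, labels)
                _side, p = exhaustive_best_clade(tree, labels)
                assert result.best.p == pytest.approx(p, abs=1e-12)
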