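"""Distance trees, bootstrap, reconciliation and gain/loss accounting."""

import math

import numpy as np
import pytest
from skbio import TreeNode
from skbio.tree import nj as skbio_nj
from skbio import DistanceMatrix as SkbioDM

from gstfam import io_formats, phylo
from gstfam.phylo import (
    DistanceMatrix,
    build_nj_tree,
    bootstrap_support,
    gainloss_from_counts,
    infer_gain_loss,
    protein_distance,
    reconcile_species_overlap,
)
from gstfam.synthetic_data import simulate_family


class TestProteinDistance:
    def test_identical_zero(self):
        assert protein_distance("MKV", "MKV", "p") == 0
        assert protein_distance("MKV", "MKV", "poisson") == 0

    def test_poisson_closed_form(self):
        a = "A" * 10
        b = "A" * 9 + "C"
        assert protein_distance(a, b, "poisson") == pytest.approx(-math.log(0.9))

    def test_symmetry(self):
        assert protein_distance("MKVA", "MRVA") == protein_distance("MRVA", "MKVA")

    def test_dual_gap_columns_dropped(self):
        assert protein_distance("MK-V", "MK-A", "p") == pytest.approx(1 / 3)

    def test_saturation(self):
        with pytest.raises(ValueError):
            protein_distance("AAAA", "CCCC", "poisson")


def _additive_matrix():
    # ((a:1,b:2):1,(c:3,d:4):1); path distances
    labels = ["a", "b", "c", "d"]
    m = np.array(
        [[0, 3, 6, 7], [3, 0, 7, 8], [6, 7, 0, 7], [7, 8, 7, 0]], dtype=float
    )
    return DistanceMatrix(labels, m)


class TestNeighborJoining:
    def test_additive_recovery(self):
        tree = build_nj_tree(_additive_matrix(), root="none")
        # the generating topology pairs (a,b) and (c,d)
        ab = tree.lca([tree.find("a"), tree.find("b")])
        assert {x.name for x in ab.tips()} == {"a", "b"}
        # branch lengths recovered exactly for an additive matrix
        dist = tree.find("a").distance(tree.find("b"))
        assert dist == pytest.approx(3.0)
        assert tree.find("c").distance(tree.find("d")) == pytest.approx(7.0)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(0)
        labels = [f"t{i}" for i in range(8)]
        base = rng.uniform(1, 10, size=(8, 8))
        m = np.triu(base, 1)
        m = m + m.T
        mine = build_nj_tree(DistanceMatrix(labels, m), root="none")
        ref = skbio_nj(SkbioDM(m, labels))
        assert mine.compare_rfd(ref) == 0

    def test_star_matrix_deterministic(self):
        labels = ["a", "b", "c", "d"]
        m = np.ones((4, 4)) - np.eye(4)
        t1 = build_nj_tree(DistanceMatrix(labels, m))
        t2 = build_nj_tree(DistanceMatrix(labels, m))
        assert str(t1) == str(t2)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            build_nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_asymmetric_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], m)

    def test_simulated_true_distances_recover_topology(self):
        tree, _ = simulate_family(10, 0.3, 0.1, 1.0, seed=11)
        for node in tree.traverse(include_self=True):
            if node.length is None:
                node.length = 0.0
            node.length += 0.01  # strictly positive branches -> additive metric
        labels = [leaf.name for leaf in tree.tips()]
        dm = tree.tip_tip_distances()
        mine = build_nj_tree(
            DistanceMatrix(list(dm.ids), dm.data.copy()), root="none"
        )
        assert mine.compare_rfd(tree.copy()) == 0
        assert len(labels) >= 4


class TestBootstrap:
    ROWS = [
        ("a", "AAAAAAAAAA" + "CCCCC"),
        ("b", "AAAAAAAAAA" + "CCCCG"),
        ("c", "TTTTTTTTTT" + "GGGGG"),
        ("d", "TTTTTTTTTT" + "GGGGC"),
    ]

    def test_congruent_columns_full_support(self):
        support = bootstrap_support(self.ROWS, reps=50, seed=1, model="p")
        assert support, "expected at least one internal bipartition"
        assert all(v == 100.0 for v in support.values())

    def test_same_seed_reproducible(self):
        s1 = bootstrap_support(self.ROWS, reps=30, seed=42, model="p")
        s2 = bootstrap_support(self.ROWS, reps=30, seed=42, model="p")
        assert s1 == s2

    def test_invalid_reps(self):
        with pytest.raises(ValueError):
            bootstrap_support(self.ROWS, reps=0, seed=1)

    def test_rep_counts_stable(self):
        rng = np.random.default_rng(5)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        groups = {"x": 0, "y": 0, "z": 1, "w": 1}
        cols = []
        for _ in range(120):
            base = rng.choice(alphabet, size=2)
            col = {k: base[g] for k, g in groups.items()}
            if rng.random() < 0.1:
                col[rng.choice(list(groups))] = rng.choice(alphabet)
            cols.append(col)
        rows = [(k, "".join(c[k] for c in cols)) for k in sorted(groups)]
        s100 = bootstrap_support(rows, reps=100, seed=0, model="p")
        s400 = bootstrap_support(rows, reps=400, seed=1, model="p")
        for part in s100:
            assert abs(s100[part] - s400[part]) <= 10.0


class TestReconciliation:
    def _labeled(self, text):
        return reconcile_species_overlap(io_formats.read_newick(text), ("P", "T"))

    def test_cherry_speciation(self):
        tree = self._labeled("(P|a,T|b);")
        assert tree.event == "speciation"

    def test_lineage_duplication(self):
        tree = self._labeled("((P|a,P|b),T|c);")
        inner = tree.lca([tree.find("P|a"), tree.find("P|b")])
        assert tree.event == "speciation"
        assert inner.event == "duplication_lineage"

    def test_ancestral_duplication(self):
        tree = self._labeled("((P|a,T|b),(P|c,T|d));")
        assert tree.event == "duplication_ancestral"
        for child in tree.children:
            assert child.event == "speciation"

    def test_three_species_rejected(self):
        with pytest.raises(ValueError):
            reconcile_species_overlap(
                io_formats.read_newick("((P|a,T|b),X|c);"), ("P", "T")
            )

    def test_polytomy_resolved_with_warning(self, caplog):
        tree = io_formats.read_newick("(P|a,P|b,T|c);")
        labeled = reconcile_species_overlap(tree, ("P", "T"))
        assert all(
            len(n.children) == 2 for n in labeled.non_tips(include_self=True)
        )


class TestGainLoss:
    def _summary(self, text):
        tree = reconcile_species_overlap(io_formats.read_newick(text), ("P", "T"))
        return infer_gain_loss(tree, ("P", "T"))

    def test_two_complete_units(self):
        s = self._summary("((P|a,T|b),(P|c,T|d));")
        assert s.mrca_units == 2
        assert s.gains == {"P": 0, "T": 0}
        assert s.losses == {"P": 0, "T": 0}
        assert s.extant == {"P": 2, "T": 2}

    def test_unit_lost_in_tomato(self):
        s = self._summary("((P|a,T|b),P|c);")
        assert s.mrca_units == 2
        assert s.losses == {"P": 0, "T": 1}
        assert s.extant == {"P": 2, "T": 1}

    def test_lineage_gain(self):
        s = self._summary("((P|a,P|b),T|c);")
        assert s.mrca_units == 1
        assert s.gains == {"P": 1, "T": 0}
        assert s.extant == {"P": 2, "T": 1}
        assert s.extant["P"] == s.mrca_units - s.losses["P"] + s.gains["P"]

    def test_identity_on_random_trees(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            labels = [
                f"{rng.choice(['P', 'T'])}|g{i}" for i in range(rng.integers(2, 12))
            ]
            tree = _random_tree(labels, rng)
            labeled = reconcile_species_overlap(tree, ("P", "T"))
            s = infer_gain_loss(labeled, ("P", "T"))  # raises if identity broken
            total_leaves = sum(s.extant.values())
            assert total_leaves == len(labels)

    def test_unit_partition_property(self):
        tree = reconcile_species_overlap(
            io_formats.read_newick("(((P|a,T|b),(P|c,P|d)),((T|e,T|f),P|g));"),
            ("P", "T"),
        )
        s = infer_gain_loss(tree, ("P", "T"))
        assert sum(s.extant.values()) == 7
        assert s.extant["P"] == s.mrca_units - s.losses["P"] + s.gains["P"]
        assert s.extant["T"] == s.mrca_units - s.losses["T"] + s.gains["T"]


def _random_tree(labels, rng):
    nodes = [TreeNode(name=lab, length=1.0) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=1.0)
        parent.extend([a, b])
        nodes.append(parent)
    return nodes[0]


class TestGainLossFromCounts:
    def test_pepper_tau(self):
        assert gainloss_from_counts(mrca=55, losses=13, extant=59)["gains"] == 17

    def test_tomato_tau(self):
        assert gainloss_from_counts(mrca=55, losses=11, extant=57)["gains"] == 13

    def test_phi_extant(self):
        assert gainloss_from_counts(mrca=7, losses=1, gains=0)["extant"] == 6

    def test_negative_solution_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            gainloss_from_counts(mrca=10, losses=0, extant=5, gains=None)

    def test_exactly_one_unknown(self):
        with pytest.raises(ValueError):
            gainloss_from_counts(mrca=1, losses=1)
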