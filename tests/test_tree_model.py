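import math

import numpy as np
import pandas as pd
import pytest

from dloopkin.io_formats import SequenceRecord
from dloopkin.synthetic_data import random_binary_tree
from dloopkin.tree_model import (
    NewickParseError,
    SaturationError,
    assign_haplogroups,
    k2p_distance,
    k2p_distance_matrix,
    nj_tree,
    parse_newick,
    root_with_outgroup,
    tip_labels,
    write_newick,
)

from conftest import leaf_distances


def unrooted_splits(tree):
    """Non-trivial splits of the unrooted topology as frozensets of the
    smaller side's labels."""
    tips = frozenset(tip_labels(tree))
    splits = set()
    for node in tree.postorder_internal_node_iter():
        below = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        for side in (below, tips - below):
            if 1 < len(side) < len(tips) - 1:
                splits.add(min(side, tips - side, key=sorted))
    return splits


class TestNewick:
    def test_three_tip_topology(self):
        t = parse_newick("((A,B),C);")
        assert sorted(tip_labels(t)) == ["A", "B", "C"]
        assert len(t.seed_node.child_nodes()) == 2

    def test_branch_lengths_stored(self):
        t = parse_newick("(A:1,B:2):0;")
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in t.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 2.0}

    def test_polytomy_preserved(self):
        t = parse_newick("((A,B,C),D);")
        inner = [n for n in t.preorder_internal_node_iter() if n.parent_node]
        assert len(inner[0].child_nodes()) == 3

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A,B),C;")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(NewickParseError, match="duplicate"):
            parse_newick("((A,A),C);")

    def test_missing_semicolon_rejected(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A,B),C)")

    def test_round_trip_preserves_topology_and_lengths(self):
        text = "((A:1.5,B:2.25):0.5,(C:3.0,D:0.75):1.0);"
        t1 = parse_newick(text)
        t2 = parse_newick(write_newick(t1))
        assert unrooted_splits(t1) == unrooted_splits(t2)
        assert leaf_distances(t1) == pytest.approx(leaf_distances(t2))


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_two_transitions(self):
        # 8 sites, 2 transitions, 0 transversions: P=0.25, Q=0
        d = k2p_distance("AAAAAAAA", "GGAAAAAA")
        assert d == pytest.approx(0.5 * math.log(2), abs=1e-10)
        assert round(d, 4) == 0.3466

    def test_saturation_error(self):
        # P = Q = 0.25 -> 1-2P-Q = 0.25 but choose P=0.375,Q=0.25 -> <= 0
        with pytest.raises(SaturationError):
            k2p_distance("AAAAAAAA", "GGGCCAAA")  # P=3/8, Q=2/8

    def test_pairwise_deletion(self):
        assert k2p_distance("ACGTN-", "ACGAAA") == k2p_distance("ACGT", "ACGA")

    def test_min_shared_sites_enforced(self):
        with pytest.raises(ValueError, match="shared"):
            k2p_distance("ANNN", "AAAA", min_shared=2)

    @pytest.mark.parametrize("n_diff", [1, 2])
    def test_first_order_agreement_with_p_distance(self, n_diff):
        # k2p -> p as p -> 0 (within 1e-3 for p <= 0.01)
        L = 400
        s1 = "A" * L
        s2 = "G" * n_diff + "A" * (L - n_diff)
        p = n_diff / L
        assert k2p_distance(s1, s2) == pytest.approx(p, abs=1e-3)
        assert k2p_distance(s1, s2) >= p  # correction never shrinks


class TestNJ:
    def test_additive_four_taxon_split_recovered(self):
        # tree ((A:1,B:1):1,(C:1,D:1):1) -> distances AB=2, CD=2, cross=4
        d = pd.DataFrame(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
            index=list("ABCD"),
            columns=list("ABCD"),
            dtype=float,
        )
        t = nj_tree(d)
        assert frozenset("AB") in unrooted_splits(t)
        # four-point condition oracle: AB|CD is the tight pairing
        assert d.at["A", "B"] + d.at["C", "D"] < d.at["A", "C"] + d.at["B", "D"]

    def test_three_taxon_unique_topology(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        t = nj_tree(d, labels=list("ABC"))
        assert sorted(tip_labels(t)) == ["A", "B", "C"]

    def test_tie_determinism(self):
        d = np.ones((4, 4)) - np.eye(4)
        t1 = write_newick(nj_tree(d))
        t2 = write_newick(nj_tree(d))
        assert t1 == t2

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(d)

    @pytest.mark.parametrize("seed", range(8))
    def test_recovers_random_additive_trees(self, seed):
        """Exhaustive split comparison on random binary trees, n <= 8."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        true = random_binary_tree(n, seed=seed)
        for edge in true.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                edge.length = float(rng.uniform(0.5, 2.0))
        dists = leaf_distances(true)
        labels = sorted(tip_labels(true))
        d = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    d[i, j] = d[j, i] = dists[(a, b)]
        rec = nj_tree(d, labels=labels)
        assert unrooted_splits(rec) == unrooted_splits(true)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_scikit_bio(self, seed):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(100 + seed)
        n = 6
        true = random_binary_tree(n, seed=300 + seed)
        for edge in true.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                edge.length = float(rng.uniform(0.5, 2.0))
        dists = leaf_distances(true)
        labels = sorted(tip_labels(true))
        d = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    d[i, j] = d[j, i] = dists[(a, b)]
        ours = nj_tree(d, labels=labels)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        their_splits = set()
        tips = frozenset(labels)
        for node in theirs.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < n - 1:
                their_splits.add(min(below, tips - below, key=sorted))
        assert unrooted_splits(ours) == their_splits


class TestRooting:
    def test_outgroup_becomes_sister_to_rest(self):
        t = root_with_outgroup(parse_newick("((A,B),(C,O));"), ["O"])
        kids = t.seed_node.child_nodes()
        sides = [
            frozenset(l.taxon.label for l in k.leaf_iter()) for k in kids
        ]
        assert frozenset(["O"]) in sides

    def test_already_rooted_is_idempotent(self):
        t1 = root_with_outgroup(parse_newick("((A,B),(C,O));"), ["O"])
        t2 = root_with_outgroup(t1, ["O"])
        assert unrooted_splits(t1) == unrooted_splits(t2)
        sides = [
            frozenset(l.taxon.label for l in k.leaf_iter())
            for k in t2.seed_node.child_nodes()
        ]
        assert frozenset(["O"]) in sides

    def test_scattered_outgroup_rejected(self):
        with pytest.raises(ValueError, match="monophyletic"):
            root_with_outgroup(parse_newick("((O1,A),(O2,B));"), ["O1", "O2"])

    def test_branch_length_split_evenly(self):
        t = root_with_outgroup(parse_newick("((A:1,B:1):1,(C:1,O:4):1);"), ["O"])
        kids = {
            frozenset(l.taxon.label for l in k.leaf_iter()): k.edge.length
            for k in t.seed_node.child_nodes()
        }
        assert kids[frozenset(["O"])] == pytest.approx(2.0)

    def test_patristic_distances_preserved_by_rerooting(self):
        t0 = parse_newick("((A:1,B:2):1,(C:1.5,O:4):0.5);")
        t1 = root_with_outgroup(t0, ["O"])
        assert leaf_distances(t0) == pytest.approx(leaf_distances(t1))


class TestHaplogroups:
    def test_cherry_with_reference(self):
        t = parse_newick("((Q1,refB),(refA,refC));")
        a = assign_haplogroups(t, {"refA": "A", "refB": "B", "refC": "C"})
        assert a.haplogroup["Q1"] == "B"
        assert a.support["Q1"] == "clade"

    def test_reference_assigned_to_itself(self):
        t = parse_newick("((Q1,refB),refA);")
        a = assign_haplogroups(t, {"refA": "A", "refB": "B"})
        assert a.haplogroup["refB"] == "B"
        assert a.support["refB"] == "reference"

    def test_mosaic_clade_falls_back_to_nearest(self):
        # Q1's smallest reference-containing clade holds both A and B refs;
        # refB is patristically nearer.
        t = parse_newick("((refB:1,refA:5):1,Q1:1);")
        a = assign_haplogroups(t, {"refA": "A", "refB": "B"})
        assert a.haplogroup["Q1"] == "B"
        assert a.support["Q1"] == "nearest"

    def test_topology_only_tree_errors_on_fallback(self):
        t = parse_newick("((Q1,refB),refA);")
        # force a mosaic at the first reference-containing clade
        t2 = parse_newick("(Q1,refB,refA);")
        with pytest.raises(ValueError, match="branch length"):
            assign_haplogroups(t2, {"refA": "A", "refB": "B"})

    def test_missing_references_error(self):
        t = parse_newick("((Q1,Q2),Q3);")
        with pytest.raises(KeyError):
            assign_haplogroups(t, {"refA": "A"})

    def test_assignment_depends_on_position_not_label(self):
        t1 = parse_newick("((query,refB),(refA,x));")
        t2 = parse_newick("((renamed,refB),(refA,x));")
        refs = {"refA": "A", "refB": "B"}
        a1 = assign_haplogroups(t1, refs)
        a2 = assign_haplogroups(t2, refs)
        assert a1.haplogroup["query"] == a2.haplogroup["renamed"]


def test_k2p_matrix_symmetric_zero_diagonal():
    recs = [
        SequenceRecord(id=f"s{i}", sequence=s)
        for i, s in enumerate(["ACGTACGT" * 10, "ACGAACGT" * 10, "ACGTACTT" * 10])
    ]
    m = k2p_distance_matrix(recs, min_shared=10)
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 0)
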