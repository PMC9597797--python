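import itertools

import numpy as np
import pandas as pd
import pytest

from dloopkin.kinship_core import (
    ConnectionMatrix,
    breed_profile,
    connection_matrix,
    find_type1_pairs,
    find_type2_triples,
    profile_distance_matrix,
)
from dloopkin.synthetic_data import random_binary_tree
from dloopkin.tree_model import parse_newick


def oracle_type1(tree):
    """Tip-pair scan: two tips are type-1 partners iff they share a parent
    that has exactly two children."""
    tips = list(tree.leaf_node_iter())
    pairs = set()
    for a, b in itertools.combinations(tips, 2):
        p = a.parent_node
        if p is b.parent_node and len(p.child_nodes()) == 2:
            pairs.add(frozenset((a.taxon.label, b.taxon.label)))
    return pairs


def oracle_type2(tree):
    """Tip scan: tip t forms a triple iff its parent is binary and t's
    sibling is a two-tip cherry."""
    triples = set()
    for t in tree.leaf_node_iter():
        p = t.parent_node
        if p is None or len(p.child_nodes()) != 2:
            continue
        sib = next(c for c in p.child_nodes() if c is not t)
        if sib.is_leaf():
            continue
        grand = sib.child_nodes()
        if len(grand) == 2 and all(g.is_leaf() for g in grand):
            triples.add(
                (
                    t.taxon.label,
                    frozenset(g.taxon.label for g in grand),
                )
            )
    return triples


def ladderize_copy(newick, left):
    t = parse_newick(newick)
    t.ladderize(ascending=left)
    return t


class TestPatternFinding:
    def test_type1_cherries(self):
        t = parse_newick("((A1,B1),(C1,(D1,E1)));")
        assert {frozenset(p) for p in find_type1_pairs(t)} == {
            frozenset(("A1", "B1")),
            frozenset(("D1", "E1")),
        }

    def test_type1_polytomy_emits_all_pairs(self):
        t = parse_newick("(A1,B1,C1);")
        assert len(find_type1_pairs(t)) == 3

    def test_no_cherry_gives_empty(self):
        # degenerate single-tip tree: no internal node with two tip children
        assert find_type1_pairs(parse_newick("(A1);")) == []
        # pectinate tree: exactly its terminal cherry, nothing else
        t = parse_newick("(A1,(B1,(C1,D1)));")
        assert {frozenset(p) for p in find_type1_pairs(t)} == {
            frozenset(("C1", "D1"))
        }

    def test_type2_triple_and_links(self):
        t = parse_newick("((A1,B1),(C1,(D1,E1)));")
        assert find_type2_triples(t) == [("C1", "D1", "E1")]

    def test_type2_pectinate(self):
        t = parse_newick("(((A1,A2),B1),C1);")
        got = {(a, frozenset((x, y))) for a, x, y in find_type2_triples(t)}
        assert got == {("B1", frozenset(("A1", "A2")))}

    def test_type2_three_tips(self):
        t = parse_newick("((A1,B1),C1);")
        assert find_type2_triples(t) == [("C1", "A1", "B1")]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_tip_scan_oracle_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        tree = random_binary_tree(n, seed=seed)
        assert {frozenset(p) for p in find_type1_pairs(tree)} == oracle_type1(tree)
        got2 = {(a, frozenset((x, y))) for a, x, y in find_type2_triples(tree)}
        assert got2 == oracle_type2(tree)


class TestConnectionMatrix:
    BREEDS = {f"{b}{i}": b for b in "ABCDE" for i in range(1, 10)}

    def test_single_cherry_offdiagonal(self):
        t = parse_newick("((A1,B1),C1);")
        m = connection_matrix(t, self.BREEDS, kinship_type=1)
        assert m.counts.at["A", "B"] == 1
        assert m.total() == 1

    def test_within_breed_on_diagonal(self):
        t = parse_newick("((A1,A2),(B1,B2));")
        m = connection_matrix(t, self.BREEDS, kinship_type=1)
        assert m.counts.at["A", "A"] == 1
        assert m.counts.at["B", "B"] == 1

    def test_type2_sum_is_twice_triples(self):
        for seed in range(6):
            tree = random_binary_tree(40, seed=seed)
            breed_of = {f"T{i}": f"B{i % 5}" for i in range(1, 41)}
            m = connection_matrix(tree, breed_of, kinship_type=2)
            assert m.counts.to_numpy().sum() + np.trace(m.counts) == 2 * 2 * len(
                find_type2_triples(tree)
            )

    def test_type1_total_equals_cherry_count(self):
        tree = random_binary_tree(60, seed=4)
        breed_of = {f"T{i}": f"B{i % 4}" for i in range(1, 61)}
        m = connection_matrix(tree, breed_of, kinship_type=1)
        assert m.total() == len(find_type1_pairs(tree))

    def test_unresolvable_tip_errors(self):
        t = parse_newick("((A1,B1),ZZZ);")
        with pytest.raises(KeyError, match="ZZZ"):
            connection_matrix(t, self.BREEDS, kinship_type=1)

    def test_ladderize_invariance(self):
        nwk = "(((A1,B1),(C1,(D1,E1))),((A2,B2),(C2,D2)));"
        breed_of = self.BREEDS
        for ktype in (1, 2):
            m_left = connection_matrix(ladderize_copy(nwk, True), breed_of, ktype)
            m_right = connection_matrix(ladderize_copy(nwk, False), breed_of, ktype)
            pd.testing.assert_frame_equal(m_left.counts, m_right.counts)

    def test_relabeling_within_breed_invariance(self):
        nwk1 = "(((A1,B1),(C1,(D1,E1))),(A2,B2));"
        nwk2 = "(((A2,B1),(C1,(D1,E1))),(A1,B2));"  # A1 <-> A2 swapped
        for ktype in (1, 2):
            m1 = connection_matrix(parse_newick(nwk1), self.BREEDS, ktype)
            m2 = connection_matrix(parse_newick(nwk2), self.BREEDS, ktype)
            pd.testing.assert_frame_equal(m1.counts, m2.counts)

    def test_tsv_round_trip(self, tmp_path):
        t = parse_newick("((A1,B1),(C1,(D1,E1)));")
        m = connection_matrix(t, self.BREEDS, kinship_type=2)
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        back = ConnectionMatrix.from_tsv(p, kinship_type=2)
        pd.testing.assert_frame_equal(m.counts, back.counts)


def matrix_from_counts(counts, breeds):
    df = pd.DataFrame(counts, index=breeds, columns=breeds)
    return ConnectionMatrix(counts=df, kinship_type=2)


class TestBreedProfile:
    def test_single_partner_is_100_percent(self):
        m = matrix_from_counts(
            [[0, 3, 0], [3, 0, 0], [0, 0, 0]], list("XYZ")
        )
        prof = breed_profile(m, "X")
        assert prof.partners["Y"] == (3, 100.0)

    def test_retention_truncation(self):
        m = matrix_from_counts(
            [[0, 3, 1], [3, 0, 0], [1, 0, 0]], list("FXY")
        )
        prof = breed_profile(m, "F", retention_fraction=0.75)
        assert prof.retained == ["X"]
        assert prof.partners["X"] == (3, 75.0)

    def test_grouping_merges_partners(self):
        # Saidi-like focal: half its links go to an East-African group
        breeds = ["SAID", "KABA", "BUZA", "REDM", "MERI"]
        counts = np.zeros((5, 5), dtype=int)
        for j, c in [(1, 3), (2, 2), (3, 1), (4, 6)]:
            counts[0, j] = counts[j, 0] = c
        m = matrix_from_counts(counts, breeds)
        grouping = {"KABA": "EastTropAfr", "BUZA": "EastTropAfr", "REDM": "EastTropAfr"}
        prof = breed_profile(m, "SAID", grouping=grouping)
        assert prof.partners["EastTropAfr"] == (6, 50.0)

    def test_percents_sum_to_100(self):
        m = matrix_from_counts(
            [[2, 3, 1], [3, 0, 5], [1, 5, 0]], list("XYZ")
        )
        prof = breed_profile(m, "X")
        assert sum(p for _, p in prof.partners.values()) == pytest.approx(100.0)

    def test_include_self_adds_diagonal(self):
        m = matrix_from_counts(
            [[2, 2, 0], [2, 0, 1], [0, 1, 0]], list("XYZ")
        )
        assert "X" not in breed_profile(m, "X").partners
        assert breed_profile(m, "X", include_self=True).partners["X"][0] == 2


class TestProfileDistance:
    def test_identical_rows_zero(self):
        m = matrix_from_counts(
            [[0, 2, 3, 4], [2, 0, 3, 4], [3, 3, 0, 9], [4, 4, 9, 0]],
            list("WXYZ"),
        )
        d = profile_distance_matrix(m, metric="correlation")
        # W and X have identical partner profiles toward Y and Z
        assert d.at["W", "X"] == pytest.approx(0.0)

    def test_anticorrelated_rows_give_two(self):
        m = matrix_from_counts(
            [[0, 0, 1, 9], [0, 0, 9, 1], [1, 9, 0, 0], [9, 1, 0, 0]],
            list("WXYZ"),
        )
        d = profile_distance_matrix(m, metric="correlation")
        assert d.at["W", "X"] == pytest.approx(2.0)

    def test_constant_row_warns_and_gives_one(self):
        m = matrix_from_counts(
            [[0, 1, 1, 1], [1, 0, 2, 3], [1, 2, 0, 4], [1, 3, 4, 0]],
            list("WXYZ"),
        )
        with pytest.warns(UserWarning, match="constant"):
            d = profile_distance_matrix(m, metric="correlation")
        assert d.at["W", "X"] == 1.0

    def test_matches_independent_correlation(self):
        counts = [
            [0, 5, 2, 7],
            [5, 0, 3, 1],
            [2, 3, 0, 4],
            [7, 1, 4, 0],
        ]
        m = matrix_from_counts(counts, list("WXYZ"))
        d = profile_distance_matrix(m, metric="correlation")
        from scipy.stats import pearsonr

        arr = np.array(counts, dtype=float)
        for i, j in itertools.combinations(range(4), 2):
            keep = [k for k in range(4) if k not in (i, j)]
            want = 1 - pearsonr(arr[i, keep], arr[j, keep]).statistic
            assert d.iloc[i, j] == pytest.approx(want, abs=1e-12)

    def test_similarity_metric(self):
        m = matrix_from_counts(
            [[0, 4, 2], [4, 0, 1], [2, 1, 0]], list("XYZ")
        )
        d = profile_distance_matrix(m, metric="similarity")
        assert d.at["X", "Y"] == pytest.approx(0.0)
        assert d.at["Y", "Z"] == pytest.approx(0.75)
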