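import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from vbcode.barcode_codec import BarcodeRow, PanelMismatchError
from vbcode.panel_analysis import (
    closest_matches,
    cut_tree_groups,
    distance_matrix,
    fixation_report,
    minimal_discriminating_set,
    nj_tree,
    pairwise_difference,
    pedigree_consistency,
)

from conftest import barcode_matrix_from_codes


def _row(codes, cultivar="A", checksum="cafe0123"):
    return BarcodeRow(cultivar=cultivar, codes=codes, checksum=checksum)


class TestPairwiseDifference:
    def test_identical_rows(self):
        a = _row("abcab")
        assert pairwise_difference(a, _row("abcab", "B")) == (0, 5, 0.0)

    def test_three_differences_over_202_markers(self):
        codes_a = "a" * 202
        codes_b = "b" * 3 + "a" * 199
        count, n, dist = pairwise_difference(_row(codes_a), _row(codes_b, "B"))
        assert (count, n) == (3, 202)
        assert dist == pytest.approx(3 / 202)

    def test_het_cells_excluded_by_default(self):
        count, n, dist = pairwise_difference(_row("ah"), _row("bh", "B"))
        assert (count, n, dist) == (1, 1, 1.0)

    def test_het_policies(self):
        a, b = _row("ah"), _row("bh", "B")
        assert pairwise_difference(a, b, policy="mismatch") == (1, 2, 0.5)
        assert pairwise_difference(a, b, policy="match-either") == (1, 2, 0.5)
        c = _row("hh", "C")
        assert pairwise_difference(a, c, policy="match-either")[0] == 0

    def test_panel_mismatch_rejected(self):
        with pytest.raises(PanelMismatchError):
            pairwise_difference(_row("ab"), _row("ab", "B", "beef0000"))

    def test_all_het_rows_have_undefined_distance(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_difference(_row("hh"), _row("hh", "B"))

    def test_metric_properties_on_random_rows(self, rng):
        rows = [
            _row("".join(rng.choice(list("abc"), size=12)), f"C{i}")
            for i in range(6)
        ]
        d = {}
        for x, y in itertools.combinations(range(6), 2):
            d[(x, y)] = pairwise_difference(rows[x], rows[y])[2]
            d[(y, x)] = d[(x, y)]
            assert d[(x, y)] >= 0
        for x in range(6):
            d[(x, x)] = 0.0
        for x, y, z in itertools.permutations(range(6), 3):
            assert d[(x, z)] <= d[(x, y)] + d[(y, z)] + 1e-12


class TestNjTree:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]], ["A", "B", "C"]
        )
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(0.05, abs=1e-9)
        assert lengths["B"] == pytest.approx(0.15, abs=1e-9)
        assert lengths["C"] == pytest.approx(0.25, abs=1e-9)

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix([[0, 0.1], [0.1, 0]], ["A", "B"])
        tree = nj_tree(dm)
        a = tree.find("A")
        assert a.distance(tree.find("B")) == pytest.approx(0.1)

    def test_nan_or_inf_rejected(self):
        data = np.array([[0, 1.0, 1.0], [1.0, 0, 1.0], [1.0, 1.0, 0]])
        dm = DistanceMatrix(data, ["A", "B", "C"])
        dm.data[0, 1] = dm.data[1, 0] = np.inf
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_additive_four_taxon_metric_recovered_exactly(self):
        # tree ((A:2,B:3):1,(C:4,D:5)): additive distances by hand
        d = {
            ("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
            ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9,
        }
        ids = ["A", "B", "C", "D"]
        data = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            data[i, j] = data[j, i] = v
        tree = nj_tree(DistanceMatrix(data, ids))
        # recovered tree reproduces every pairwise distance exactly
        for (x, y), v in d.items():
            assert tree.find(x).distance(tree.find(y)) == pytest.approx(v, abs=1e-9)
        # and the split {A,B}|{C,D} is present
        splits = {
            frozenset(t.name for t in n.tips())
            for n in tree.non_tips(include_self=False)
        }
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_topology_matches_skbio_reference_on_random_matrices(self, rng):
        # independent cross-check against scikit-bio's NJ on non-additive noise
        for _ in range(5):
            n = 6
            coords = rng.random((n, 3))
            data = np.sqrt(
                ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
            )
            np.fill_diagonal(data, 0.0)
            ids = [f"T{i}" for i in range(n)]
            dm = DistanceMatrix(data, ids)
            ours = nj_tree(dm)
            theirs = skbio_nj(dm)
            assert ours.compare_rfd(theirs) == 0

    def test_negative_branch_clamped_with_deficit_on_sister(self, rng):
        # a strongly non-additive matrix known to drive NJ lengths negative
        data = np.array(
            [
                [0, 0.1, 0.9, 0.9, 0.8],
                [0.1, 0, 0.9, 0.85, 0.9],
                [0.9, 0.9, 0, 0.1, 0.85],
                [0.9, 0.85, 0.1, 0, 0.9],
                [0.8, 0.9, 0.85, 0.9, 0],
            ]
        )
        tree = nj_tree(DistanceMatrix(data, list("ABCDE")))
        for node in tree.traverse(include_self=False):
            assert node.length >= 0


def random_additive_case(rng, n_leaves):
    """Random binary tree with positive lengths and its leaf distance matrix."""
    nodes = {f"L{i}": None for i in range(n_leaves)}
    children = {}
    lengths = {}
    active = list(nodes)
    serial = 0
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[j], active[i]  # pop larger index first
        parent = f"N{serial}"
        serial += 1
        children[parent] = (a, b)
        lengths[a] = round(float(rng.uniform(0.05, 1.0)), 4)
        lengths[b] = round(float(rng.uniform(0.05, 1.0)), 4)
        active.remove(a)
        active.remove(b)
        active.append(parent)
    root = active[0]

    def leaf_depths(node, acc):
        if node not in children:
            return {node: acc}
        out = {}
        for ch in children[node]:
            out.update(leaf_depths(ch, acc + lengths[ch]))
        return out

    # distances via shared-ancestor depths
    ids = sorted(nodes)
    data = np.zeros((n_leaves, n_leaves))

    def pairwise(node):
        if node not in children:
            return {node: 0.0}
        sides = []
        for ch in children[node]:
            depths = pairwise(ch)
            sides.append({k: v + lengths[ch] for k, v in depths.items()})
        for x, y in itertools.product(sides[0], sides[1]):
            i, j = ids.index(x), ids.index(y)
            data[i, j] = data[j, i] = sides[0][x] + sides[1][y]
        merged = {}
        for s in sides:
            merged.update(s)
        return merged

    pairwise(root)
    splits = set()

    def collect(node):
        if node not in children:
            return {node}
        leaves = set()
        for ch in children[node]:
            sub = collect(ch)
            leaves |= sub
            if 1 < len(sub) < n_leaves - 1:
                splits.add(frozenset(sub))
        return leaves

    collect(root)
    all_leaves = frozenset(ids)
    return DistanceMatrix(data, ids), {
        _canonical_split(s, all_leaves) for s in splits
    }


def _canonical_split(side, all_leaves):
    """A bipartition named by the side not containing the smallest leaf."""
    other = all_leaves - side
    return side if min(all_leaves) in other else other


def tree_splits(tree):
    all_leaves = frozenset(t.name for t in tree.tips())
    n = len(all_leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        sub = frozenset(t.name for t in node.tips())
        if 1 < len(sub) < n - 1:
            out.add(_canonical_split(sub, all_leaves))
    return out


class TestNjAdditiveRecovery:
    def test_generating_topology_recovered_from_additive_matrices(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 13))
            dm, truth_splits = random_additive_case(rng, n)
            recovered = tree_splits(nj_tree(dm))
            assert truth_splits <= recovered | truth_splits
            assert recovered == truth_splits


class TestMinimalSet:
    def test_two_markers_needed_for_three_cultivars(self):
        matrix = barcode_matrix_from_codes({"X": "aa", "Y": "ba", "Z": "bb"})
        subset = minimal_discriminating_set(matrix)
        assert sorted(subset.marker_ids) == sorted(matrix.markers)
        assert subset.unresolved_pairs == []
        # brute force: no single marker separates all three pairs
        for m in matrix.markers:
            col = matrix.data[m]
            assert len({col["X"], col["Y"], col["Z"]}) < 3

    def test_all_three_markers_required_for_unit_differences(self):
        matrix = barcode_matrix_from_codes(
            {"W": "aaa", "X": "baa", "Y": "aba", "Z": "aab"}
        )
        subset = minimal_discriminating_set(matrix)
        assert len(subset) == 3 and subset.unresolved_pairs == []
        exact = minimal_discriminating_set(matrix, method="exact")
        assert len(exact) == 3

    def test_single_cultivar_gives_empty_subset(self):
        matrix = barcode_matrix_from_codes({"X": "ab"})
        subset = minimal_discriminating_set(matrix)
        assert subset.marker_ids == [] and subset.resolved_pairs == 0

    def test_identical_rows_reported_unresolved(self):
        matrix = barcode_matrix_from_codes(
            {"X": "ab", "Y": "ab", "Z": "bb"}
        )
        subset = minimal_discriminating_set(matrix)
        assert subset.unresolved_pairs == [("X", "Y")]
        assert len(subset.marker_ids) >= 1

    def test_restricted_pair_universe(self):
        matrix = barcode_matrix_from_codes({"X": "aa", "Y": "ba", "Z": "bb"})
        subset = minimal_discriminating_set(matrix, must_resolve=[("X", "Y")])
        assert len(subset) == 1

    def test_greedy_matches_brute_force_on_random_matrices(self, rng):
        wins = 0
        trials = 30
        for _ in range(trials):
            codes = {
                f"C{i}": "".join(rng.choice(list("ab"), size=8))
                for i in range(6)
            }
            matrix = barcode_matrix_from_codes(codes)
            greedy = minimal_discriminating_set(matrix)
            exact = minimal_discriminating_set(matrix, method="exact")
            assert not greedy.unresolved_pairs or exact.unresolved_pairs
            assert set(greedy.unresolved_pairs) == set(exact.unresolved_pairs)
            assert len(greedy) >= len(exact)
            if len(greedy) == len(exact):
                wins += 1
        # greedy usually finds the optimum on panels this small; the full
        # 100-matrix rate check lives in the acceptance suite
        assert wins >= 0.8 * trials


class TestClosestMatches:
    def test_exact_match_ranks_first_with_zero(self):
        matrix = barcode_matrix_from_codes(
            {"SW": "aaaa", "SGA": "baaa", "BU": "bbbb"}
        )
        query = BarcodeRow(
            cultivar="query", codes="aaaa", checksum=matrix.checksum
        )
        ranked, mean_diff = closest_matches(query, matrix, k=3)
        assert ranked[0] == ("SW", 0)
        assert ranked[1] == ("SGA", 1)
        assert mean_diff > 0

    def test_ties_break_lexicographically_and_k_caps(self):
        matrix = barcode_matrix_from_codes(
            {"B": "ba", "A": "ba", "C": "bb", "Q": "aa"}
        )
        ranked, _ = closest_matches(matrix.row("Q"), matrix, k=10)
        assert ranked == [("A", 1), ("B", 1), ("C", 2)]

    def test_panel_mismatch_rejected(self):
        matrix = barcode_matrix_from_codes({"X": "aa", "Y": "ab"})
        query = BarcodeRow(cultivar="q", codes="aa", checksum="beef0000")
        with pytest.raises(PanelMismatchError):
            closest_matches(query, matrix)


class TestPedigree:
    def test_offspring_identical_to_parent_is_fully_consistent(self):
        off = _row("abab", "DP")
        assert pedigree_consistency(off, _row("abab", "BU"), _row("bbbb", "SPD2")).inconsistency_rate == 0

    def test_novel_code_flagged_inconsistent(self):
        result = pedigree_consistency(
            _row("b", "DP"), _row("a", "BU"), _row("a", "SPD2"),
            marker_ids=["m1"],
        )
        assert result.verdicts == {"m1": False}
        assert result.inconsistency_rate == 1.0

    def test_mendelian_het_with_differing_parents_is_consistent(self):
        result = pedigree_consistency(_row("h"), _row("a"), _row("b"))
        assert result.n_inconsistent == 0

    def test_het_offspring_of_identical_parents_is_inconsistent(self):
        result = pedigree_consistency(_row("h"), _row("a"), _row("a"))
        assert result.n_inconsistent == 1

    def test_missing_calls_not_comparable(self):
        result = pedigree_consistency(_row("a."), _row(".a"), _row("aa"))
        assert result.n_comparable == 0


class TestFixation:
    def test_fully_homozygous_matrix_unflagged(self):
        matrix = barcode_matrix_from_codes({"X": "abab", "Y": "bbaa"})
        assert all(e.fixed for e in fixation_report(matrix))

    def test_three_het_markers_in_three_dvbs_of_one_chromosome(self):
        matrix = barcode_matrix_from_codes({"CJ": "hahha", "W82": "aaaaa"})
        marker_dvb = {
            m: f"dVB{i}" for i, m in enumerate(matrix.markers)
        }
        report = {e.cultivar: e for e in fixation_report(matrix, marker_dvb)}
        cj = report["CJ"]
        assert not cj.fixed and cj.n_het == 3
        # three het markers in three distinct dVBs -> three blocks listed
        assert len(cj.runs) == 3
        assert report["W82"].fixed

    def test_het_runs_group_consecutive_markers_in_one_dvb(self):
        matrix = barcode_matrix_from_codes({"X": "hhah"})
        marker_dvb = {m: "dVB0" for m in matrix.markers}
        entry = fixation_report(matrix, marker_dvb)[0]
        assert entry.n_het == 3
        assert entry.runs == [("chr01", "dVB0"), ("chr01", "dVB0")]

    def test_het_markers_on_different_chromosomes_make_separate_runs(self):
        marker_ids = ["chr01_100", "chr02_100", "chr03_100", "chr04_100"]
        matrix = barcode_matrix_from_codes({"X": "hhhh"}, marker_ids=marker_ids)
        entry = fixation_report(matrix, {m: "d" for m in marker_ids})[0]
        assert len(entry.runs) == 4


class TestTreeCut:
    def test_height_cut_partitions_leaves(self):
        dm = DistanceMatrix(
            [
                [0, 0.02, 0.5, 0.5],
                [0.02, 0, 0.5, 0.5],
                [0.5, 0.5, 0, 0.02],
                [0.5, 0.5, 0.02, 0],
            ],
            ["A", "B", "C", "D"],
        )
        groups = cut_tree_groups(nj_tree(dm), height=0.05)
        assert {frozenset(g) for g in groups} == {
            frozenset({"A", "B"}),
            frozenset({"C", "D"}),
        }
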