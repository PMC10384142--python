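import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import jaccard as scipy_jaccard
from scipy.spatial.distance import squareform

from indelmark import (
    MarkerValidation,
    RunConfig,
    call_alleles,
    jaccard_matrix,
    min_discriminating_set,
    score_bands,
    upgma,
    validation_summary,
)

from conftest import oracle_upgma_heights, tree_cluster_heights

ACC = ["M01", "M02", "M03", "M04", "M05", "M06"]


class TestCallAlleles:
    def test_expected_fragments_and_heterozygote(self):
        obs = {"M01": [250], "M02": [280], "M03": [250, 280], "M04": []}
        calls = call_alleles(obs, 250, 280)
        assert [calls[a].call for a in obs] == ["A", "B", "H", None]

    def test_fragment_within_tolerance_matches(self):
        calls = call_alleles({"M01": [253]}, 250, 280)
        assert calls["M01"].call == "A"

    def test_novel_alleles_lettered_in_detection_order(self):
        obs = {
            "M01": [250],
            "M02": [360],  # second novel size seen -> D? No: first is M02 -> C
            "M03": [320],
            "M04": [360],
            "M05": [321],  # within tolerance of 320 -> same class as M03
        }
        calls = call_alleles(obs, 250, 280)
        assert calls["M02"].call == "C"
        assert calls["M03"].call == "D"
        assert calls["M04"].call == "C"
        assert calls["M05"].call == "D"

    def test_threshold_is_relative_to_both_expected_sizes(self):
        # 305 is >=30 above 250 but only 25 above 280 -> not novel, ambiguous
        calls = call_alleles({"M01": [305]}, 250, 280)
        assert calls["M01"].ambiguous and calls["M01"].call is None
        calls = call_alleles({"M01": [310]}, 250, 280)
        assert calls["M01"].call == "C"

    def test_intermediate_fragment_flagged_ambiguous(self):
        calls = call_alleles({"M01": [265]}, 250, 280)
        assert calls["M01"].ambiguous

    def test_expected_sizes_too_close_rejected(self):
        with pytest.raises(ValueError, match="min_size_diff"):
            call_alleles({"M01": [250]}, 250, 258)


class TestScoreBands:
    def test_monomorphic_marker_columns(self):
        mat = pd.DataFrame({"SM001": ["A"] * 6}, index=ACC)
        bands = score_bands(mat)
        assert list(bands["SM001:A"]) == [1] * 6
        assert list(bands["SM001:B"]) == [0] * 6

    def test_balanced_marker_complementary_columns(self):
        mat = pd.DataFrame({"SM001": ["A", "A", "A", "B", "B", "B"]}, index=ACC)
        bands = score_bands(mat)
        assert list(bands["SM001:A"]) == [1, 1, 1, 0, 0, 0]
        assert list(bands["SM001:B"]) == [0, 0, 0, 1, 1, 1]

    def test_het_lights_both_columns_and_novel_gets_own(self):
        mat = pd.DataFrame({"SM001": ["H", "A", "C", None, "B", "B"]}, index=ACC)
        bands = score_bands(mat)
        assert list(bands.columns) == ["SM001:A", "SM001:B", "SM001:C"]
        assert list(bands.loc["M01"]) == [1, 1, 0]
        assert list(bands.loc["M03"]) == [0, 0, 1]
        assert list(bands.loc["M04"]) == [0, 0, 0]

    def test_ab_h_calls_reconstructable_from_bands(self):
        mat = pd.DataFrame(
            {
                "SM001": ["A", "A", "H", "B", "B", "B"],
                "SM002": ["B", "A", "A", "H", "A", None],
            },
            index=ACC,
        )
        bands = score_bands(mat)
        for marker in mat.columns:
            a, b = bands[f"{marker}:A"], bands[f"{marker}:B"]
            for acc in ACC:
                call = {(1, 0): "A", (0, 1): "B", (1, 1): "H", (0, 0): None}[
                    (a[acc], b[acc])
                ]
                assert call == mat.loc[acc, marker]

    def test_single_band_encoding(self):
        mat = pd.DataFrame({"SM001": ["A", None, "B", "H", "C", "A"]}, index=ACC)
        bands = score_bands(mat, single_band_per_marker=True)
        assert list(bands["SM001"]) == [1, 0, 1, 1, 1, 1]


class TestJaccard:
    def test_identical_and_disjoint_rows(self):
        bands = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]], index=["a", "b", "c"]
        )
        S = jaccard_matrix(bands)
        assert S.loc["a", "b"] == 1.0
        assert S.loc["a", "c"] == 0.0
        assert np.allclose(np.diag(S), 1.0)

    def test_hand_counted_example(self):
        bands = pd.DataFrame([[1, 1, 0, 1, 0], [0, 1, 0, 1, 1]], index=["a", "b"])
        # n11 = 2 (cols 2,4), n10 = 1, n01 = 1 -> 2/4
        assert jaccard_matrix(bands).loc["a", "b"] == 0.5

    def test_matches_scipy_on_random_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            X = rng.integers(0, 2, size=(5, 12))
            if np.any((X.sum(axis=1) == 0)):
                continue
            bands = pd.DataFrame(X)
            S = jaccard_matrix(bands)
            for i, j in itertools.combinations(range(5), 2):
                expected = 1 - scipy_jaccard(X[i], X[j])
                assert S.iloc[i, j] == pytest.approx(expected)

    def test_all_zero_column_changes_only_joint_absence_variant(self):
        bands = pd.DataFrame([[1, 0, 1], [0, 1, 1]], index=["a", "b"])
        padded = pd.DataFrame([[1, 0, 1, 0], [0, 1, 1, 0]], index=["a", "b"])
        assert (
            jaccard_matrix(bands).loc["a", "b"]
            == jaccard_matrix(padded).loc["a", "b"]
        )
        assert jaccard_matrix(padded, count_joint_absences=True).loc[
            "a", "b"
        ] != jaccard_matrix(bands, count_joint_absences=True).loc["a", "b"]

    def test_empty_union_is_error(self):
        bands = pd.DataFrame([[0, 0], [0, 0]], index=["a", "b"])
        with pytest.raises(ValueError, match="no .*band"):
            jaccard_matrix(bands)


def _random_distance(rng, n):
    condensed = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
    labels = [f"L{i}" for i in range(n)]
    return pd.DataFrame(squareform(condensed), index=labels, columns=labels)


class TestUpgma:
    def test_two_leaves_half_distance(self):
        D = pd.DataFrame([[0, 0.8], [0.8, 0]], index=["A", "B"], columns=["A", "B"])
        tree = upgma(D)
        assert tree.leaf_depths() == {"A": 0.4, "B": 0.4}

    def test_hand_worked_four_leaf_agglomeration(self):
        labels = list("ABCD")
        D = pd.DataFrame(
            [
                [0.0, 0.2, 0.6, 0.8],
                [0.2, 0.0, 0.5, 0.9],
                [0.6, 0.5, 0.0, 0.4],
                [0.8, 0.9, 0.4, 0.0],
            ],
            index=labels,
            columns=labels,
        )
        heights = tree_cluster_heights(upgma(D))
        # joins: {A,B}@0.1, {C,D}@0.2, root@ mean(0.6,0.8,0.5,0.9)/2 = 0.35
        assert heights[frozenset("AB")] == pytest.approx(0.1)
        assert heights[frozenset("CD")] == pytest.approx(0.2)
        assert heights[frozenset("ABCD")] == pytest.approx(0.35)

    @pytest.mark.parametrize("n", [5, 6, 7, 8])
    def test_agrees_with_naive_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            D = _random_distance(rng, n)
            tree = upgma(D)
            got = tree_cluster_heights(tree)
            want = oracle_upgma_heights(D.to_numpy(), list(D.index))
            want = {k: v for k, v in want.items() if len(k) > 1}
            assert set(got) == set(want)
            for cluster, height in want.items():
                assert got[cluster] == pytest.approx(height, abs=1e-12)

    @pytest.mark.parametrize("n", [5, 8])
    def test_cophenetic_distances_match_scipy_average_linkage(self, n):
        rng = np.random.default_rng(200 + n)
        D = _random_distance(rng, n)
        tree = upgma(D)
        heights = tree_cluster_heights(tree)
        condensed = squareform(D.to_numpy(), checks=False)
        coph = squareform(hierarchy.cophenet(hierarchy.linkage(condensed, "average")))
        labels = list(D.index)
        for i, j in itertools.combinations(range(n), 2):
            joins = [h for c, h in heights.items() if labels[i] in c and labels[j] in c]
            assert 2 * min(joins) == pytest.approx(coph[i, j])

    def test_ultrametricity(self):
        rng = np.random.default_rng(33)
        D = _random_distance(rng, 8)
        depths = upgma(D).leaf_depths().values()
        assert max(depths) - min(depths) < 1e-9

    def test_tie_break_joins_lexicographically_smallest_pair(self):
        labels = list("ABCD")
        D = pd.DataFrame(0.5, index=labels, columns=labels)
        np.fill_diagonal(D.values, 0.0)
        heights = tree_cluster_heights(upgma(D))
        assert frozenset("AB") in heights  # all pairs tie at 0.5

    def test_asymmetric_matrix_rejected(self):
        D = pd.DataFrame([[0, 1.0], [0.5, 0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError, match="symmetric"):
            upgma(D)


class TestMinDiscriminatingSet:
    def test_two_accessions_single_marker(self):
        mat = pd.DataFrame({"X": ["A", "B"], "Y": ["A", "A"]}, index=["a", "b"])
        result = min_discriminating_set(mat)
        assert result.markers == ("X",) and result.optimal

    def test_six_marker_panel_discriminates_six_accessions(self):
        # balanced markers with distinct accession partitions
        mat = pd.DataFrame(
            {
                "SM026": ["A", "A", "A", "B", "B", "B"],
                "SM034": ["A", "B", "A", "B", "A", "B"],
                "SM102": ["B", "A", "A", "A", "B", "B"],
                "SM135": ["A", "B", "B", "A", "A", "B"],
                "SM176": ["B", "B", "A", "A", "B", "A"],
                "SM182": ["A", "A", "B", "B", "A", "B"],
            },
            index=ACC,
        )
        result = min_discriminating_set(mat)
        assert result.discriminates
        profiles = {tuple(mat.loc[a]) for a in ACC}
        assert len(profiles) == 6

    def test_size_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            mat = pd.DataFrame(
                rng.choice(["A", "B"], size=(4, 5)),
                index=list("wxyz"),
                columns=[f"SM{i}" for i in range(5)],
            )
            result = min_discriminating_set(mat)
            sizes = [
                len(combo)
                for k in range(1, 6)
                for combo in itertools.combinations(mat.columns, k)
                if len({tuple(mat.loc[a, list(combo)]) for a in mat.index}) == 4
            ]
            if not sizes:
                assert result.markers is None
            else:
                assert result.markers is not None
                assert len(result.markers) == min(sizes)

    def test_indistinct_profiles_reported_impossible(self):
        mat = pd.DataFrame({"X": ["A", "A"], "Y": ["B", "B"]}, index=["a", "b"])
        result = min_discriminating_set(mat)
        assert not result.discriminates and result.markers is None

    def test_greedy_fallback_still_discriminates(self):
        rng = np.random.default_rng(17)
        mat = pd.DataFrame(
            rng.choice(["A", "B"], size=(6, 30)),
            index=ACC,
            columns=[f"SM{i:03d}" for i in range(30)],
        )
        result = min_discriminating_set(mat, exhaustive_limit=25)
        assert result.discriminates and not result.optimal
        sub = mat[list(result.markers)]
        assert len({tuple(sub.loc[a]) for a in ACC}) == 6


class TestValidationSummary:
    def test_category_counts_and_percentages(self):
        outcomes = (
            [MarkerValidation(f"P{i}", True, True) for i in range(177)]
            + [MarkerValidation(f"F{i}", False, False) for i in range(33)]
            + [MarkerValidation(f"M{i}", True, False) for i in range(21)]
        )
        summary = validation_summary(outcomes)
        assert summary.total == 231
        assert (summary.n_polymorphic, summary.n_failed, summary.n_monomorphic) == (
            177,
            33,
            21,
        )
        assert (
            summary.pct_polymorphic,
            summary.pct_failed,
            summary.pct_monomorphic,
        ) == (77, 14, 9)

    def test_all_failed(self):
        outcomes = [MarkerValidation(f"F{i}", False, False) for i in range(5)]
        s = validation_summary(outcomes)
        assert (s.pct_polymorphic, s.pct_failed, s.pct_monomorphic) == (0, 100, 0)

    def test_pattern_het_and_pairwise_counts(self):
        calls_303 = dict(zip(ACC, ["A", "A", "A", "B", "B", "B"]))
        calls_het = dict(zip(ACC, ["A", "H", "A", "B", "B", "B"]))
        calls_same56 = dict(zip(ACC, ["A", "B", "A", "B", "A", "A"]))
        outcomes = [
            MarkerValidation("S1", True, True, calls=calls_303),
            MarkerValidation("S2", True, True, calls=calls_het),
            MarkerValidation("S3", True, True, calls=calls_same56),
        ]
        s = validation_summary(outcomes)
        assert s.n_expected_pattern == 1
        assert s.n_with_het == 1
        # M01 vs M04 differ at all three markers; M01 vs M02 at two;
        # M05 vs M06 agree everywhere
        assert s.pairwise_polymorphic.loc["M01", "M04"] == 3
        assert s.pairwise_polymorphic.loc["M01", "M02"] == 2
        assert s.pairwise_polymorphic.loc["M05", "M06"] == 0

    def test_overlapping_categories_rejected(self):
        with pytest.raises(ValueError):
            MarkerValidation("X", amplified=False, polymorphic=True)
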