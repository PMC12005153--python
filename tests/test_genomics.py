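"""Marker QC, imputation, VanRaden G, distances, PCA — exact micro-oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from histgp.exceptions import DataError
from histgp.genomics import (GMatrix, MarkerMatrix, compute_grm, impute_missing,
                             mean_pairwise_distance, pca_markers,
                             qc_filter_markers, read_dosage_csv, read_hapmap)

from conftest import random_marker_matrix


def matrix_from_dosage(dosage, ids=None):
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    ids = ids or [f"I{i}" for i in range(n)]
    markers = pd.DataFrame({"chrom": 1, "pos": np.arange(1, m + 1)},
                           index=[f"M{j}" for j in range(m)])
    return MarkerMatrix(ids=np.array(ids, dtype=object), dosage=dosage,
                        markers=markers)


class TestQC:
    def test_toy_counts_by_reason(self):
        # 10 markers: 3 at MAF 0.04 (below 5%), 2 at 60% missing -> keep 5
        rng = np.random.default_rng(0)
        n = 100
        dosage = rng.binomial(2, 0.3, size=(n, 10)).astype(float)
        for j in range(3):                      # MAF 0.04
            col = np.zeros(n)
            col[: int(round(0.04 * 2 * n / 2))] = 1.0  # 4 hets -> p = 0.04
            col[:8] = 1.0
            col[8:] = 0.0
            dosage[:, j] = col
        for j in (3, 4):                        # 60% missing
            dosage[:60, j] = np.nan
            dosage[60:, j] = rng.binomial(2, 0.4, 40)
        m = matrix_from_dosage(dosage)
        out, report = qc_filter_markers(m, return_report=True)
        assert report.n_removed_maf == 3
        assert report.n_removed_missing == 2
        assert out.n_markers == 5

    def test_maf_exactly_at_threshold_is_retained(self):
        # removal rule is strictly below the threshold
        n = 100
        col = np.zeros(n)
        col[:10] = 1.0                          # p = 0.05 exactly
        dosage = np.column_stack([col, np.tile([0, 1, 2, 1], 25)])
        out = qc_filter_markers(matrix_from_dosage(dosage), maf_min=0.05)
        assert out.n_markers == 2

    def test_no_thresholds_is_identity(self):
        m = random_marker_matrix(np.random.default_rng(1), 20, 15)
        out = qc_filter_markers(m, maf_min=0.0, max_missing=1.0)
        np.testing.assert_array_equal(out.dosage, m.dosage)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        m = random_marker_matrix(rng, 50, 40)
        m.dosage[rng.random(m.dosage.shape) < 0.3] = np.nan
        once = qc_filter_markers(m)
        twice = qc_filter_markers(once)
        assert list(once.markers.index) == list(twice.markers.index)

    def test_all_removed_raises(self):
        dosage = np.zeros((10, 3))              # all monomorphic, MAF 0
        with pytest.raises(DataError):
            qc_filter_markers(matrix_from_dosage(dosage))


class TestImputation:
    def test_column_mean_fill(self):
        m = matrix_from_dosage(np.array([[0.0], [2.0], [np.nan]]))
        out = impute_missing(m)
        assert out.dosage[2, 0] == pytest.approx(1.0)

    def test_identity_without_missing(self):
        m = random_marker_matrix(np.random.default_rng(3), 10, 8)
        assert impute_missing(m) is m

    def test_means_preserved(self):
        rng = np.random.default_rng(4)
        m = random_marker_matrix(rng, 40, 30)
        observed_means = np.nanmean(m.dosage, axis=0)
        m.dosage[rng.random(m.dosage.shape) < 0.2] = np.nan
        before = np.nanmean(m.dosage, axis=0)
        after = impute_missing(m).dosage.mean(axis=0)
        np.testing.assert_allclose(before, after, atol=1e-12)

    def test_fully_missing_marker_named_in_error(self):
        dosage = np.array([[1.0, np.nan], [0.0, np.nan]])
        with pytest.raises(DataError, match="M1"):
            impute_missing(matrix_from_dosage(dosage))


class TestGRM:
    def test_two_individual_hand_computation(self):
        g = compute_grm(matrix_from_dosage([[0.0], [2.0]]))
        np.testing.assert_allclose(g.values, [[2.0, -2.0], [-2.0, 2.0]],
                                   atol=1e-12)

    def test_duplicated_individuals_share_relationship(self):
        rng = np.random.default_rng(5)
        row = rng.binomial(2, 0.4, 50).astype(float)
        other = rng.binomial(2, 0.4, 50).astype(float)
        g = compute_grm(matrix_from_dosage([row, row, other]))
        assert g.values[0, 0] == pytest.approx(g.values[1, 1])
        assert g.values[0, 1] == pytest.approx(g.values[0, 0])

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        m = random_marker_matrix(rng, 50, 200)
        g = compute_grm(m)
        p = m.dosage.mean(axis=0) / 2
        denom = 2 * np.sum(p * (1 - p))
        w = m.dosage - 2 * p
        expected = np.empty((50, 50))
        for i in range(50):
            for j in range(50):
                expected[i, j] = np.sum(w[i] * w[j]) / denom
        np.testing.assert_allclose(g.values, expected, atol=1e-10)

    def test_symmetric_and_psd(self):
        m = random_marker_matrix(np.random.default_rng(7), 40, 120)
        g = compute_grm(m)
        np.testing.assert_allclose(g.values, g.values.T, atol=1e-10)
        assert np.linalg.eigvalsh(g.values).min() >= -1e-8

    def test_monomorphic_only_raises(self):
        with pytest.raises(DataError):
            compute_grm(matrix_from_dosage(np.ones((5, 4)) * 2))

    def test_missing_dosage_rejected(self):
        with pytest.raises(DataError):
            compute_grm(matrix_from_dosage([[0.0, np.nan], [1.0, 2.0]]))


class TestDistance:
    def test_hand_computed_pair(self):
        m = matrix_from_dosage([[0.0, 0.0], [2.0, 2.0]], ids=["x", "y"])
        assert mean_pairwise_distance(m, ["x"], ["y"]) == pytest.approx(np.sqrt(8))

    def test_self_distance_zero(self):
        m = matrix_from_dosage([[1.0, 2.0]], ids=["x"])
        assert mean_pairwise_distance(m, ["x"], ["x"]) == 0.0

    def test_brute_force_average(self):
        rng = np.random.default_rng(8)
        m = random_marker_matrix(rng, 5, 3)
        a, b = list(m.ids[:2]), list(m.ids[2:])
        expected = np.mean([np.linalg.norm(m.dosage[i] - m.dosage[j])
                            for i in range(2) for j in range(2, 5)])
        assert mean_pairwise_distance(m, a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_in_sets(self):
        m = random_marker_matrix(np.random.default_rng(9), 6, 10)
        a, b = list(m.ids[:3]), list(m.ids[3:])
        assert mean_pairwise_distance(m, a, b) == pytest.approx(
            mean_pairwise_distance(m, b, a))

    def test_empty_set_rejected(self):
        m = random_marker_matrix(np.random.default_rng(10), 4, 5)
        with pytest.raises(DataError):
            mean_pairwise_distance(m, [], list(m.ids))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 9), st.integers(0, 9), st.integers(0, 9))
    def test_triangle_inequality_on_rows(self, i, j, k):
        m = random_marker_matrix(np.random.default_rng(11), 10, 12)
        ids = list(m.ids)
        dij = mean_pairwise_distance(m, [ids[i]], [ids[j]])
        djk = mean_pairwise_distance(m, [ids[j]], [ids[k]])
        dik = mean_pairwise_distance(m, [ids[i]], [ids[k]])
        assert dik <= dij + djk + 1e-9


class TestPCA:
    def test_rank_one_matrix_single_component(self):
        u = np.array([0.0, 1.0, 2.0, 1.0])
        v = np.array([1.0, 0.0, 1.0])
        m = matrix_from_dosage(np.clip(np.outer(u, v), 0, 2))
        _, var = pca_markers(m, 2)
        assert var[0] > 0.999

    def test_variance_explained_non_increasing_and_bounded(self):
        m = random_marker_matrix(np.random.default_rng(12), 30, 100)
        _, var = pca_markers(m, 10)
        assert (np.diff(var) <= 1e-12).all()
        assert var.sum() <= 1.0 + 1e-12

    def test_matches_direct_eigendecomposition(self):
        m = random_marker_matrix(np.random.default_rng(13), 30, 100)
        _, var = pca_markers(m, 5)
        x = m.dosage - m.dosage.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(x.T @ x))[::-1]
        np.testing.assert_allclose(var, evals[:5] / evals.sum(), atol=1e-8)

    def test_invalid_k_rejected(self):
        m = random_marker_matrix(np.random.default_rng(14), 5, 8)
        with pytest.raises(DataError):
            pca_markers(m, 0)


class TestIO:
    def test_dosage_csv_roundtrip(self, tmp_path):
        m = random_marker_matrix(np.random.default_rng(15), 8, 6)
        path = tmp_path / "dosage.csv"
        m.to_csv(path)
        back = read_dosage_csv(path)
        np.testing.assert_allclose(back.dosage, m.dosage)
        assert list(back.ids) == list(m.ids)

    def test_hapmap_roundtrip_with_missing(self, tmp_path):
        m = random_marker_matrix(np.random.default_rng(16), 8, 6)
        m.dosage[0, 0] = np.nan
        path = tmp_path / "geno.hmp.txt"
        m.to_hapmap(path)
        back = read_hapmap(path)
        np.testing.assert_allclose(back.dosage, m.dosage, equal_nan=True)
        assert list(back.markers.index) == list(m.markers.index)
        assert (back.markers["pos"] == m.markers["pos"]).all()

    def test_gmatrix_csv_roundtrip(self, tmp_path):
        m = random_marker_matrix(np.random.default_rng(17), 10, 40)
        g = compute_grm(m)
        path = tmp_path / "G.csv"
        g.to_csv(path)
        back = GMatrix.from_csv(path)
        np.testing.assert_allclose(back.values, g.values, atol=1e-12)
        assert list(back.ids) == list(g.ids)
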