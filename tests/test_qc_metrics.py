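"""Per-array quality metrics against hand computations and brute-force oracles."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from arrayqc import (
    QCThresholds,
    SEMatrix,
    assemble_array_qc,
    classify_quadrant,
    compute_dfarray,
    compute_lumi_outlier,
    compute_nuse,
    compute_rle,
    compute_stress,
    iqr_skew,
    quantile_normalize,
    stress_from_shifts,
)

from conftest import make_matrix


class TestStress:
    @pytest.mark.parametrize(
        "shifts, expected",
        [
            ((0.0, 0.0, 0.0, 0.0), 1.0),          # no deformation
            ((0.7, 0.7, 0.7, 0.7), 1.0),          # constant shift: not stress
            ((-2.0, -2.0, -2.0), 1.0),
            ((0.0, 0.0, 1.0, 2.0, 2.0), 2.0),     # centered |dev| median = 1
        ],
    )
    def test_hand_examples(self, shifts, expected):
        S = np.array(shifts)[:, None]
        assert stress_from_shifts(S)[0] == pytest.approx(expected)

    def test_stress_at_least_one(self):
        rng = np.random.default_rng(0)
        S = rng.normal(0, 2, (200, 8))
        assert np.all(stress_from_shifts(S) >= 1.0)

    def test_constant_raw_offset_invisible_through_quantile_norm(self):
        rng = np.random.default_rng(1)
        X = rng.normal(8, 2, (800, 6))  # tie-free continuous data
        base = compute_stress(quantile_normalize(make_matrix(X)))
        X2 = X.copy()
        X2[:, 3] += 2.5
        shifted = compute_stress(quantile_normalize(make_matrix(X2)))
        np.testing.assert_allclose(shifted, base, atol=1e-9)


def dfarray_loo_bruteforce(X, q=0.75):
    """Naive O(p*n^2) leave-one-out oracle, independent of the implementation."""
    p, n = X.shape
    grid = np.empty((p, n))
    for i in range(p):
        for j in range(n):
            rest = np.delete(X[i], j)
            sd = rest.std(ddof=1)
            num = X[i, j] - rest.mean()
            if sd == 0:
                grid[i, j] = 0.0 if abs(num) < 1e-12 else np.nan
            else:
                grid[i, j] = num / sd
    summary = np.nanquantile(np.abs(grid), q, axis=0)
    return grid, summary


class TestDfArray:
    def test_exact_loo_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            X = np.random.default_rng(seed).normal(8, 1.5, (10, 6))
            em = make_matrix(X)
            grid, summary = compute_dfarray(em, mode="exact_loo")
            grid_o, summary_o = dfarray_loo_bruteforce(X)
            np.testing.assert_allclose(grid, grid_o, rtol=1e-9)
            np.testing.assert_allclose(summary, summary_o, rtol=1e-9)

    def test_constant_feature_is_zero(self):
        X = np.vstack([np.full(5, 7.0), np.random.default_rng(0).normal(0, 1, (4, 5))])
        em = make_matrix(X)
        for mode in ("robust", "exact_loo"):
            grid, _ = compute_dfarray(em, mode=mode)
            np.testing.assert_array_equal(grid[0], 0.0)

    def test_zero_spread_guard_excludes_cell(self):
        # feature (0,0,0,0,3): robust median/MAD both 0; LOO sd for j=4 is 0
        X = np.vstack([[0.0, 0.0, 0.0, 0.0, 3.0],
                       np.random.default_rng(1).normal(0, 1, (6, 5))])
        em = make_matrix(X)
        grid_r, _ = compute_dfarray(em, mode="robust")
        assert grid_r[0, 0] == 0.0          # zero numerator at zero spread
        assert np.isnan(grid_r[0, 4])       # nonzero numerator: excluded
        grid_e, _ = compute_dfarray(em, mode="exact_loo")
        assert np.isnan(grid_e[0, 4])

    def test_robust_tracks_exact_loo_on_heterogeneous_gaussian(self, gaussian_matrix):
        em, outlier_idx = gaussian_matrix
        _, rob = compute_dfarray(em, mode="robust")
        _, loo = compute_dfarray(em, mode="exact_loo")
        assert spearmanr(rob, loo).statistic >= 0.9
        assert np.max(np.abs(rob - loo) / loo) <= 0.15
        assert int(np.argmax(rob)) == outlier_idx
        assert int(np.argmax(loo)) == outlier_idx

    def test_small_matrix_variant_agreement(self):
        rng = np.random.default_rng(1)
        scales = np.exp(rng.normal(0, 0.3, 6))
        X = rng.normal(8, 1, (50, 1)) + scales[None, :] * rng.normal(0, 0.5, (50, 6))
        em = make_matrix(X)
        _, rob = compute_dfarray(em, mode="robust")
        _, loo = compute_dfarray(em, mode="exact_loo")
        assert spearmanr(rob, loo).statistic >= 0.9

    def test_requires_three_arrays(self, tiny_matrix):
        with pytest.raises(ValueError):
            compute_dfarray(tiny_matrix, mode="exact_loo")


class TestRLE:
    def test_identical_columns_zero(self):
        col = np.array([2.0, 5.0, 3.0, 8.0])
        em = make_matrix(np.column_stack([col] * 4))
        grid, med, iqr = compute_rle(em)
        np.testing.assert_array_equal(grid, 0.0)
        np.testing.assert_array_equal(med, 0.0)

    def test_shifted_column_median_one(self):
        rng = np.random.default_rng(3)
        col = rng.normal(8, 2, 50)
        X = np.column_stack([col, col, col + 1.0, col])
        grid, med, _ = compute_rle(make_matrix(X))
        np.testing.assert_allclose(med, [0, 0, 1, 0], atol=1e-12)

    def test_row_medians_zero_by_construction(self):
        rng = np.random.default_rng(4)
        grid, _, _ = compute_rle(make_matrix(rng.normal(8, 2, (60, 7))))
        np.testing.assert_allclose(np.median(grid, axis=1), 0, atol=1e-12)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        em = make_matrix(rng.normal(8, 2, (40, 6)))
        perm = [2, 4, 0, 5, 1, 3]
        em_p = em.subset_samples([em.sample_ids[j] for j in perm])
        _, med, iqr = compute_rle(em)
        _, med_p, iqr_p = compute_rle(em_p)
        np.testing.assert_allclose(med_p, med[perm], atol=1e-12)
        np.testing.assert_allclose(iqr_p, iqr[perm], atol=1e-12)


class TestNUSE:
    def se(self, X):
        p, n = X.shape
        return SEMatrix(X, [f"f{i}" for i in range(p)], [f"s{j}" for j in range(n)])

    def test_identical_se_gives_ones(self):
        col = np.array([0.5, 1.0, 2.0])
        se = self.se(np.column_stack([col] * 4))
        grid, med, dropped = compute_nuse(se)
        np.testing.assert_allclose(grid, 1.0)
        np.testing.assert_allclose(med, 1.0)
        assert dropped == 0

    def test_uniformly_inflated_array(self):
        col = np.array([0.5, 1.0, 2.0, 0.8])
        X = np.column_stack([col, col, 1.5 * col, col])
        _, med, _ = compute_nuse(self.se(X))
        assert med[2] == pytest.approx(1.5)
        np.testing.assert_allclose(np.delete(med, 2), 1.0)

    def test_global_scale_invariance(self):
        rng = np.random.default_rng(6)
        X = np.abs(rng.normal(1, 0.3, (30, 5)))
        _, med1, _ = compute_nuse(self.se(X))
        _, med2, _ = compute_nuse(self.se(3.7 * X))
        np.testing.assert_allclose(med1, med2, rtol=1e-12)

    def test_all_zero_feature_dropped_and_counted(self):
        X = np.vstack([np.zeros(4), np.abs(np.random.default_rng(7).normal(1, 0.2, (5, 4)))])
        grid, med, dropped = compute_nuse(self.se(X))
        assert dropped == 1
        assert np.all(np.isnan(grid[0]))

    def test_reference_denominator_variant(self):
        rng = np.random.default_rng(8)
        X = np.abs(rng.normal(1, 0.2, (20, 4)))
        ref = np.median(X, axis=1)
        _, med_default, _ = compute_nuse(self.se(X))
        _, med_ref, _ = compute_nuse(self.se(X), reference=ref)
        np.testing.assert_allclose(med_default, med_ref, rtol=1e-12)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_nuse(self.se(np.zeros((4, 4))))


def lumi_distance_bruteforce(X, kind):
    """Independently coded standardization + distance oracle."""
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    Z = (X[keep] - mean[keep, None]) / sd[keep, None]
    target = np.median(Z, axis=1)
    out = []
    for j in range(X.shape[1]):
        if kind == "euclidean":
            out.append(np.linalg.norm(Z[:, j] - target))
        else:
            out.append(1 - np.corrcoef(Z[:, j], target)[0, 1])
    return np.array(out)


class TestLumiOutlier:
    @pytest.mark.parametrize("kind", ["euclidean", "one_minus_correlation"])
    def test_noisy_column_flagged_and_distances_match_oracle(self, kind):
        rng = np.random.default_rng(9)
        profile = rng.normal(8, 2, 100)
        X = profile[:, None] + rng.normal(0, 0.2, (100, 8))
        X[:, 4] = profile + rng.normal(0, 2.0, 100)  # 10x noise scale
        dist, flags = compute_lumi_outlier(make_matrix(X), kind, th=2.0)
        np.testing.assert_allclose(dist, lumi_distance_bruteforce(X, kind),
                                   rtol=1e-9)
        assert int(np.argmax(dist)) == 4
        assert flags[4] and flags.sum() == 1

    def test_feature_duplication_scales_distance_not_flags(self):
        rng = np.random.default_rng(10)
        profile = rng.normal(8, 2, 60)
        X = profile[:, None] + rng.normal(0, 0.3, (60, 6))
        X[:, 1] += rng.normal(0, 1.5, 60)
        dist, flags = compute_lumi_outlier(make_matrix(X), "euclidean")
        dist2, flags2 = compute_lumi_outlier(make_matrix(np.vstack([X, X])),
                                             "euclidean")
        np.testing.assert_allclose(dist2, np.sqrt(2) * dist, rtol=1e-9)
        np.testing.assert_array_equal(flags, flags2)

    def test_degenerate_input_rejected(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        em = make_matrix(np.column_stack([col] * 4))
        with pytest.raises(ValueError, match="positive spread"):
            compute_lumi_outlier(em)


class TestQuadrants:
    def test_symmetric_distribution_skew_half(self):
        iqr, skew = iqr_skew(np.linspace(-3, 3, 101))
        assert skew == pytest.approx(0.5)
        assert iqr == pytest.approx(3.0)

    def test_bottom_heavy_distribution_low_skew(self):
        vals = np.array([0, 0, 0, 0, 0, 0, 5, 10, 15, 20], dtype=float)
        iqr, skew = iqr_skew(vals)
        # Q1 = Q2 = 0 but Q3 = 8.75 under type-7 quantiles: skew 0
        assert skew == pytest.approx(0.0)
        assert iqr == pytest.approx(8.75)

    def test_zero_iqr_sentinel_and_r4(self):
        X = np.column_stack([np.ones(10), np.linspace(0, 9, 10)])
        em = make_matrix(X)
        iqrs, skews, quads, n_degenerate = classify_quadrant(em)
        assert np.isnan(skews[0]) and quads[0] == "R4"
        assert n_degenerate == 1

    def test_quadrant_assignment_consistent_with_cutoffs(self):
        rng = np.random.default_rng(11)
        em = make_matrix(rng.normal(8, 2, (500, 8)))
        iqrs, skews, quads, _ = classify_quadrant(em, iqr_cut=2.0, skew_cut=0.2)
        for iqr, skew, quad in zip(iqrs, skews, quads):
            expected = ("R1" if skew > 0.2 else "R2") if iqr > 2.0 else \
                       ("R3" if skew > 0.2 else "R4")
            assert quad == expected


class TestAssembly:
    def test_threshold_boundaries_inclusive(self):
        qc = assemble_array_qc(
            ["a", "b", "c"],
            QCThresholds(),
            stress=np.array([1.49, 1.5, 1.0]),
            dfarray75=np.array([1.0, 1.0, 2.0]),
        )
        assert qc[0].flags == set()
        assert qc[1].flags == {"stress_outlier"}
        assert qc[2].flags == {"dfarray_outlier"}

    def test_nuse_flagging_only_when_provided(self):
        qc = assemble_array_qc(["a", "b"], nuse_median=np.array([1.0, 1.3]))
        assert qc[1].flags == {"nuse_outlier"}
        qc2 = assemble_array_qc(["a", "b"], stress=np.array([1.0, 1.0]))
        assert all(r.nuse_median is None for r in qc2)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            assemble_array_qc(["a", "b"], stress=np.array([1.0]))


class TestThresholds:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            QCThresholds(stress_cut=0.0)
        with pytest.raises(ValueError):
            QCThresholds(dfarray_quantile=1.5)

    def test_from_yaml_and_keyvalue(self, tmp_path):
        y = tmp_path / "t.yaml"
        y.write_text("stress_cut: 1.8\ndfarray_cut: 2.5\n")
        t = QCThresholds.from_file(y)
        assert t.stress_cut == 1.8 and t.dfarray_cut == 2.5
        k = tmp_path / "t.cfg"
        k.write_text("stress_cut = 1.6\n# comment\nlumi_th = 3\n")
        t2 = QCThresholds.from_file(k)
        assert t2.stress_cut == 1.6 and t2.lumi_th == 3.0

    def test_unknown_key_rejected(self, tmp_path):
        f = tmp_path / "t.yaml"
        f.write_text("bogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            QCThresholds.from_file(f)
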