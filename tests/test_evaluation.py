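"""Metrics, effect sizes with covariate correction, and EM label subdivision."""

import numpy as np
import pandas as pd
import pytest

from drseg.evaluation import (
    GroupStudyTable,
    cohens_d,
    covariate_correct,
    em_subdivide,
    hard_dice,
    soft_volume,
    surface_distance_95,
)
from drseg.volumes import IntensityVolume, LabelVolume


def _cube(shape, lo, hi, label=1):
    data = np.zeros(shape, dtype=np.int32)
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = label
    return LabelVolume(data)


class TestDice:
    def test_identical_masks(self, rng):
        vol = LabelVolume(rng.integers(0, 3, (10, 10, 10)))
        assert hard_dice(vol, vol, 1) == 1.0

    def test_both_empty_is_one_disjoint_is_zero(self):
        a = _cube((10, 10, 10), (0, 0, 0), (3, 3, 3))
        b = _cube((10, 10, 10), (5, 5, 5), (8, 8, 8))
        assert hard_dice(a, b, 9) == 1.0  # label 9 absent from both
        assert hard_dice(a, b, 1) == 0.0

    def test_offset_cubes_half_overlap(self):
        a = _cube((10, 10, 10), (2, 2, 2), (4, 4, 4))
        b = _cube((10, 10, 10), (3, 2, 2), (5, 4, 4))
        assert hard_dice(a, b, 1) == pytest.approx(0.5)

    def test_symmetry(self, rng):
        a = LabelVolume(rng.integers(0, 2, (8, 8, 8)))
        b = LabelVolume(rng.integers(0, 2, (8, 8, 8)))
        assert hard_dice(a, b, 1) == hard_dice(b, a, 1)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hard_dice(_cube((8, 8, 8), (0, 0, 0), (2, 2, 2)),
                      _cube((10, 10, 10), (0, 0, 0), (2, 2, 2)), 1)


class TestSurfaceDistance:
    def test_identical_masks_zero(self):
        a = _cube((12, 12, 12), (3, 3, 3), (8, 8, 8))
        assert surface_distance_95(a, a, 1) == 0.0

    def test_single_voxels_three_apart(self):
        a = _cube((12, 12, 12), (2, 5, 5), (3, 6, 6))
        b = _cube((12, 12, 12), (5, 5, 5), (6, 6, 6))
        assert surface_distance_95(a, b, 1) == pytest.approx(3.0)

    def test_scales_linearly_with_spacing(self):
        a = _cube((12, 12, 12), (2, 5, 5), (3, 6, 6))
        b = _cube((12, 12, 12), (5, 5, 5), (6, 6, 6))
        d1 = surface_distance_95(a, b, 1, spacing=(1, 1, 1))
        d2 = surface_distance_95(a, b, 1, spacing=(2, 2, 2))
        assert d2 == pytest.approx(2 * d1)

    def test_symmetric_in_arguments(self, rng):
        a = _cube((14, 14, 14), (2, 2, 2), (7, 9, 6))
        b = _cube((14, 14, 14), (4, 3, 3), (9, 10, 9))
        assert surface_distance_95(a, b, 1) == pytest.approx(
            surface_distance_95(b, a, 1))

    def test_empty_mask_rejected(self):
        a = _cube((8, 8, 8), (1, 1, 1), (3, 3, 3))
        empty = LabelVolume(np.zeros((8, 8, 8), int))
        with pytest.raises(ValueError):
            surface_distance_95(a, empty, 1)


class TestSoftVolume:
    def test_one_hot_equals_count_times_voxel_volume(self, rng):
        lab = rng.integers(0, 3, (8, 8, 8))
        y = np.stack([(lab == c).astype(float) for c in range(3)])
        assert soft_volume(y, 1, (2, 2, 2)) == pytest.approx((lab == 1).sum() * 8.0)

    def test_uniform_half(self):
        y = np.zeros((2, 10, 1, 1))
        y[1, :, 0, 0] = 0.5
        assert soft_volume(y, 1) == pytest.approx(5.0)

    def test_bounds_under_fuzzing(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            from drseg.nn import softmax

            y = softmax(rng.normal(0, 2, (3, 6, 6, 6)))
            v = soft_volume(y, 1)
            assert 0.0 <= v <= y[0].size


def _study(volumes_c, volumes_ad, **covs):
    rows = []
    for i, v in enumerate(volumes_c):
        rows.append({"group": "C", "volume": v,
                     **{k: c[i] for k, c in covs.items()}})
    for i, v in enumerate(volumes_ad):
        rows.append({"group": "AD", "volume": v,
                     **{k: c[len(volumes_c) + i] for k, c in covs.items()}})
    return GroupStudyTable(pd.DataFrame(rows))


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d(_study([1, 2, 3], [3, 2, 1])) == pytest.approx(0.0)

    def test_hand_case_minus_three(self):
        assert cohens_d(_study([1, 2, 3], [4, 5, 6])) == pytest.approx(-3.0)

    def test_antisymmetric_under_group_swap(self):
        d1 = cohens_d(_study([1, 2, 3], [4, 5, 7]))
        d2 = cohens_d(_study([4, 5, 7], [1, 2, 3]))
        assert d1 == pytest.approx(-d2)

    def test_matches_brute_force_for_fuzzed_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            nc, na = int(rng.integers(2, 20)), int(rng.integers(2, 20))
            vc = rng.normal(10, 3, nc)
            va = rng.normal(8, 2, na)
            d = cohens_d(_study(list(vc), list(va)))
            s2 = ((nc - 1) * np.var(vc, ddof=1) + (na - 1) * np.var(va, ddof=1)) / (
                nc + na - 2)
            assert d == pytest.approx((vc.mean() - va.mean()) / np.sqrt(s2))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(_study([1.0], [2.0, 3.0]))
        with pytest.raises(ValueError):
            cohens_d(_study([1.0, 1.0], [1.0, 1.0]))


class TestCovariateCorrect:
    def test_constant_covariates_leave_volumes_unchanged(self):
        # a constant covariate carries no information: the fit reduces to the
        # grand mean and corrected volumes equal the originals
        study = _study([5.0, 6, 7], [8.0, 9, 10], age=[1.0] * 6)
        corrected = covariate_correct(study)
        np.testing.assert_allclose(corrected.table["volume"],
                                   study.table["volume"], atol=1e-12)

    def test_exact_linear_dependence_removed(self):
        ages = [50.0, 60, 70, 50, 60, 70]
        vols = [2 * a for a in ages]
        study = _study(vols[:3], vols[3:], age=ages)
        corrected = covariate_correct(study)
        vals = corrected.table["volume"].to_numpy()
        np.testing.assert_allclose(vals, vals[0], atol=1e-9)

    def test_residual_orthogonal_to_covariates(self):
        rng = np.random.default_rng(2)
        age = rng.normal(70, 8, 40)
        icv = rng.normal(1500, 100, 40)
        vol = 3 * age + 0.5 * icv + rng.normal(0, 5, 40)
        study = _study(list(vol[:20]), list(vol[20:]), age=list(age), icv=list(icv))
        corrected = covariate_correct(study)
        resid = corrected.table["volume"].to_numpy() - vol.mean()
        for cov in (age, icv):
            r = np.corrcoef(resid, cov)[0, 1]
            assert abs(r) < 1e-8


class TestEMSubdivide:
    def test_trivial_split_is_relabelling(self, rng):
        lab = LabelVolume(rng.integers(0, 3, (10, 10, 10)))
        scan = IntensityVolume(rng.random((10, 10, 10)))
        res = em_subdivide(scan, lab, n_sub_fg=1, n_sub_bg_range=(1, 1), rng=rng)
        merged = res.merge_by_parent()
        np.testing.assert_array_equal(merged.data, lab.data)
        assert len(set(res.parents.values())) == 3

    def test_merge_by_parent_reproduces_input(self, small_corpus):
        vol = small_corpus[0][0]
        rng = np.random.default_rng(3)
        scan = IntensityVolume(rng.normal(100, 20, vol.shape))
        res = em_subdivide(scan, vol, n_sub_fg=2, n_sub_bg_range=(3, 10), rng=rng)
        np.testing.assert_array_equal(res.merge_by_parent().data, vol.data)

    def test_two_gaussian_split_matches_threshold_oracle(self):
        rng = np.random.default_rng(4)
        lab = LabelVolume(np.ones((16, 16, 16), int))
        half = lab.data.size // 2
        vals = np.concatenate([rng.normal(50, 5, half),
                               rng.normal(200, 5, lab.data.size - half)])
        rng.shuffle(vals)
        scan = IntensityVolume(vals.reshape(lab.shape))
        res = em_subdivide(scan, lab, n_sub_fg=2, n_sub_bg_range=(1, 1), rng=rng)
        # brute-force optimal threshold oracle: midpoint sweep
        thresholds = np.linspace(vals.min(), vals.max(), 512)
        truth = scan.data > 125.0
        sub = res.labels.data.copy()
        sub_ids = sorted(set(sub[lab.data == 1].ravel()))
        assert len(sub_ids) == 2
        pred = sub == sub_ids[1] if scan.data[sub == sub_ids[1]].mean() > 125 \
            else sub == sub_ids[0]
        agreement = np.mean(pred == truth)
        assert agreement >= 0.99

    def test_agrees_with_sklearn_mixture(self):
        # independent implementation cross-check on a hard 1-D problem
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(6)
        lab = LabelVolume(np.ones((14, 14, 14), int))
        n = lab.data.size
        vals = np.concatenate([rng.normal(40, 8, n // 2), rng.normal(110, 12, n - n // 2)])
        rng.shuffle(vals)
        scan = IntensityVolume(vals.reshape(lab.shape))
        res = em_subdivide(scan, lab, n_sub_fg=2, n_sub_bg_range=(1, 1), rng=rng)
        sub = res.labels.data
        ids = sorted(set(sub.ravel()))
        ours_hi = sub == max(ids, key=lambda i: scan.data[sub == i].mean())
        gm = GaussianMixture(2, random_state=0, n_init=3).fit(vals.reshape(-1, 1))
        ref = gm.predict(scan.data.reshape(-1, 1)).reshape(lab.shape)
        ref_hi = ref == int(np.argmax(gm.means_.ravel()))
        assert np.mean(ours_hi == ref_hi) >= 0.99

    def test_log_likelihood_monotone(self):
        rng = np.random.default_rng(5)
        lab = LabelVolume(np.ones((12, 12, 12), int))
        scan = IntensityVolume(rng.normal(0, 1, lab.shape) +
                               (rng.random(lab.shape) > 0.5) * 5)
        res = em_subdivide(scan, lab, n_sub_fg=3, n_sub_bg_range=(1, 1), rng=rng)
        lls = res.log_likelihoods[1]
        assert len(lls) >= 2
        assert np.all(np.diff(lls) >= -1e-6)

    def test_too_few_voxels_rejected(self):
        lab = LabelVolume(np.zeros((4, 4, 4), int))
        lab.data[0, 0, 0] = 1
        scan = IntensityVolume(np.random.default_rng(0).random((4, 4, 4)))
        with pytest.raises(ValueError):
            em_subdivide(scan, LabelVolume(lab.data), n_sub_fg=2,
                         n_sub_bg_range=(1, 1), rng=np.random.default_rng(0))
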