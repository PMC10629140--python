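import math

import numpy as np
import pytest

import sctradiomics as s
from sctradiomics.errors import EmptyMaskError, GeometryError
from sctradiomics.iqm import IqmConfig, evaluate_iqms, records_to_frame, summarize_iqms


def _vol(arr):
    return s.ImageVolume(np.asarray(arr, float))


def _pair_on_two_voxels(a, b):
    real = np.zeros((1, 1, 2))
    syn = np.zeros((1, 1, 2))
    real[0, 0, :] = a
    syn[0, 0, :] = b
    mask = s.RoiMask(np.ones((1, 1, 2)))
    return _vol(real), _vol(syn), mask


class TestMaeRmse:
    def test_identity_is_zero(self, phantom_case):
        mask = phantom_case.masks["GTVnx"]
        assert s.mae(phantom_case.real, phantom_case.real, mask) == 0.0
        assert s.rmse(phantom_case.real, phantom_case.real, mask) == 0.0

    def test_constant_offset(self, phantom_case):
        mask = phantom_case.masks["brainstem"]
        shifted = phantom_case.real.with_values(phantom_case.real.values + 4.0)
        assert s.mae(phantom_case.real, shifted, mask) == pytest.approx(4.0)

    def test_hand_values_two_voxels(self):
        real, syn, mask = _pair_on_two_voxels([0, 0], [3, 5])
        assert s.mae(real, syn, mask) == pytest.approx(4.0)
        assert s.rmse(real, syn, mask) == pytest.approx(math.sqrt(17))

    def test_rmse_dominates_mae_and_symmetry(self, rng):
        real = _vol(rng.normal(size=(6, 6, 6)))
        syn = _vol(rng.normal(size=(6, 6, 6)))
        mask = s.RoiMask(rng.random((6, 6, 6)) < 0.5)
        assert s.rmse(real, syn, mask) >= s.mae(real, syn, mask)
        assert s.mae(real, syn, mask) == s.mae(syn, real, mask)
        assert s.rmse(real, syn, mask) == s.rmse(syn, real, mask)

    def test_empty_mask_and_grid_mismatch(self):
        real = _vol(np.zeros((4, 4, 4)))
        with pytest.raises(EmptyMaskError):
            s.mae(real, real, s.RoiMask(np.zeros((4, 4, 4))))
        with pytest.raises(GeometryError):
            s.mae(real, _vol(np.zeros((5, 5, 5))), s.RoiMask(np.ones((4, 4, 4))))


class TestPsnr:
    def test_identical_images_hit_sentinel(self):
        real, syn, mask = _pair_on_two_voxels([0, 1], [0, 1])
        assert s.psnr(real, syn, mask, IqmConfig(psnr_max=100.0)) == math.inf

    def test_hand_value_20db(self):
        # RMSE 10 with peak 100: 10 log10(100^2 / 100) = 20 dB
        real, syn, mask = _pair_on_two_voxels([0, 0], [10, 10])
        cfg = IqmConfig(psnr_max=100.0)
        assert s.psnr(real, syn, mask, cfg) == pytest.approx(20.0)

    def test_doubling_peak_adds_six_db(self):
        real, syn, mask = _pair_on_two_voxels([0, 0], [10, 10])
        lo = s.psnr(real, syn, mask, IqmConfig(psnr_max=100.0))
        hi = s.psnr(real, syn, mask, IqmConfig(psnr_max=200.0))
        assert hi - lo == pytest.approx(20 * math.log10(2))

    def test_monotone_in_mse(self, phantom_case, rng):
        mask = phantom_case.masks["GTVnx"]
        cfg = IqmConfig(psnr_max=2000.0)
        vals = []
        for sigma in (5.0, 20.0, 50.0):
            noisy = phantom_case.real.with_values(
                phantom_case.real.values + rng.normal(0, sigma, phantom_case.real.shape)
            )
            vals.append(s.psnr(phantom_case.real, noisy, mask, cfg))
        assert vals[0] > vals[1] > vals[2]


class TestSsim:
    def test_identity_is_one(self, phantom_case):
        mask = phantom_case.masks["GTVnx"]
        assert s.ssim(phantom_case.real, phantom_case.real, mask) == pytest.approx(1.0)

    def test_affine_distortion_below_one(self, phantom_case):
        mask = phantom_case.masks["GTVnx"]
        distorted = phantom_case.real.with_values(phantom_case.real.values * 1.5 + 30)
        assert s.ssim(phantom_case.real, distorted, mask) < 1.0

    def test_independent_noise_decorrelates(self, rng):
        # two unrelated noise fields: SSIM ~ 0 when averaged over >= 1e3 windows
        a = _vol(rng.normal(0, 50, (14, 14, 14)))
        b = _vol(rng.normal(0, 50, (14, 14, 14)))
        mask = s.RoiMask(np.ones((14, 14, 14)))
        cfg = IqmConfig(ssim_data_range=200.0)
        assert abs(s.ssim(a, b, mask, cfg)) < 0.1

    def test_small_roi_falls_back_to_global_window(self):
        real = _vol(np.random.default_rng(1).normal(size=(8, 8, 8)))
        syn = _vol(np.random.default_rng(2).normal(size=(8, 8, 8)))
        mask = np.zeros((8, 8, 8), bool)
        mask[4, 4, 4:6] = True  # bounding box 1x1x2 < 7^3 window
        value, fallback = s.ssim(
            real, syn, s.RoiMask(mask), IqmConfig(ssim_data_range=5.0),
            return_fallback=True,
        )
        assert fallback
        assert -1.0 <= value <= 1.0

    def test_symmetry(self, phantom_case):
        mask = phantom_case.masks["brainstem"]
        noisy = phantom_case.real.with_values(
            phantom_case.real.values
            + np.random.default_rng(3).normal(0, 30, phantom_case.real.shape)
        )
        cfg = IqmConfig(ssim_data_range=2000.0)
        assert s.ssim(phantom_case.real, noisy, mask, cfg) == pytest.approx(
            s.ssim(noisy, phantom_case.real, mask, cfg)
        )


def test_additive_noise_mae_matches_half_normal_mean(rng):
    # E|N(0, sigma^2)| = sigma * sqrt(2/pi); check within 5% at >= 1e5 voxels
    sigma = 25.0
    shape = (50, 50, 50)
    real = _vol(np.zeros(shape))
    syn = _vol(rng.normal(0, sigma, shape))
    mask = s.RoiMask(np.ones(shape))
    expected = sigma * math.sqrt(2 / math.pi)
    assert s.mae(real, syn, mask) == pytest.approx(expected, rel=0.05)


class TestEvaluateIqms:
    def test_record_cardinality(self, small_cohort):
        records = evaluate_iqms(small_cohort)
        # 3 subjects x 7 ROIs x 2 models
        assert len(records) == 3 * 7 * 2

    def test_identity_cohort_perfect_scores(self, identity_cohort):
        records = evaluate_iqms(identity_cohort)
        df = records_to_frame(records)
        assert (df["mae"] == 0).all()
        assert (df["rmse"] == 0).all()
        assert np.allclose(df["ssim"], 1.0)
        assert np.isinf(df["psnr"]).all()

    def test_cohort_mean_is_arithmetic_mean(self, small_cohort):
        records = evaluate_iqms(small_cohort)
        df = records_to_frame(records)
        summary = summarize_iqms(records)
        one = summary[
            (summary.roi == "GTVnx")
            & (summary.model == df.model.iloc[0])
            & (summary.metric == "mae")
        ]["mean"].iloc[0]
        manual = df[(df.roi == "GTVnx") & (df.model == df.model.iloc[0])]["mae"].mean()
        assert one == pytest.approx(manual)
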