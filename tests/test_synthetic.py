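import math

import numpy as np
import pytest

import sctradiomics as s
from sctradiomics.errors import GeometryError
from sctradiomics.synthetic import gtv_class_fractions


class TestGeneratePhantom:
    def test_deterministic_for_fixed_seed(self):
        spec = s.PhantomSpec()
        a = s.generate_phantom(spec, seed=42)
        b = s.generate_phantom(spec, seed=42)
        np.testing.assert_array_equal(a.real.values, b.real.values)
        for roi in a.masks:
            np.testing.assert_array_equal(a.masks[roi].values, b.masks[roi].values)

    def test_different_seeds_differ(self):
        a = s.generate_phantom(s.PhantomSpec(), seed=1)
        b = s.generate_phantom(s.PhantomSpec(), seed=2)
        assert (a.real.values != b.real.values).any()

    def test_gtv_air_fraction_near_target(self):
        spec = s.PhantomSpec()
        for seed in (0, 1, 2):
            case = s.generate_phantom(spec, seed)
            air, soft, bone = gtv_class_fractions(case, spec)
            assert 0.06 <= air <= 0.10
            assert abs(soft - 0.63) <= 0.05
            assert abs(bone - 0.29) <= 0.05

    def test_all_rois_present_inside_body(self):
        case = s.generate_phantom(s.PhantomSpec(), seed=7)
        assert set(case.masks) == {
            "body", "GTVnx", "brainstem", "parotid_l", "parotid_r",
            "temporal_lobe_l", "temporal_lobe_r",
        }
        body = case.masks["body"].values
        for roi, mask in case.masks.items():
            assert mask.n_voxels > 0
            assert np.all(body[mask.values]), roi

    def test_hu_structure_air_soft_bone(self):
        case = s.generate_phantom(s.PhantomSpec(), seed=3)
        outside = ~case.masks["body"].values
        assert case.real.values[outside].mean() < -900
        brainstem = case.real.values[case.masks["brainstem"].values]
        assert -100 < brainstem.mean() < 200

    def test_small_grid_raises_geometry_error(self):
        with pytest.raises(GeometryError):
            s.generate_phantom(s.PhantomSpec(grid=(16, 16, 16)), seed=0)


class TestDegrade:
    def test_zero_strength_is_identity(self, phantom_case):
        out = s.degrade(phantom_case.real, phantom_case.masks,
                        s.DegradationSpec("id"), seed=0)
        np.testing.assert_array_equal(out.values, phantom_case.real.values)

    def test_noise_only_mae_calibration(self):
        # larger body so the calibration sees >= 1e5 masked voxels
        spec = s.PhantomSpec(grid=(72, 72, 72), body_radii=(33.0, 32.0, 31.0))
        case = s.generate_phantom(spec, seed=11)
        sigma = 30.0
        out = s.degrade(case.real, case.masks, s.noise_only("n", sigma), seed=1)
        body = case.masks["body"]
        assert body.n_voxels >= 1e5
        observed = s.mae(case.real, out, body)
        assert observed == pytest.approx(sigma * math.sqrt(2 / math.pi), rel=0.05)

    def test_blur_contracts_masked_variance(self, phantom_case):
        out = s.degrade(phantom_case.real, phantom_case.masks,
                        s.DegradationSpec("b", blur_sigma=2.0), seed=0)
        m = phantom_case.masks["body"].values
        assert out.values[m].var() < phantom_case.real.values[m].var()

    def test_deterministic_per_seed(self, phantom_case):
        spec = s.DegradationSpec("n", noise_sigma=20.0)
        a = s.degrade(phantom_case.real, phantom_case.masks, spec, seed=9)
        b = s.degrade(phantom_case.real, phantom_case.masks, spec, seed=9)
        np.testing.assert_array_equal(a.values, b.values)


class TestGenerateCohort:
    def test_cardinality(self, small_cohort):
        assert len(small_cohort.cases) == 3
        for case in small_cohort.cases:
            assert len(case.synthetic) == 2
            assert len(case.masks) == 7

    def test_same_master_seed_identical(self):
        a = s.generate_cohort(2, master_seed=31)
        b = s.generate_cohort(2, master_seed=31)
        for ca, cb in zip(a.cases, b.cases):
            np.testing.assert_array_equal(ca.real.values, cb.real.values)
            for m in ca.synthetic:
                np.testing.assert_array_equal(
                    ca.synthetic[m].values, cb.synthetic[m].values
                )

    def test_adding_a_subject_never_perturbs_earlier_ones(self):
        a = s.generate_cohort(2, master_seed=8)
        b = s.generate_cohort(3, master_seed=8)
        for ca, cb in zip(a.cases, b.cases[:2]):
            np.testing.assert_array_equal(ca.real.values, cb.real.values)

    def test_different_master_seed_differs(self):
        a = s.generate_cohort(2, master_seed=1)
        b = s.generate_cohort(2, master_seed=2)
        assert (a.cases[0].real.values != b.cases[0].real.values).any()

    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError):
            s.generate_cohort(1)


class TestAnalyticCccFixture:
    def test_zero_noise_gives_exact_one(self):
        x, y, pop = s.analytic_ccc_fixture(100, 1.0, 0.0, seed=0)
        assert pop == 1.0
        assert s.lin_ccc(x, y) == pytest.approx(1.0)

    def test_population_value_formula(self):
        _, _, pop = s.analytic_ccc_fixture(10, 2.0, 2.0 * np.sqrt(2), seed=0)
        # sigma_e^2 = 2 sigma_x^2 -> CCC = 0.5
        assert pop == pytest.approx(0.5)

    def test_degenerate_x(self):
        x, y, pop = s.analytic_ccc_fixture(50, 0.0, 1.0, seed=0)
        assert pop == 0.0
        assert np.var(x) == 0.0
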