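import math

import numpy as np
import pytest

from melrisk.imaging_io import LesionMask, ValidationError, Volume
from melrisk.quant_features import (
    LesionFeatures,
    PEAK_SPHERE_RADIUS_MM,
    adc_mean_roi,
    apply_small_lesion_rule,
    blr,
    compute_lbm,
    lesion_diameter_axial,
    mtv_isocontour,
    patient_feature_summary,
    select_target_lesion,
    slr,
    sul_peak,
    tlg,
    to_sul,
)


def brute_force_sul_peak(pet: Volume, mask: LesionMask) -> float:
    """Exhaustive search over all mask voxels as sphere centres."""
    r = PEAK_SPHERE_RADIUS_MM
    shape = pet.shape
    sp = pet.spacing
    best = -np.inf
    idx = np.indices(shape)
    for c in np.argwhere(mask.values):
        d2 = sum(((idx[d] - c[d]) * sp[d]) ** 2 for d in range(3))
        inside = d2 <= r**2
        best = max(best, float(pet.values[inside].mean()))
    return best


def make_sphere(shape, spacing, center, radius, inner=1.0, outer=0.0):
    idx = np.indices(shape)
    r2 = sum(((idx[d] - center[d]) * spacing[d]) ** 2 for d in range(3))
    inside = r2 <= radius**2
    vals = np.where(inside, inner, outer).astype(np.float32)
    return vals, inside


class TestLBM:
    def test_male_example(self):
        # 80 kg, 1.80 m -> BMI 24.69, LBM = 9270*80/(6680+216*24.69)
        bmi = 80 / 1.80**2
        expected = 9270 * 80 / (6680 + 216 * bmi)
        assert compute_lbm("m", 80, 1.80) == pytest.approx(expected)
        assert expected == pytest.approx(61.7, abs=0.1)

    def test_female_example(self):
        bmi = 60 / 1.65**2
        expected = 9270 * 60 / (8780 + 244 * bmi)
        assert compute_lbm("f", 60, 1.65) == pytest.approx(expected)
        assert expected == pytest.approx(39.3, abs=0.1)

    def test_lbm_below_weight_over_grid(self):
        for w in np.linspace(45, 140, 12):
            for h in np.linspace(1.45, 2.05, 9):
                if w / h**2 > 12:
                    assert compute_lbm("m", w, h) < w
                    assert compute_lbm("f", w, h) < w

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            compute_lbm("m", -1, 1.8)
        with pytest.raises(ValidationError):
            compute_lbm("x", 80, 1.8)


class TestToSul:
    def test_uniform_distribution_gives_sul_one(self):
        # activity equal to dose/LBM everywhere -> SUL == 1
        dose, lbm = 316.0, 60.0
        conc = dose * 1e6 / (lbm * 1e3)
        v = Volume(np.full((4, 4, 4), conc, dtype=np.float32), (2, 2, 2), "PET_MR",
                   units="Bq/mL")
        out = to_sul(v, dose, lbm)
        np.testing.assert_allclose(out.values, 1.0, rtol=1e-6)

    def test_doubling_dose_halves_sul(self):
        v = Volume(np.full((3, 3, 3), 5000.0), (2, 2, 2), "PET_MR", units="Bq/mL")
        a = to_sul(v, 300, 60).values
        b = to_sul(v, 600, 60).values
        np.testing.assert_allclose(a, 2 * b, rtol=1e-6)

    def test_nonpositive_dose_rejected(self):
        v = Volume(np.ones((2, 2, 2)), (1, 1, 1), "PET_MR")
        with pytest.raises(ValidationError):
            to_sul(v, 0, 60)


class TestSULpeak:
    def test_uniform_lesion_gives_its_value(self):
        vals, inside = make_sphere((30, 30, 30), (1.5, 1.5, 1.5), (15, 15, 15),
                                   12.0, inner=7.0, outer=7.0)
        pet = Volume(vals, (1.5, 1.5, 1.5), "PET_MR")
        mask = LesionMask(inside, (1.5, 1.5, 1.5), "l", "liver")
        peak, fb = sul_peak(pet, mask)
        assert not fb
        assert peak == pytest.approx(7.0)

    def test_matches_brute_force_on_hot_voxel(self):
        shape, sp = (24, 24, 24), (1.5, 1.5, 1.5)
        vals = np.ones(shape, dtype=np.float32)
        vals[12, 12, 12] = 10.0
        _, inside = make_sphere(shape, sp, (12, 12, 12), 10.0)
        pet = Volume(vals, sp, "PET_MR")
        mask = LesionMask(inside, sp, "l", "bone")
        peak, _ = sul_peak(pet, mask)
        assert peak == pytest.approx(brute_force_sul_peak(pet, mask), rel=1e-6)

    def test_matches_brute_force_on_random_fields(self):
        rng = np.random.default_rng(7)
        for trial in range(3):
            shape, sp = (20, 20, 16), (2.0, 2.0, 2.5)
            vals = rng.random(shape).astype(np.float32) * 8
            _, inside = make_sphere(shape, sp, (10, 10, 8), 9.0)
            pet = Volume(vals, sp, "PET_MR")
            mask = LesionMask(inside, sp, f"l{trial}", "lung")
            peak, fb = sul_peak(pet, mask)
            assert not fb
            assert peak == pytest.approx(brute_force_sul_peak(pet, mask), rel=1e-6)

    def test_peak_bounded_by_max(self):
        rng = np.random.default_rng(3)
        vals = rng.random((16, 16, 16)).astype(np.float32) * 5
        _, inside = make_sphere((16, 16, 16), (2, 2, 2), (8, 8, 8), 8.0)
        pet = Volume(vals, (2, 2, 2), "PET_MR")
        mask = LesionMask(inside, (2, 2, 2), "l", "spleen")
        peak, _ = sul_peak(pet, mask)
        assert peak <= vals.max() + 1e-6

    def test_small_mask_falls_back_to_mean(self):
        vals = np.full((10, 10, 10), 3.0, dtype=np.float32)
        mask_arr = np.zeros((10, 10, 10), bool)
        mask_arr[5, 5, 5] = True
        pet = Volume(vals, (2, 2, 2), "PET_MR")
        mask = LesionMask(mask_arr, (2, 2, 2), "l", "brain")
        peak, fb = sul_peak(pet, mask)
        assert fb
        assert peak == pytest.approx(3.0)


class TestMTVandTLG:
    def test_uniform_sphere_matches_analytic_volume(self, sphere_phantom):
        pet, mask = sphere_phantom
        mtv_ml, submask, degen = mtv_isocontour(pet, mask)
        assert not degen
        analytic = 4.0 / 3.0 * math.pi * 10.0**3 / 1000.0  # 4.19 mL
        assert mtv_ml == pytest.approx(analytic, rel=0.05)

    def test_two_level_lesion_thresholds_at_42_percent(self):
        vals = np.zeros((10, 10, 10), dtype=np.float32)
        mask_arr = np.zeros((10, 10, 10), bool)
        mask_arr[2:8, 2:8, 2:8] = True
        vals[2:8, 2:8, 2:8] = 3.0
        vals[4:6, 4:6, 4:6] = 10.0  # threshold 4.2 keeps only these
        pet = Volume(vals, (1, 1, 1), "PET_MR")
        mask = LesionMask(mask_arr, (1, 1, 1), "l", "liver")
        mtv_ml, submask, _ = mtv_isocontour(pet, mask)
        assert submask.sum() == 8
        np.testing.assert_array_equal(submask, vals == 10.0)
        # TLG: submask uniform at 10 -> mtv * 10
        value, flag = tlg(pet, mtv_ml, submask)
        assert not flag
        assert value == pytest.approx(mtv_ml * 10.0)

    def test_fraction_zero_returns_connected_component(self):
        vals = np.ones((8, 8, 8), dtype=np.float32)
        mask_arr = np.zeros((8, 8, 8), bool)
        mask_arr[1:4, 1:4, 1:4] = True
        pet = Volume(vals, (1, 1, 1), "PET_MR")
        mask = LesionMask(mask_arr, (1, 1, 1), "l", "lung")
        _, submask, _ = mtv_isocontour(pet, mask, fraction=0.0)
        np.testing.assert_array_equal(submask, mask_arr)

    def test_monotone_in_fraction(self, sphere_phantom):
        pet, mask = sphere_phantom
        noisy = Volume(
            pet.values + np.random.default_rng(0).random(pet.shape).astype(np.float32),
            pet.spacing, "PET_MR",
        )
        last = np.inf
        for frac in (0.2, 0.42, 0.6, 0.8):
            mtv_ml, _, _ = mtv_isocontour(noisy, mask, fraction=frac)
            assert mtv_ml <= last + 1e-12
            last = mtv_ml

    def test_zero_pet_is_degenerate(self):
        pet = Volume(np.zeros((6, 6, 6)), (1, 1, 1), "PET_MR")
        mask = LesionMask(np.ones((6, 6, 6), bool), (1, 1, 1), "l", "bone")
        mtv_ml, _, degen = mtv_isocontour(pet, mask)
        assert degen and mtv_ml == 0.0

    def test_tlg_bounded_by_mtv_times_max(self, sphere_phantom):
        pet, mask = sphere_phantom
        mtv_ml, submask, _ = mtv_isocontour(pet, mask)
        value, _ = tlg(pet, mtv_ml, submask)
        assert value <= mtv_ml * pet.values[mask.values].max() + 1e-9


class TestDiameter:
    def test_sphere_diameter(self):
        _, inside = make_sphere((40, 40, 40), (1, 1, 1), (20, 20, 20), 10.0)
        mask = LesionMask(inside, (1, 1, 1), "l", "liver")
        assert lesion_diameter_axial(mask) == pytest.approx(20.0, abs=1.5)

    def test_ellipsoid_long_axis_in_plane(self):
        idx = np.indices((40, 40, 40)).astype(float)
        r2 = (
            ((idx[0] - 20) * 1.0 / 15.0) ** 2
            + ((idx[1] - 20) * 1.0 / 10.0) ** 2
            + ((idx[2] - 20) * 1.0 / 5.0) ** 2
        )
        mask = LesionMask(r2 <= 1.0, (1, 1, 1), "l", "lung")
        assert lesion_diameter_axial(mask) == pytest.approx(30.0, abs=1.5)

    def test_single_voxel_reports_one_voxel_extent(self):
        arr = np.zeros((8, 8, 8), bool)
        arr[4, 4, 4] = True
        mask = LesionMask(arr, (1.7, 1.7, 3.0), "l", "brain")
        assert lesion_diameter_axial(mask) == pytest.approx(1.7)


class TestSmallLesionRule:
    def test_sub_cm_recorded_as_5mm(self):
        out = apply_small_lesion_rule(8.0, "lung")
        assert out == {"dm_mm": 5.0, "sub_cm": True, "functional_suppressed": True}

    def test_large_lung_lesion_keeps_functional(self):
        out = apply_small_lesion_rule(12.0, "lung")
        assert out == {"dm_mm": 12.0, "sub_cm": False, "functional_suppressed": False}

    def test_brain_keeps_only_diameter(self):
        out = apply_small_lesion_rule(25.0, "brain")
        assert out["dm_mm"] == 25.0
        assert not out["sub_cm"]
        assert out["functional_suppressed"]


class TestADC:
    def test_uniform_adc(self):
        adc = Volume(np.full((10, 10, 10), 900.0), (1, 1, 1), "ADC")
        arr = np.zeros((10, 10, 10), bool)
        arr[2:8, 2:8, 4:6] = True
        mask = LesionMask(arr, (1, 1, 1), "l", "liver")
        value, flagged = adc_mean_roi(adc, mask)
        assert value == pytest.approx(900.0)

    def test_artifact_returns_missing(self):
        adc = Volume(np.full((6, 6, 6), 900.0), (1, 1, 1), "ADC")
        mask = LesionMask(np.ones((6, 6, 6), bool), (1, 1, 1), "l", "liver")
        value, flagged = adc_mean_roi(adc, mask, artifact_flag=True)
        assert value is None and flagged

    def test_erosion_removes_border_ring(self):
        adc_vals = np.full((12, 12, 3), 100.0, dtype=np.float32)
        adc_vals[3:9, 3:9, 1] = 1000.0  # core on the central slice
        arr = np.zeros((12, 12, 3), bool)
        arr[2:10, 2:10, 1] = True  # mask includes a border ring at 100
        adc = Volume(adc_vals, (1, 1, 1), "ADC")
        mask = LesionMask(arr, (1, 1, 1), "l", "liver")
        value, flagged = adc_mean_roi(adc, mask)
        assert not flagged
        assert value == pytest.approx(1000.0)

    def test_erosion_fallback_on_thin_lesion(self):
        adc = Volume(np.full((8, 8, 3), 500.0), (1, 1, 1), "ADC")
        arr = np.zeros((8, 8, 3), bool)
        arr[4, 2:6, 1] = True  # one-voxel-wide line: erosion empties it
        mask = LesionMask(arr, (1, 1, 1), "l", "bone")
        value, flagged = adc_mean_roi(adc, mask)
        assert flagged
        assert value == pytest.approx(500.0)


class TestPatientSummary:
    def _lesion(self, i, mtv=None, peak=None, dm=20.0, adc=None, region="lung"):
        return LesionFeatures(
            lesion_id=f"l{i}", organ_region=region, dm_mm=dm,
            sul_peak=peak, mtv_ml=mtv, tlg=mtv, adc_mean=adc,
        )

    def test_cap_at_200(self):
        lesions = [self._lesion(0, mtv=1.0, peak=2.0)]
        out = patient_feature_summary(lesions, n_found=250)
        assert out.n_lesions == 200

    def test_single_lesion_ranges_zero(self):
        out = patient_feature_summary(
            [self._lesion(0, mtv=2.0, peak=3.0, adc=900.0)]
        )
        assert out.dm_range == 0.0
        assert out.sul_peak_range == 0.0
        assert out.adc_mean_range == 0.0

    def test_tmtv_is_sum(self):
        lesions = [self._lesion(i, mtv=m, peak=2.0) for i, m in enumerate([1.0, 2.0, 3.0])]
        out = patient_feature_summary(lesions)
        assert out.tmtv_ml == pytest.approx(6.0, rel=1e-9)

    def test_suppressed_lesions_excluded_from_functional_aggregates(self):
        lesions = [
            self._lesion(0, mtv=2.0, peak=4.0, adc=800.0),
            LesionFeatures(lesion_id="sub", organ_region="lung", dm_mm=5.0,
                           sub_cm=True, functional_suppressed=True),
        ]
        out = patient_feature_summary(lesions)
        assert out.tmtv_ml == pytest.approx(2.0)
        assert out.sul_peak_mean == pytest.approx(4.0)
        assert out.n_lesions == 2

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            patient_feature_summary([])


class TestReferenceRatios:
    def _pet_with_organs(self, liver=2.0, spleen=2.2, vertebrae=(1, 1, 1, 1)):
        vals = np.zeros((40, 40, 60), dtype=np.float32)
        sp = (2.0, 2.0, 2.0)
        idx = np.indices((40, 40, 60)).astype(float)
        organs = {"liver": ((10, 20, 30), liver), "spleen": ((30, 20, 30), spleen)}
        vert_centers = [(20, 30, 8 + 12 * i) for i in range(4)]
        verts = list(zip(vert_centers, vertebrae))
        for (c, u) in list(organs.values()) + verts:
            r2 = sum(((idx[d] - c[d]) * sp[d]) ** 2 for d in range(3))
            vals[r2 <= 11.0**2] = u
        return Volume(vals, sp, "PET_MR"), (10, 20, 30), (30, 20, 30), vert_centers

    def test_slr_ratio_and_sweep(self):
        pet, liver_c, spleen_c, _ = self._pet_with_organs(liver=2.0, spleen=2.2)
        ratio, classes = slr(pet, liver_c, spleen_c)
        assert ratio == pytest.approx(1.1, abs=0.02)
        assert len(classes) == 5
        assert set(classes) == {1.1, 1.05, 1.0, 0.95, 0.9}

    def test_blr_uniform(self):
        pet, liver_c, _, verts = self._pet_with_organs(liver=2.0, vertebrae=(1, 1, 1, 1))
        out = blr(pet, verts, [False] * 4, liver_c)
        assert out == pytest.approx(0.5, abs=0.02)

    def test_blr_with_exclusion(self):
        pet, liver_c, _, verts = self._pet_with_organs(liver=2.0, vertebrae=(9, 1, 1, 4))
        out = blr(pet, verts, [True, False, False, False], liver_c)
        assert out == pytest.approx((1 + 1 + 4) / 3 / 2.0, abs=0.05)

    def test_blr_all_excluded_missing(self):
        pet, liver_c, _, verts = self._pet_with_organs()
        assert blr(pet, verts, [True] * 4, liver_c) is None


class TestTargetLesion:
    def _lesion(self, i, peak, dm=20.0, region="lung"):
        return LesionFeatures(lesion_id=f"l{i}", organ_region=region,
                              dm_mm=dm, sul_peak=peak)

    def test_highest_peak_wins(self):
        lesions = [self._lesion(i, p) for i, p in enumerate([3.0, 8.0, 5.0])]
        assert select_target_lesion(lesions) == "l1"

    def test_tie_broken_by_diameter(self):
        lesions = [self._lesion(0, 8.0, dm=20.0), self._lesion(1, 7.9, dm=40.0)]
        assert select_target_lesion(lesions) == "l1"

    def test_brain_only_raises(self):
        lesions = [self._lesion(0, 9.0, region="brain")]
        with pytest.raises(ValidationError):
            select_target_lesion(lesions)


class TestPhantomRecovery:
    def test_planted_geometry_recovered(self, small_cohort):
        """Feature extraction on rendered phantoms recovers the planted
        SULmax (exactly, by construction) and diameters within one in-plane
        voxel."""
        from melrisk.pipeline import case_lesion_features

        for case in small_cohort[:2]:
            feats = {f.lesion_id: f for f in case_lesion_features(case)}
            for info, mask in zip(case.lesion_info, case.lesions):
                f = feats[info.lesion_id]
                if f.functional_suppressed:
                    continue
                pet_max = case.volumes["PET_MR"].values[mask.values].max()
                assert pet_max == pytest.approx(info.sul_max, rel=0.10)
                assert f.dm_mm == pytest.approx(
                    info.diameter_mm, abs=2 * mask.spacing[0]
                )
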