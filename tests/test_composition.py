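import numpy as np
import pytest
from hypothesis import given, strategies as st

from ctbodycomp.composition import (
    CompositionError,
    SarcopeniaThresholds,
    caliper_mm,
    classify_sarcopenia,
    derive_areas,
    impute_unmeasurable_dpd,
    mean_muscle_attenuation,
    skeletal_muscle_index,
    stratify_duct,
    stratify_parenchyma,
)
from ctbodycomp.phantom import generate_phantom
from ctbodycomp.segmentation import CTSlice, muscle_range, standardize_slice


class TestDeriveAreas:
    def test_sat_is_tat_minus_vat(self):
        c = derive_areas(300.0, 127.5, 130.0, 20.3, 55.8)
        assert c.a_sat == pytest.approx(172.5)
        assert c.a_tat == 300.0 and c.a_vat == 127.5

    def test_ventral_wall_muscle_by_exclusion(self):
        c = derive_areas(300.0, 127.5, 130.0, 20.3, 55.8)
        assert c.a_mven == pytest.approx(53.9)
        assert c.a_mtot == pytest.approx(130.0)
        assert c.a_mtot == pytest.approx(c.a_mpso + c.a_mspi + c.a_mven)

    def test_fov_truncation_marks_sat_non_quantifiable(self):
        c = derive_areas(300.0, 127.5, 130.0, 20.3, 55.8, fov_truncated=True)
        assert c.a_sat is None
        assert c.a_vat == 127.5 and c.a_mven == pytest.approx(53.9)

    @pytest.mark.parametrize("args, msg", [
        ((100.0, 150.0, 130.0, 20.0, 50.0), "fat"),
        ((300.0, 100.0, 60.0, 20.0, 50.0), "muscle"),
        ((-1.0, 0.0, 10.0, 1.0, 1.0), ">= 0"),
    ])
    def test_nesting_violations_identified(self, args, msg):
        with pytest.raises(CompositionError, match=msg):
            derive_areas(*args)

    @given(
        fat_a=st.floats(0, 500), fat_frac=st.floats(0, 1),
        mus_c=st.floats(0, 60), mus_d=st.floats(0, 80), mus_ven=st.floats(0, 100),
    )
    def test_invariants_hold_on_random_valid_input(self, fat_a, fat_frac, mus_c, mus_d, mus_ven):
        fat_b = fat_a * fat_frac
        mus_a = mus_c + mus_d + mus_ven
        c = derive_areas(fat_a, fat_b, mus_a, mus_c, mus_d)
        assert c.a_sat >= -1e-9
        assert c.a_sat == pytest.approx(c.a_tat - c.a_vat)
        assert c.a_mtot == pytest.approx(c.a_mpso + c.a_mspi + c.a_mven)


class TestMeanMuscleAttenuation:
    def test_constant_muscle_gives_that_value(self):
        px = np.full((20, 20), -500.0)
        px[5:15, 5:15] = 40.0
        ct = CTSlice(px, (1.0, 1.0), 1.0)
        roi_c = [(5, 5), (5, 9), (14, 9), (14, 5)]
        roi_d = [(5, 10), (5, 14), (14, 14), (14, 10)]
        assert mean_muscle_attenuation(ct, roi_c, roi_d, muscle_range()) == 40.0

    def test_overlapping_rois_not_double_counted(self):
        px = np.full((10, 10), -500.0)
        px[2:5, 2:5] = 100.0  # 9 pixels at 100 HU
        px[5, 2] = 10.0       # 1 pixel at 10 HU
        ct = CTSlice(px, (1.0, 1.0), 1.0)
        roi = [(2, 2), (2, 4), (5, 4), (5, 2)]  # covers all 10 muscle pixels
        # same polygon passed as both C and D: the union must count each
        # muscle pixel once, giving (9*100 + 10) / 10
        got = mean_muscle_attenuation(ct, roi, roi, muscle_range())
        assert got == pytest.approx(91.0)

    def test_matches_per_pixel_loop_on_phantom(self, tiny_spec):
        ct, truth = generate_phantom(tiny_spec)
        ct = standardize_slice(ct)
        got = mean_muscle_attenuation(
            ct, truth.roi_set.roi_c, truth.roi_set.roi_d, muscle_range()
        )
        from ctbodycomp.segmentation import pixels_in_roi_mask

        union = pixels_in_roi_mask(ct.shape, truth.roi_set.roi_c) | pixels_in_roi_mask(
            ct.shape, truth.roi_set.roi_d
        )
        acc, n = 0.0, 0
        for r in range(ct.shape[0]):
            for c in range(ct.shape[1]):
                hu = ct.pixels[r, c]
                if union[r, c] and -30.0 < hu <= 150.0:
                    acc += hu
                    n += 1
        assert got == pytest.approx(acc / n)
        assert got == pytest.approx(truth.ma_hu)

    def test_no_muscle_pixels_is_an_error_not_zero(self):
        px = np.full((10, 10), -500.0)
        ct = CTSlice(px, (1.0, 1.0), 1.0)
        roi = [(1, 1), (1, 8), (8, 8), (8, 1)]
        with pytest.raises(CompositionError, match="no muscle"):
            mean_muscle_attenuation(ct, roi, roi, muscle_range())


class TestSmi:
    def test_direct_formula(self):
        assert skeletal_muscle_index(130.0, 1.70) == pytest.approx(44.98, abs=0.005)

    def test_identity_at_unit_height_and_zero_muscle(self):
        assert skeletal_muscle_index(123.4, 1.0) == 123.4
        assert skeletal_muscle_index(0.0, 1.8) == 0.0

    def test_nonpositive_height_rejected(self):
        with pytest.raises(CompositionError):
            skeletal_muscle_index(100.0, 0.0)


class TestSarcopenia:
    def test_low_ma_alone_triggers_combined_flag(self):
        by_smi, by_ma, both = classify_sarcopenia(60.0, 20.0, "male", 24.0)
        assert not by_smi and by_ma and both

    def test_exactly_at_cutoff_is_not_sarcopenic(self):
        th = SarcopeniaThresholds()
        by_smi, by_ma, both = classify_sarcopenia(
            th.smi_male_low_bmi, th.ma_low_bmi, "male", 24.0, th
        )
        assert not by_smi and not by_ma and not both

    def test_bmi_class_switches_cutoffs(self):
        # SMI 48 is sarcopenic for an overweight man (cutoff 53), not a lean one (43)
        assert classify_sarcopenia(48.0, 45.0, "male", 26.0)[0]
        assert not classify_sarcopenia(48.0, 45.0, "male", 24.0)[0]
        assert not classify_sarcopenia(48.0, 45.0, "female", 26.0)[0]

    def test_missing_covariates_listed(self):
        with pytest.raises(CompositionError, match="smi"):
            classify_sarcopenia(None, 40.0, "male", 24.0)

    @given(
        smi=st.floats(10, 80), ma=st.floats(-20, 100),
        d_smi=st.floats(0, 20), d_ma=st.floats(0, 20),
        male=st.booleans(), bmi=st.floats(17, 40),
    )
    def test_monotone_lowering_smi_or_ma_never_clears_status(self, smi, ma, d_smi, d_ma, male, bmi):
        sex = "male" if male else "female"
        before = classify_sarcopenia(smi, ma, sex, bmi)[2]
        after = classify_sarcopenia(smi - d_smi, ma - d_ma, sex, bmi)[2]
        assert after or not before


class TestCaliper:
    @pytest.mark.parametrize("p1, p2, spacing, expect", [
        ((0, 0), (0, 10), (1.0, 1.0), 10.0),
        ((0, 0), (3, 4), (1.0, 1.0), 5.0),
        ((0, 0), (0, 10), (0.7, 0.7), 7.0),
        ((2, 3), (2, 3), (1.0, 1.0), 0.0),
    ])
    def test_known_distances(self, p1, p2, spacing, expect):
        assert caliper_mm(p1, p2, spacing) == pytest.approx(expect)

    def test_off_raster_point_rejected(self):
        with pytest.raises(CompositionError, match="off the raster"):
            caliper_mm((0, 0), (100, 0), (1.0, 1.0), shape=(50, 50))

    @given(
        pts=st.lists(
            st.tuples(st.floats(0, 50), st.floats(0, 50)), min_size=3, max_size=3
        ),
        rs=st.floats(0.3, 3.0), cs=st.floats(0.3, 3.0),
    )
    def test_symmetry_and_triangle_inequality(self, pts, rs, cs):
        a, b, c = pts
        sp = (rs, cs)
        assert caliper_mm(a, b, sp) == pytest.approx(caliper_mm(b, a, sp))
        assert caliper_mm(a, c, sp) <= caliper_mm(a, b, sp) + caliper_mm(b, c, sp) + 1e-9


class TestDuctStratification:
    @pytest.mark.parametrize("dpd, expect", [
        (2.9, "narrow"), (3.0, "wide"), (0.7, "narrow"), (10.7, "wide"), (None, "unmeasurable"),
    ])
    def test_three_mm_cutoff_strict(self, dpd, expect):
        assert stratify_duct(dpd) == expect

    def test_parenchyma_twelve_mm_cutoff(self):
        assert stratify_parenchyma(11.9) == "thin"
        assert stratify_parenchyma(12.0) == "thick"
        assert stratify_parenchyma(None) == "unmeasurable"

    def test_imputation_sensitivity_mode(self):
        from ctbodycomp.cohort import CohortSpec, generate_cohort

        recs = generate_cohort(CohortSpec(n_patients=60, missing_dpd_fraction=0.3, seed=5))
        n_missing = sum(r.dpd is None for r in recs)
        assert n_missing > 0
        imputed = impute_unmeasurable_dpd(recs, standard_width_mm=3.0)
        assert all(r.dpd is not None for r in imputed)
        assert sum(r.dpd == 3.0 for r in imputed) >= n_missing
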