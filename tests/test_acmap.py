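import numpy as np
import pytest

from sute_ac.acmap import (ACCoefficients, CalibrationFit, classify_ct,
                           classify_vendor_ute, default_r2star_calibration,
                           fit_r2star_calibration, hu_to_mu, make_ac_map,
                           make_mc_ac_map, reference_ac_from_labels)
from sute_ac.segmentation import SegmentationResult
from sute_ac.template import CLASSES
from sute_ac.volume import LabelMask, Volume


def _seg_from_hard(air, bone, soft, shape=(8, 8, 8)):
    """One-hot posteriors from boolean masks."""
    maps = {c: Volume(np.zeros(shape), (1, 1, 1), units="probability")
            for c in CLASSES}
    maps["air"] = Volume(air.astype(float), (1, 1, 1), units="probability")
    maps["bone"] = Volume(bone.astype(float), (1, 1, 1), units="probability")
    maps["soft"] = Volume(soft.astype(float), (1, 1, 1), units="probability")
    return SegmentationResult(maps, [], np.array([0.0]), CLASSES)


def _three_region_seg(shape=(9, 9, 9)):
    air = np.zeros(shape, bool)
    bone = np.zeros(shape, bool)
    air[:3] = True
    bone[3:6] = True
    return _seg_from_hard(air, bone, ~(air | bone), shape)


class TestCoefficients:
    def test_defaults_match_assigned_values(self):
        c = ACCoefficients()
        assert (c.bone, c.soft, c.air) == (0.151, 0.100, 0.0)
        assert (c.gm, c.wm, c.csf) == (0.099, 0.099, 0.096)

    def test_air_must_be_zero(self):
        with pytest.raises(ValueError):
            ACCoefficients(air=0.01)


class TestCalibration:
    def test_exact_cubic_recovered(self):
        rng = np.random.default_rng(0)
        coeffs = np.array([0.1, 0.02, -0.003, 0.0004])
        r = np.linspace(0.0, 2.5, 12)
        mu = np.polynomial.polynomial.polyval(r, coeffs)
        fit = fit_r2star_calibration(r, mu, mu_clamp=(-10, 10))
        residual = np.abs(fit(r) - mu)
        assert residual.max() < 1e-8
        np.testing.assert_allclose(fit.coeffs, coeffs, atol=1e-8)

    def test_constant_samples_give_constant_polynomial(self):
        r = np.linspace(0, 2, 10)
        fit = fit_r2star_calibration(r, np.full(10, 0.12), mu_clamp=(0, 1))
        assert fit.coeffs[0] == pytest.approx(0.12, abs=1e-10)
        assert np.allclose(fit.coeffs[1:], 0.0, atol=1e-9)

    def test_decreasing_samples_rejected(self):
        r = np.linspace(0, 2, 10)
        with pytest.raises(ValueError, match="monoton"):
            fit_r2star_calibration(r, 0.2 - 0.05 * r)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="8"):
            fit_r2star_calibration([0, 1, 2], [0.1, 0.12, 0.15])

    def test_default_calibration_hits_the_anchors(self):
        calib = default_r2star_calibration()
        assert calib(np.array([0.0]))[0] == pytest.approx(0.100, abs=1e-6)
        assert calib(np.array([2.0]))[0] == pytest.approx(0.151, abs=1e-6)

    def test_output_clamped(self):
        calib = default_r2star_calibration()
        assert calib(np.array([50.0]))[0] <= 0.20


class TestMakeAcMap:
    def test_pre_smoothing_values_per_class(self):
        seg = _three_region_seg()
        ac = make_ac_map(seg, mode="fix", smoothing_fwhm_mm=0.0)
        assert set(np.unique(ac.data)) == {0.0, 0.100, 0.151}
        assert np.all(ac.data[4] == 0.151)
        assert np.all(ac.data[0] == 0.0)
        assert np.all(ac.data[7] == 0.100)

    def test_smoothed_interface_stays_inside_range(self):
        shape = (16, 16, 32)
        air = np.zeros(shape, bool)
        bone = np.zeros(shape, bool)
        bone[:, :, 16:] = True
        seg = _seg_from_hard(air, bone, ~bone, shape)
        ac = make_ac_map(seg, mode="fix", smoothing_fwhm_mm=2.0)
        seam = ac.data[8, 8, 14:18]
        assert np.all(seam > 0.100) and np.all(seam < 0.151)

    def test_cont_mode_requires_calibration(self):
        with pytest.raises(ValueError, match="cont"):
            make_ac_map(_three_region_seg(), mode="cont")

    def test_fix_equals_cont_under_constant_calibration(self):
        seg = _three_region_seg()
        r2s = Volume(np.random.default_rng(1).random((9, 9, 9)) * 2,
                     (1, 1, 1), units="r2star_per_ms")
        calib = CalibrationFit((0.151, 0.0, 0.0, 0.0), (0.0, 3.0),
                               mu_clamp=(0.0, 0.2))
        fix = make_ac_map(seg, mode="fix", smoothing_fwhm_mm=0.0)
        cont = make_ac_map(seg, mode="cont", r2s=r2s, calib=calib,
                           smoothing_fwhm_mm=0.0)
        np.testing.assert_allclose(fix.data, cont.data, atol=1e-12)

    def test_fallback_pasted_outside_coverage(self):
        seg = _three_region_seg()
        cover = Volume(np.ones((9, 9, 9)), (1, 1, 1))
        cover.data[:, :, :2] = 0.0
        fallback = Volume(np.full((9, 9, 9), 0.05), (1, 1, 1),
                          units="mu_cm_inv")
        ac = make_ac_map(seg, mode="fix", smoothing_fwhm_mm=0.0,
                         coverage_mask=cover, fallback=fallback)
        assert np.all(ac.data[:, :, :2] == 0.05)
        assert np.all(ac.data[7, :, 2:] == 0.100)


class TestMcAcMap:
    def _labels6(self):
        labels = np.zeros((6, 4, 4), dtype=np.int16)
        table = {0: "air", 1: "soft", 2: "bone", 3: "gm", 4: "wm", 5: "csf"}
        for i in range(6):
            labels[i] = i
        return LabelMask(labels, table)

    def test_brain_compartment_values(self):
        ac = make_mc_ac_map(self._labels6(), smoothing_fwhm_mm=0.0)
        assert np.all(ac.data[5] == 0.096)   # CSF
        assert np.all(ac.data[3] == 0.099)   # GM
        assert np.all(ac.data[4] == 0.099)   # WM

    def test_all_soft_map_is_constant_and_smoothing_invariant_interior(self):
        labels = LabelMask(np.ones((24, 24, 24), dtype=np.int16), {1: "soft"})
        raw = make_mc_ac_map(labels, smoothing_fwhm_mm=0.0)
        sm = make_mc_ac_map(labels, smoothing_fwhm_mm=2.0)
        assert np.all(raw.data == 0.100)
        np.testing.assert_allclose(sm.data[6:-6, 6:-6, 6:-6], 0.100, rtol=1e-9)

    def test_unknown_label_rejected(self):
        labels = LabelMask(np.zeros((2, 2, 2), dtype=np.int16), {0: "plasma"})
        with pytest.raises(ValueError, match="unknown"):
            make_mc_ac_map(labels)


class TestReferenceMap:
    def _truth(self):
        labels = np.zeros((6, 2, 2), dtype=np.int16)
        table = {0: "air", 1: "soft", 2: "bone", 3: "gm", 4: "wm", 5: "csf"}
        for i in range(6):
            labels[i] = i
        return LabelMask(labels, table)

    def test_three_compartment_values(self):
        ac = reference_ac_from_labels(self._truth())
        assert np.all(ac.data[2] == 0.151)
        assert np.all(ac.data[1] == 0.100)
        assert np.all(ac.data[0] == 0.0)

    def test_brain_classes_fold_to_soft(self):
        ac = reference_ac_from_labels(self._truth())
        for idx in (3, 4, 5):
            assert np.all(ac.data[idx] == 0.100)

    def test_piecewise_constant_value_set(self):
        ac = reference_ac_from_labels(self._truth())
        assert set(np.unique(ac.data)) <= {0.0, 0.100, 0.151}

    def test_vendor_classification_round_trips_reference_map(self):
        truth = self._truth()
        labels = classify_vendor_ute(reference_ac_from_labels(truth))
        three = np.where(truth.labels >= 3, 1, truth.labels)
        np.testing.assert_array_equal(labels.labels, three)


class TestCtConversion:
    def _hu(self, values):
        return Volume(np.asarray(values, float).reshape(1, 1, -1),
                      (1, 1, 1), units="HU")

    def test_air_and_water_anchors(self):
        mu = hu_to_mu(self._hu([-1000.0, 0.0]))
        np.testing.assert_allclose(mu.data.ravel(), [0.0, 0.096], atol=1e-12)

    def test_monotone_in_hu(self):
        hu = np.linspace(-1000, 2000, 100)
        mu = hu_to_mu(self._hu(hu))
        assert np.all(np.diff(mu.data.ravel()) >= 0)

    def test_classification_thresholds_are_strict(self):
        labels = classify_ct(self._hu([-800.0, -500.0, 0.0, 300.0, 500.0]))
        names = [labels.label_table[int(v)] for v in labels.labels.ravel()]
        assert names == ["air", "soft", "soft", "soft", "bone"]

    def test_wrong_units_rejected(self):
        with pytest.raises(ValueError, match="HU"):
            hu_to_mu(Volume(np.zeros((2, 2, 2)), (1, 1, 1)))


class TestVendorClassification:
    def test_exact_rule(self):
        ac = Volume(np.array([[[0.151, 0.0, 0.100, 0.13]]]), (1, 1, 1),
                    units="mu_cm_inv")
        labels = classify_vendor_ute(ac)
        names = [labels.label_table[int(v)] for v in labels.labels.ravel()]
        assert names == ["bone", "air", "soft", "soft"]

    def test_tolerance_widens_the_match(self):
        ac = Volume(np.array([[[0.1509999]]]), (1, 1, 1), units="mu_cm_inv")
        assert classify_vendor_ute(ac, eps=1e-3).labels[0, 0, 0] == 2
        near = Volume(np.array([[[0.1505]]]), (1, 1, 1), units="mu_cm_inv")
        assert classify_vendor_ute(near, eps=1e-3).labels[0, 0, 0] == 2
        assert classify_vendor_ute(near, eps=1e-6).labels[0, 0, 0] == 1
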