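import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nervequant._util import rng_from
from nervequant.ph import (
    BUFFER_LADDER_PH,
    CalibrationCurve,
    CalibrationError,
    MeasurementRejected,
    RatioMeasurement,
    build_calibration,
    compute_ratio,
    detect_contacts,
    estimate_background,
    estimate_ph,
    measure_contact_ph,
    sample_membrane_rois,
)
from nervequant.puncta import detect_puncta
from nervequant.synth import forward_ratio_model, make_ratiometric_scene

from conftest import disk_mask


class TestBackground:
    def test_constant_background_recovered(self):
        rng = np.random.default_rng(0)
        img = rng.normal(50, 1, (200, 200))
        cells = disk_mask((200, 200), 100, 100, 40)
        img[cells] += 500
        assert estimate_background(img, cells) == pytest.approx(50, abs=1)

    def test_zero_background(self):
        img = np.zeros((64, 64))
        cells = disk_mask((64, 64), 32, 32, 10)
        img[cells] = 100
        assert estimate_background(img, cells) == 0.0

    def test_gradient_background_median_bounded(self):
        yy, xx = np.mgrid[0:100, 0:100]
        img = 10 + 0.5 * xx.astype(float)
        cells = disk_mask((100, 100), 50, 50, 15)
        b = estimate_background(img, cells)
        assert img.min() <= b <= img.max()

    def test_full_field_cells_rejected(self):
        with pytest.raises(ValueError, match="background ROI"):
            estimate_background(np.ones((32, 32)), np.ones((32, 32), bool))


class TestComputeRatio:
    def test_arithmetic(self):
        m = RatioMeasurement(I_m_long=200, I_b_long=50, I_m_short=100, I_b_short=25)
        assert compute_ratio(m) == pytest.approx(2.0)

    def test_equal_corrected_channels_give_one(self):
        m = RatioMeasurement(120, 20, 150, 50)
        assert compute_ratio(m) == pytest.approx(1.0)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(MeasurementRejected) as e:
            compute_ratio(RatioMeasurement(200, 50, 25, 25))
        assert e.value.reason == "nonpositive_denominator"

    def test_nonpositive_numerator_rejected(self):
        with pytest.raises(MeasurementRejected) as e:
            compute_ratio(RatioMeasurement(40, 50, 100, 25))
        assert e.value.reason == "nonpositive_numerator"

    @given(st.floats(1, 1e4), st.floats(1, 1e4), st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_background_shift_invariance(self, num, den, shift):
        # adding a constant to a channel and its background leaves the ratio unchanged
        base = compute_ratio(RatioMeasurement(100 + num, 100, 50 + den, 50))
        shifted = compute_ratio(
            RatioMeasurement(100 + num + shift, 100 + shift, 50 + den, 50)
        )
        assert shifted == pytest.approx(base, rel=1e-12)


class TestMembraneRois:
    def test_requested_rois_disjoint_with_expected_area(self):
        mem = np.zeros((400, 400), bool)
        mem[180:220, :] = True
        rois = sample_membrane_rois(mem, 0.07, 10, seed=1)
        assert len(rois) == 10
        expected_px = (2.0 / 0.07) * (0.5 / 0.07)
        for r in rois:
            assert len(r) == pytest.approx(expected_px, rel=0.08)
        all_px = [tuple(p) for r in rois for p in r]
        assert len(all_px) == len(set(all_px))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            sample_membrane_rois(np.zeros((32, 32), bool), 0.07, 3)

    def test_same_seed_same_rois(self):
        mem = np.zeros((300, 300), bool)
        mem[100:140, :] = True
        a = sample_membrane_rois(mem, 0.07, 5, seed=9)
        b = sample_membrane_rois(mem, 0.07, 5, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestCalibration:
    def test_noiseless_ladder_accuracy(self, clean_curve):
        for p0 in np.linspace(4.0, 7.5, 60):
            est, extrap = estimate_ph(forward_ratio_model(p0), clean_curve)
            assert not extrap
            assert est == pytest.approx(p0, abs=0.05)

    def test_gross_ratio_outliers_rejected(self, clean_ladder_points, clean_curve):
        pts = clean_ladder_points + [
            (5.0, forward_ratio_model(5.0) * 3),
            (6.5, forward_ratio_model(6.5) * 3),
        ]
        curve = build_calibration(pts)
        assert len(curve.rejected) == 2
        grid = np.linspace(clean_curve.ratio_min, clean_curve.ratio_max, 50)
        clean = np.polynomial.polynomial.polyval(grid, clean_curve.coefficients)
        cont = np.polynomial.polynomial.polyval(grid, curve.coefficients)
        assert np.max(np.abs(cont - clean) / np.abs(clean)) < 0.01

    def test_span_precondition(self):
        pts = [(7.0, 2.0 + 0.01 * i) for i in range(10)]
        with pytest.raises(CalibrationError, match="span"):
            build_calibration(pts)

    def test_too_few_points(self):
        pts = [(p, forward_ratio_model(p)) for p in (4.0, 5.0, 6.0, 7.0, 8.0)]
        with pytest.raises(CalibrationError, match="at least 8"):
            build_calibration(pts)

    def test_curve_json_roundtrip(self, tmp_path, clean_curve):
        path = tmp_path / "curve.json"
        clean_curve.to_json(path)
        back = CalibrationCurve.from_json(path)
        assert np.allclose(back.coefficients, clean_curve.coefficients)
        assert back.ratio_min == clean_curve.ratio_min
        assert back.retained == clean_curve.retained

    def test_summary_mentions_fit_quality(self, clean_curve):
        s = clean_curve.summary()
        assert "RMSE" in s and "retained" in s

    def test_noisy_roi_level_recovery_and_outlier_removal(self):
        n_runs, caught, errs = 40, 0, []
        for k in range(n_runs):
            rng = rng_from(5000 + k)
            pts = []
            for p in BUFFER_LADDER_PH:
                r = forward_ratio_model(p)
                pts += [(p, r * rng.normal(1, 0.05) / rng.normal(1, 0.05)) for _ in range(8)]
            gi = rng.choice(len(pts), 2, replace=False)
            planted = []
            for i in gi:
                pts[i] = (pts[i][0], pts[i][1] * 3.0)
                planted.append(pts[i][1])
            curve = build_calibration(pts)
            retained_ratios = {r for _, r in curve.retained}
            if all(pr not in retained_ratios for pr in planted):
                caught += 1
            errs += [
                abs(estimate_ph(forward_ratio_model(p0), curve)[0] - p0)
                for p0 in np.linspace(4.5, 7.5, 20)
            ]
        assert np.median(errs) < 0.1
        assert caught / n_runs >= 0.95


class TestEstimatePh:
    def test_calibration_point_consistency(self, clean_curve):
        for p, r in clean_curve.retained:
            if 4.0 <= p <= 7.5:
                assert estimate_ph(r, clean_curve)[0] == pytest.approx(p, abs=0.05)

    def test_out_of_range_clamped_and_flagged(self, clean_curve):
        ph_hi, extrap = estimate_ph(clean_curve.ratio_max * 1.5, clean_curve)
        assert extrap
        assert ph_hi == pytest.approx(clean_curve.predict(clean_curve.ratio_max))


class TestContacts:
    def test_adjacent_structures_bridge(self):
        mito = np.zeros((60, 60), bool)
        mito[28:33, :] = True
        lyso = disk_mask((60, 60), 37, 30, 4)  # disk resting just below the tube
        assert not (mito & lyso).any()
        labels = detect_contacts(mito, lyso, contact_radius_px=2)
        assert labels.max() == 1

    def test_distant_structures_no_contact(self):
        mito = np.zeros((60, 60), bool)
        mito[10:13, :] = True
        lyso = disk_mask((60, 60), 45, 30, 4)
        assert detect_contacts(mito, lyso, contact_radius_px=2).max() == 0

    def test_planted_contacts_recovered_from_truth_masks(self):
        sc = make_ratiometric_scene(n_contacts=8, snr=None, seed=5)
        labels = detect_contacts(sc.truth["mito_mask"], sc.truth["lyso_mask"])
        assert labels.max() == 8


class TestMeasureContactPh:
    def test_uniform_ph_recovered(self, clean_curve):
        sc = make_ratiometric_scene(n_contacts=12, base_ph=7.0, contact_ph=7.0,
                                    snr=20, backgrounds=(30, 40, 20), seed=6)
        i405 = sc.image.channel("ex405")
        i475 = sc.image.channel("ex475")
        tab = measure_contact_ph(sc.truth["contact_labels"], i475, i405,
                                 (40.0, 30.0), clean_curve, 0.07)
        assert len(tab) == 12
        assert tab["ph"].mean() == pytest.approx(7.0, abs=0.1)

    def test_no_contacts_empty_table(self, clean_curve):
        tab = measure_contact_ph(np.zeros((32, 32), np.int32),
                                 np.ones((32, 32)), np.ones((32, 32)),
                                 (0.0, 0.0), clean_curve)
        assert len(tab) == 0

    def test_rejected_measurement_carries_reason(self, clean_curve):
        contacts = np.zeros((16, 16), np.int32)
        contacts[4:8, 4:8] = 1
        i_long = np.full((16, 16), 100.0)
        i_short = np.full((16, 16), 10.0)
        tab = measure_contact_ph(contacts, i_long, i_short, (50.0, 30.0), clean_curve)
        assert tab.loc[0, "reason"] == "nonpositive_denominator"
        assert np.isnan(tab.loc[0, "ph"])

    def test_two_population_difference_recovered(self, clean_curve):
        sc = make_ratiometric_scene(n_contacts=32, base_ph=7.0,
                                    contact_ph=[7.1] * 16 + [6.3] * 16,
                                    snr=20, backgrounds=(30, 40, 20),
                                    seed=7, shape=(448, 448))
        i405 = sc.image.channel("ex405")
        i475 = sc.image.channel("ex475")
        tab = measure_contact_ph(sc.truth["contact_labels"], i475, i405,
                                 (40.0, 30.0), clean_curve, 0.07)
        ph = tab.sort_values("object_id")["ph"].to_numpy()
        diff = np.median(ph[:16]) - np.median(ph[16:])
        assert diff == pytest.approx(0.8, abs=0.1)
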