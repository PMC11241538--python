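"""Time–intensity extraction, AUC integration, and the CCIA ratio."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccia.errors import RoiError, SignalError, ValidationError
from ccia.io_stack import FrameStack, RoiSpec
from ccia.tic_core import (Injection, TimeIntensityCurve, auc, ccia,
                           compute_ccia_from_stack, define_proximal_roi,
                           extract_signal, stewart_hamilton_flow)
from conftest import make_attenuated_stack


MASK = np.zeros((20, 40), dtype=bool)
MASK[8:12, 10:20] = True


class TestExtractSignal:
    def test_uniform_stack_gives_zero_signal(self, flat_stack):
        mask = np.zeros((20, 40), dtype=bool)
        mask[5:10, 5:10] = True
        curve = extract_signal(flat_stack, mask, baseline_frames=5)
        assert np.all(curve.values == 0)
        assert curve.baseline_level == pytest.approx(1000.0)

    def test_recovers_known_attenuation_sequence(self):
        atten = np.array([0, 0, 0, 50, 120, 80, 20, 0], dtype=float)
        stack = make_attenuated_stack(atten, MASK)
        curve = extract_signal(stack, MASK, baseline_frames=3)
        np.testing.assert_allclose(curve.values, atten)
        assert curve.roi_pixel_count == MASK.sum()

    def test_linearity_in_attenuation(self):
        atten = np.array([0, 0, 30, 60, 10], dtype=float)
        c1 = extract_signal(make_attenuated_stack(atten, MASK), MASK, 2)
        c2 = extract_signal(make_attenuated_stack(2 * atten, MASK), MASK, 2)
        np.testing.assert_allclose(c2.values, 2 * c1.values)

    def test_errors_on_empty_mask_and_bad_baseline(self, flat_stack):
        with pytest.raises(RoiError):
            extract_signal(flat_stack, np.zeros((20, 40), bool), 5)
        with pytest.raises(SignalError):
            extract_signal(flat_stack, MASK, baseline_frames=60)


class TestAuc:
    def test_rectangle(self):
        c = TimeIntensityCurve([0, 1, 2, 3], [5, 5, 5, 5], 10, 0.0)
        assert auc(c, 0, 3) == pytest.approx(15.0)

    def test_triangle_ramp(self):
        c = TimeIntensityCurve([0.0, 1.0], [0.0, 1.0], 10, 0.0)
        assert auc(c, 0, 1) == pytest.approx(0.5)

    def test_gamma_variate_matches_closed_form(self):
        # C(t) = t^2 exp(-t); integral over [0, inf) is Gamma(3) = 2
        t = np.arange(0, 40.0 + 1e-3, 1e-3)
        c = TimeIntensityCurve(t, t ** 2 * np.exp(-t), 1, 0.0)
        assert auc(c, 0.0, 40.0) == pytest.approx(math.gamma(3), abs=1e-4)

    def test_interpolated_window_edges(self):
        c = TimeIntensityCurve([0, 1, 2], [0, 2, 0], 1, 0.0)
        assert auc(c, 0.5, 1.5) == pytest.approx(1.5)

    def test_window_outside_support_raises(self):
        c = TimeIntensityCurve([0, 1], [1, 1], 1, 0.0)
        with pytest.raises(ValidationError):
            auc(c, -1.0, 1.0)
        with pytest.raises(ValidationError):
            auc(c, 0.8, 0.2)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=11),
           st.lists(st.floats(0.0, 1000.0), min_size=12, max_size=12))
    def test_exact_on_piecewise_linear_curves(self, dts, vals):
        """Trapezoid integration is exact when samples sit on breakpoints."""
        t = np.concatenate([[0.0], np.cumsum(dts)])
        v = np.array(vals[:len(t)])
        expected = sum((t[i + 1] - t[i]) * (v[i] + v[i + 1]) / 2
                       for i in range(len(t) - 1))
        c = TimeIntensityCurve(t, v, 1, 0.0)
        assert auc(c, t[0], t[-1]) == pytest.approx(expected, rel=1e-12)


class TestCciaRatio:
    @pytest.mark.parametrize("proximal,stenotic,expected", [
        (1706.0, 1041.0, 0.61),
        (448.0, 491.0, 1.10),
        (477.0, 48.0, 0.10),
        (660.0, 113.0, 0.17),
        (212.0, 91.89, 0.43),
    ])
    def test_clinical_intensity_pairs(self, proximal, stenotic, expected):
        assert round(ccia(proximal, stenotic).ccia, 2) == pytest.approx(expected)

    def test_equal_aucs_give_unity(self):
        assert ccia(123.4, 123.4).ccia == 1.0

    def test_nonpositive_auc_raises(self):
        with pytest.raises(ValidationError):
            ccia(0.0, 10.0)
        with pytest.raises(ValidationError):
            ccia(10.0, -1.0)


class TestStewartHamilton:
    def test_unit_case(self):
        assert stewart_hamilton_flow(Injection(1.0, 1.0), 1.0) == pytest.approx(1.0)

    def test_four_ml_over_two_auc(self):
        assert stewart_hamilton_flow(Injection(4.0, 16.0), 2.0) == pytest.approx(2.0)

    def test_gain_rescaling(self):
        f1 = stewart_hamilton_flow(Injection(4.0, 16.0), 10.0, calibration_gain=5.0)
        f2 = stewart_hamilton_flow(Injection(4.0, 16.0), 2.0, calibration_gain=1.0)
        assert f1 == pytest.approx(f2)

    def test_zero_auc_raises(self):
        with pytest.raises(ValidationError):
            stewart_hamilton_flow(Injection(4.0, 16.0), 0.0)


class TestProximalRoi:
    def test_pixel_count_preserved_and_gap_correct(self, straight_vessel_roi):
        prox = define_proximal_roi(straight_vessel_roi)
        sten = straight_vessel_roi.stenotic_mask
        assert prox.sum() == sten.sum()
        # 10 mm at 0.2 mm/px = 50 px of clearance between the ROIs
        prox_cols = np.nonzero(prox.any(axis=0))[0]
        sten_cols = np.nonzero(sten.any(axis=0))[0]
        assert sten_cols.min() - prox_cols.max() == 50
        # same rows: pure translation along the horizontal centerline
        assert (prox.any(axis=1) == sten.any(axis=1)).all()

    def test_gap_scales_with_calibration(self):
        mask = np.zeros((10, 120), dtype=bool)
        mask[4:6, 60:80] = True
        cl = np.column_stack([np.full(120, 4.5), np.arange(120)])
        roi = RoiSpec(mask, cl, calibration=1.0)
        prox = define_proximal_roi(roi)
        prox_cols = np.nonzero(prox.any(axis=0))[0]
        assert 60 - prox_cols.max() == 10  # 10 mm at 1 mm/px

    def test_centerline_too_short_raises(self):
        mask = np.zeros((10, 60), dtype=bool)
        mask[4:6, 20:50] = True
        cl = np.column_stack([np.full(60, 4.5), np.arange(60)])
        with pytest.raises(RoiError):
            define_proximal_roi(RoiSpec(mask, cl, calibration=0.2))


class TestComputeFromStack:
    def _stack_and_roi(self, scale=1.0):
        rng = np.random.default_rng(7)
        n, h, w = 40, 20, 200
        frames = np.full((n, h, w), 2000.0)
        mask = np.zeros((h, w), dtype=bool)
        mask[8:12, 120:150] = True
        cl = np.column_stack([np.full(w, 9.5), np.arange(w)])
        roi = RoiSpec(mask, cl, calibration=0.2)
        prox = define_proximal_roi(roi)
        bolus = np.concatenate([np.zeros(5), np.hanning(30) * 400, np.zeros(5)])
        for t in range(n):
            frames[t][mask] -= 0.6 * bolus[t]
            frames[t][prox] -= bolus[t]
        stack = FrameStack(frames * scale, np.arange(n) / 30.0, 0.2)
        return stack, roi

    def test_known_attenuation_ratio(self):
        stack, roi = self._stack_and_roi()
        res = compute_ccia_from_stack(stack, roi, baseline_frames=5)
        assert res.ccia == pytest.approx(0.6, rel=1e-6)
        assert res.ccia == pytest.approx(res.auc_stenotic / res.auc_proximal)

    def test_global_rescaling_leaves_ccia_unchanged(self):
        s1, roi = self._stack_and_roi(1.0)
        s2, _ = self._stack_and_roi(2.0)
        r1 = compute_ccia_from_stack(s1, roi, 5)
        r2 = compute_ccia_from_stack(s2, roi, 5)
        assert abs(r1.ccia - r2.ccia) < 1e-9
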