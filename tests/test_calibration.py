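import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazecal.calibration import (
    CalibrationPair,
    design_matrix,
    fit_mapping,
    pair_streams,
    predict,
    reprojection_residuals,
    split_pairs,
)
from gazecal.exceptions import DegenerateGeometry, InsufficientCalibrationPoints
from gazecal.metrics import pairs_from_table


def _quadratic_pairs(n=40, seed=0, coeffs=None):
    rng = np.random.default_rng(seed)
    pupil = rng.uniform([200, 150], [440, 330], (n, 2))
    cx = coeffs[0] if coeffs else np.array([100.0, 4.0, 0.5, 0.003, 0.002, 0.001])
    cy = coeffs[1] if coeffs else np.array([50.0, 0.3, 3.5, -0.002, 0.001, 0.002])
    A = design_matrix(pupil)
    marker = np.column_stack([A @ cx, A @ cy])
    return [
        CalibrationPair(i * 9, tuple(pupil[i]), tuple(marker[i])) for i in range(n)
    ]


class TestPairStreams:
    def test_identical_grids_all_matched(self):
        pupils = [(t, 1.0, 2.0) for t in range(0, 100, 10)]
        markers = [(t, 3.0, 4.0) for t in range(0, 100, 10)]
        pairs, dropped = pair_streams(pupils, markers)
        assert len(pairs) == 10 and dropped == 0

    def test_offset_beyond_window_drops_all(self):
        pupils = [(t, 1.0, 2.0) for t in range(0, 100, 10)]
        markers = [(t + 100, 3.0, 4.0) for t in range(0, 100, 10)]
        pairs, dropped = pair_streams(pupils, markers, max_dt_ms=9)
        assert pairs == [] and dropped == 10

    def test_nearest_timestamp_wins(self):
        pairs, _ = pair_streams([(10, 1.0, 2.0)], [(6, 5.0, 5.0), (13, 7.0, 7.0)])
        assert pairs[0].marker == (7.0, 7.0)

    def test_equidistant_tie_breaks_to_later(self):
        pairs, _ = pair_streams([(10, 1.0, 2.0)], [(7, 5.0, 5.0), (13, 7.0, 7.0)])
        assert pairs[0].marker == (7.0, 7.0)

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            pairs, _ = pair_streams([], [(0, 1.0, 2.0)])
        assert pairs == []


class TestSplitPairs:
    def test_half_split_of_228(self):
        pairs = _quadratic_pairs(228)
        X, Y = split_pairs(pairs, 0.5, seed=0)
        assert len(X) == 114 and len(Y) == 114
        assert {id(p) for p in X}.isdisjoint(id(p) for p in Y)

    def test_same_seed_same_split(self):
        pairs = _quadratic_pairs(50)
        assert split_pairs(pairs, 0.5, 3)[0] == split_pairs(pairs, 0.5, 3)[0]

    def test_threshold_rule_on_ten_pairs(self):
        pairs = _quadratic_pairs(10)
        X, Y = split_pairs(pairs, 0.9, seed=0)  # X=9, Y=1: allowed
        assert len(X) == 9 and len(Y) == 1
        with pytest.raises(InsufficientCalibrationPoints):
            split_pairs(pairs, 0.4, seed=0)  # X=4 < 6


class TestFitPredict:
    def test_noiseless_quadratic_recovered(self):
        pairs = _quadratic_pairs(60)
        model = fit_mapping(pairs)
        res = reprojection_residuals(model, pairs)
        assert np.abs(res.vectors).max() <= 1e-6

    def test_five_pairs_rejected(self):
        with pytest.raises(InsufficientCalibrationPoints):
            fit_mapping(_quadratic_pairs(5))

    def test_collinear_pupils_degenerate(self):
        pairs = [
            CalibrationPair(i, (float(i), 2.0 * i), (float(i), float(i)))
            for i in range(20)
        ]
        with pytest.raises(DegenerateGeometry) as exc:
            fit_mapping(pairs)
        assert exc.value.deficient_basis is not None

    def test_training_point_maps_to_its_marker(self):
        pairs = _quadratic_pairs(30)
        model = fit_mapping(pairs)
        np.testing.assert_allclose(
            predict(model, pairs[7].pupil), pairs[7].marker, atol=1e-8
        )

    def test_affine_data_kills_quadratic_coefficients(self):
        cx = np.array([10.0, 2.0, 0.5, 0.0, 0.0, 0.0])
        cy = np.array([-5.0, 0.1, 1.5, 0.0, 0.0, 0.0])
        model = fit_mapping(_quadratic_pairs(40, coeffs=(cx, cy)))
        # standardized-basis cross/square terms vanish for affine truth
        assert np.abs(model.coeff_x[3:]).max() <= 1e-8
        assert np.abs(model.coeff_y[3:]).max() <= 1e-8

    def test_extrapolation_flagged_outside_hull(self):
        model = fit_mapping(_quadratic_pairs(40))
        _, flag_out = predict(model, (0.0, 0.0), return_flags=True)
        _, flag_in = predict(model, (320.0, 240.0), return_flags=True)
        assert flag_out and not flag_in

    def test_standardization_does_not_change_predictions(self):
        pairs = _quadratic_pairs(50, seed=2)
        m1 = fit_mapping(pairs, standardize=True)
        m2 = fit_mapping(pairs, standardize=False)
        probe = np.array([[250.0, 200.0], [400.0, 300.0], [320.0, 240.0]])
        np.testing.assert_allclose(predict(m1, probe), predict(m2, probe), atol=1e-9)

    @given(st.floats(-500, 500), st.floats(-500, 500))
    @settings(max_examples=25, deadline=None)
    def test_marker_offset_shifts_predictions_exactly(self, dx, dy):
        pairs = _quadratic_pairs(30, seed=1)
        shifted = [
            CalibrationPair(p.timestamp, p.pupil, (p.marker[0] + dx, p.marker[1] + dy))
            for p in pairs
        ]
        probe = (300.0, 250.0)
        base = predict(fit_mapping(pairs), probe)
        moved = predict(fit_mapping(shifted), probe)
        np.testing.assert_allclose(moved - base, [dx, dy], atol=1e-6)


class TestResiduals:
    def test_noiseless_residuals_are_zero(self):
        pairs = _quadratic_pairs(30)
        res = reprojection_residuals(fit_mapping(pairs), pairs)
        assert np.abs(res.vectors).max() <= 1e-8
        assert len(res) == 30

    def test_least_squares_residuals_sum_to_zero(self, noisy_session):
        pairs = pairs_from_table(noisy_session.table)
        res = reprojection_residuals(fit_mapping(pairs), pairs)
        # the basis contains the intercept, so residual components average out
        assert abs(res.vectors[:, 0].sum()) <= 1e-6
        assert abs(res.vectors[:, 1].sum()) <= 1e-6

    def test_nodes_sit_at_marker_centers(self):
        pairs = _quadratic_pairs(20)
        res = reprojection_residuals(fit_mapping(pairs), pairs)
        np.testing.assert_array_equal(res.node_xy, [p.marker for p in pairs])
        np.testing.assert_array_equal(res.node_t, [p.timestamp for p in pairs])
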