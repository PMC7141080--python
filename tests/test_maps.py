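import numpy as np
import pytest

from gazecal.calibration import ResidualSet, fit_mapping
from gazecal.correction import CorrectionField, idw_vector
from gazecal.maps import UncertaintyMap, accumulate, bump_render, error_map, project_contour
from gazecal.metrics import pairs_from_table

from conftest import brute_force_idw


def _circle(cx, cy, R, n=80):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + R * np.cos(th), cy + R * np.sin(th)])


class TestGaussianKernel:
    def test_single_sample_unit_mass(self):
        m = accumulate(UncertaintyMap("gaussian"), [(960.0, 540.0)])
        assert m.grid.sum() == pytest.approx(1.0, abs=1e-6)
        assert m.n_samples == 1

    def test_two_identical_samples_double_the_grid(self):
        m1 = accumulate(UncertaintyMap("gaussian"), [(400.0, 300.0)])
        m2 = accumulate(UncertaintyMap("gaussian"), [(400.0, 300.0)] * 2)
        np.testing.assert_allclose(m2.grid, 2 * m1.grid, atol=1e-12)

    def test_total_mass_tracks_sample_count(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform([300, 300], [1600, 800], (25, 2))
        m = accumulate(UncertaintyMap("gaussian"), pts)
        assert m.grid.sum() == pytest.approx(25.0, abs=1e-3)


class TestPolygonKernel:
    def test_disk_kernel_is_one_minus_rho_over_R(self):
        R = 200.0
        m = accumulate(UncertaintyMap("pupil-polygon"), [_circle(800, 500, R, n=200)])
        cx, cy = int(800 / m.factor), int(500 / m.factor)
        R_cells = R / m.factor
        for rho in (0, 10, 20, 30, 40):
            got = m.grid[cy, cx + rho]
            assert got == pytest.approx(1 - rho / R_cells, abs=1.5 / R_cells)

    def test_bigger_polygons_spread_more_mass(self):
        small = accumulate(UncertaintyMap("pupil-polygon"), [_circle(800, 500, 80)])
        big = accumulate(UncertaintyMap("pupil-polygon"), [_circle(800, 500, 240)])
        assert (big.grid > 0).sum() > 4 * (small.grid > 0).sum()
        assert big.grid.sum() > small.grid.sum()

    def test_degenerate_polygon_skipped_and_counted(self):
        line = np.array([[100.0, 100.0], [101.0, 100.0], [102.0, 100.0]])
        m = accumulate(UncertaintyMap("pupil-polygon"), [line])
        assert m.n_samples == 0 and m.n_skipped == 1


class TestBumpRender:
    def test_constant_map_is_uniform_mid_gray(self):
        out = bump_render(np.full((30, 40), 3.7))
        assert np.all(out == 0.5)

    def test_linear_ramp_is_uniform(self):
        ramp = np.tile(np.arange(50, dtype=float), (30, 1))
        out = bump_render(ramp)
        inner = out[1:-1, 1:-1]  # edges use one-sided differences
        assert np.ptp(inner) <= 1e-12

    def test_hemisphere_matches_analytic_lambert_at_probes(self):
        R, n = 40.0, 121
        yy, xx = np.mgrid[0:n, 0:n] - n // 2
        rho2 = xx**2 + yy**2
        h = np.where(rho2 < R**2, np.sqrt(np.maximum(R**2 - rho2, 0.0)), 0.0)
        az, el = 315.0, 45.0
        out = bump_render(h, az, el)
        # direct evaluation with analytic gradients, identical normalization
        gx = np.where(rho2 < R**2, -xx / np.maximum(h, 1e-12), 0.0)
        gy = np.where(rho2 < R**2, -yy / np.maximum(h, 1e-12), 0.0)
        light = np.array(
            [
                np.cos(np.deg2rad(el)) * np.cos(np.deg2rad(az)),
                np.cos(np.deg2rad(el)) * np.sin(np.deg2rad(az)),
                np.sin(np.deg2rad(el)),
            ]
        )
        shade = np.clip(
            (-gx * light[0] - gy * light[1] + light[2]) / np.sqrt(gx**2 + gy**2 + 1),
            0,
            None,
        )
        want = (shade - shade.min()) / (shade.max() - shade.min())
        c = n // 2
        for du, dv in [(0, 0), (10, 0), (0, 10), (-12, 5), (8, -8)]:
            assert out[c + dv, c + du] == pytest.approx(want[c + dv, c + du], abs=0.05)


class TestErrorMap:
    def test_zero_residuals_zero_map(self):
        f = CorrectionField(
            ResidualSet(np.array([[10.0, 10.0]]), np.array([0.0]), np.array([[0.0, 0.0]]))
        )
        assert error_map(f, factor=16).max() == 0.0

    def test_single_node_constant_norm(self):
        f = CorrectionField(
            ResidualSet(np.array([[500.0, 300.0]]), np.array([0.0]), np.array([[3.0, 4.0]]))
        )
        em = error_map(f, factor=16)
        np.testing.assert_allclose(em, 5.0)

    def test_two_nodes_match_brute_force_at_random_cells(self):
        xy = np.array([[100.0, 100.0], [900.0, 700.0]])
        vec = np.array([[1.0, 0.0], [0.0, 2.0]])
        f = CorrectionField(ResidualSet(xy, np.array([0.0, 1.0]), vec))
        em = error_map(f, factor=8)
        rng = np.random.default_rng(0)
        for _ in range(10):
            j, i = rng.integers(em.shape[0]), rng.integers(em.shape[1])
            p = ((i + 0.5) * 8, (j + 0.5) * 8)
            assert em[j, i] == pytest.approx(
                float(np.hypot(*brute_force_idw(xy, vec, p, 2.0))), abs=1e-9
            )

    def test_continuity_bound_between_adjacent_cells(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 1000, (12, 2))
        vec = rng.normal(0, 3, (12, 2))
        f = CorrectionField(ResidualSet(xy, np.arange(12.0), vec))
        em = error_map(f, factor=16)
        vmax = np.hypot(*vec.T).max()
        assert np.abs(np.diff(em, axis=0)).max() <= vmax
        assert np.abs(np.diff(em, axis=1)).max() <= vmax


class TestProjectContour:
    def test_affine_model_maps_polygon_without_fold(self, noiseless_session):
        pairs = pairs_from_table(noiseless_session.table)
        model = fit_mapping(pairs)
        contour = _circle(320, 240, 40, n=60)
        world, folded = project_contour(model, contour)
        assert not folded and world.shape == contour.shape

    def test_strong_quadratic_far_outside_hull_folds(self):
        from gazecal.calibration import MappingModel

        # x = u^2 folds the plane across u = 0: points u and -u coincide
        model = MappingModel(
            coeff_x=np.array([0.0, 0.0, 0.0, 0.0, 1.0, 0.0]),
            coeff_y=np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0]),
            norm_mean=np.zeros(2),
            norm_scale=np.ones(2),
            train_pupil_bbox=np.array([[1.0, -1.0], [2.0, 1.0]]),
        )
        # circle straddling the fold line maps onto a doubled-over arc
        contour = _circle(0.0, 0.0, 3.0, n=60)
        _, folded = project_contour(model, contour)
        assert folded

    def test_short_contour_rejected(self, noiseless_session):
        model = fit_mapping(pairs_from_table(noiseless_session.table))
        with pytest.raises(ValueError):
            project_contour(model, np.zeros((4, 2)))
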