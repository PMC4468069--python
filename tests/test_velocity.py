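"""Quadratic activation-surface fitting and the velocity-vector relation."""

import math

import numpy as np
import pytest

import meamap as m


def _map_from_times(layout, times, pad=2.0):
    vals = np.array(list(times.values()))
    window = m.AnalysisWindow(float(vals.min()) - pad, float(np.ptp(vals)) + 2 * pad)
    return m.ActivationMap(times, {lab: -100.0 for lab in times}, window)


class TestSurfaceFit:
    def test_exact_quadratic_recovered(self, layout, quadratic_truth_map):
        coeffs, amap = quadratic_truth_map
        fit = m.fit_activation_surface(amap, layout)
        np.testing.assert_allclose(fit.coefficients, coeffs, rtol=1e-9, atol=1e-15)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_plane_wave_linear_truth(self, layout):
        # t = x / v with v = 200 mm/s -> d = 0.005 ms/um, a=b=c=e=0, f=t0
        xy = layout.coords()
        times = {lab: 3.0 + x / 200.0 for lab, (x, _) in zip(layout.labels, xy)}
        fit = m.fit_activation_surface(_map_from_times(layout, times), layout)
        a, b, c, d, e, f = fit.coefficients
        assert abs(a) < 1e-12 and abs(b) < 1e-12 and abs(c) < 1e-12 and abs(e) < 1e-12
        assert d == pytest.approx(0.005, rel=1e-9)
        assert f == pytest.approx(3.0, rel=1e-9)

    def test_six_points_in_general_position_interpolate(self, rng):
        x = np.array([0.0, 200, 400, 100, 350, 50])
        y = np.array([0.0, 100, 50, 300, 250, 150])
        t = rng.normal(10, 1, 6)
        fit = m.fit_surface_to_points(x, y, t)
        assert max(abs(r) for r in fit.residuals.values()) < 1e-8

    def test_fewer_than_six_points_rejected(self, layout, quadratic_truth_map):
        _, amap = quadratic_truth_map
        with pytest.raises(ValueError, match="6"):
            m.fit_activation_surface(amap, layout, exclude=layout.labels[:55])

    def test_predicted_plus_residual_equals_observed(self, planar_map, layout):
        fit = m.fit_activation_surface(planar_map, layout)
        xy = layout.coords(fit.labels)
        pred = m.predict_time(fit, xy[:, 0], xy[:, 1])
        obs = np.array([planar_map.times[lab] for lab in fit.labels])
        res = np.array([fit.residuals[lab] for lab in fit.labels])
        np.testing.assert_allclose(pred + res, obs, atol=1e-9)

    def test_residuals_orthogonal_to_design(self, planar_map, layout):
        fit = m.fit_activation_surface(planar_map, layout)
        xy = layout.coords(fit.labels)
        mx, my, sx, sy = fit.scaling
        u, v = (xy[:, 0] - mx) / sx, (xy[:, 1] - my) / sy
        X = np.column_stack([u * u, v * v, u * v, u, v, np.ones_like(u)])
        res = np.array([fit.residuals[lab] for lab in fit.labels])
        obs = np.array([planar_map.times[lab] for lab in fit.labels])
        assert np.max(np.abs(X.T @ res)) <= 1e-6 * np.linalg.norm(obs)

    def test_ols_local_optimality(self, layout, rng):
        xy = layout.coords()
        times = {lab: 5 + x / 300 + y / 500 + rng.normal(0, 0.05)
                 for lab, (x, y) in zip(layout.labels, xy)}
        amap = _map_from_times(layout, times)
        fit = m.fit_activation_surface(amap, layout)
        t = np.array([times[lab] for lab in fit.labels])
        mx, my, sx, sy = fit.scaling
        u, v = (xy[:, 0] - mx) / sx, (xy[:, 1] - my) / sy
        X = np.column_stack([u * u, v * v, u * v, u, v, np.ones_like(u)])
        beta = np.linalg.lstsq(X, t, rcond=None)[0]
        rss0 = np.sum((t - X @ beta) ** 2)
        for j in range(6):
            for dv in (1e-3, -1e-3):
                pert = beta.copy()
                pert[j] += dv
                assert np.sum((t - X @ pert) ** 2) > rss0


class TestGradientAndPrediction:
    def test_constant_surface(self):
        fit = m.fit_surface_to_points(
            np.array([0.0, 200, 400, 100, 350, 50]),
            np.array([0.0, 100, 50, 300, 250, 150]),
            np.full(6, 7.5),
        )
        assert m.predict_time(fit, 123.0, 456.0) == pytest.approx(7.5)
        tx, ty = m.surface_gradient(fit, 123.0, 456.0)
        assert abs(tx) < 1e-12 and abs(ty) < 1e-12

    def test_gradient_at_origin_is_d_e(self, layout, quadratic_truth_map):
        coeffs, amap = quadratic_truth_map
        fit = m.fit_activation_surface(amap, layout)
        tx, ty = m.surface_gradient(fit, 0.0, 0.0)
        assert tx == pytest.approx(coeffs[3], rel=1e-8)
        assert ty == pytest.approx(coeffs[4], rel=1e-8)

    def test_gradient_matches_finite_differences(self, planar_map, layout):
        fit = m.fit_activation_surface(planar_map, layout)
        h = 1.0  # um
        for x, y in [(0.0, 0.0), (700.0, 700.0), (1400.0, 200.0)]:
            tx, ty = m.surface_gradient(fit, x, y)
            fx = (m.predict_time(fit, x + h, y) - m.predict_time(fit, x - h, y)) / (2 * h)
            fy = (m.predict_time(fit, x, y + h) - m.predict_time(fit, x, y - h)) / (2 * h)
            assert tx == pytest.approx(fx, rel=1e-6, abs=1e-15)
            assert ty == pytest.approx(fy, rel=1e-6, abs=1e-15)


class TestVelocityVectors:
    def test_bayly_identity_v_dot_grad_is_one(self, planar_map, layout):
        fit = m.fit_activation_surface(planar_map, layout)
        field = m.velocity_vectors(fit, layout)
        for lab in field.labels:
            dot = field.vx[lab] * field.tx[lab] + field.vy[lab] * field.ty[lab]
            assert abs(dot - 1.0) <= 1e-9
            grad_mag = math.hypot(field.tx[lab], field.ty[lab])
            assert abs(field.speed[lab] - 1.0 / grad_mag) <= 1e-12

    def test_plane_wave_closed_form_vectors(self, layout):
        # 200 mm/s at 30 deg -> every vector (173.205..., 100.0) mm/s
        th = math.radians(30.0)
        xy = layout.coords()
        times = {lab: 5.0 + (x * math.cos(th) + y * math.sin(th)) / 200.0
                 for lab, (x, y) in zip(layout.labels, xy)}
        fit = m.fit_activation_surface(_map_from_times(layout, times), layout)
        field = m.velocity_vectors(fit, layout)
        for lab in field.labels:
            assert field.vx[lab] == pytest.approx(200.0 * math.cos(th), rel=1e-6)
            assert field.vy[lab] == pytest.approx(100.0, rel=1e-6)

    def test_doubling_times_halves_speeds(self, layout, quadratic_truth_map):
        _, amap = quadratic_truth_map
        fit1 = m.fit_activation_surface(amap, layout)
        doubled = _map_from_times(layout, {lab: 2 * t for lab, t in amap.times.items()})
        fit2 = m.fit_activation_surface(doubled, layout)
        f1 = m.velocity_vectors(fit1, layout)
        f2 = m.velocity_vectors(fit2, layout)
        for lab in f1.labels:
            assert f2.speed[lab] == pytest.approx(f1.speed[lab] / 2, rel=1e-6)

    def test_stationary_surface_rejected(self):
        fit = m.SurfaceFit((0.0,) * 6, ("a",), {"a": 0.0}, 0.0, (0, 0, 1, 1))
        with pytest.raises(ValueError, match="stationary"):
            m.velocity_vectors(fit, m.standard_layout())

    def test_mean_is_permutation_invariant_and_arithmetic(self, planar_map, layout):
        fit = m.fit_activation_surface(planar_map, layout)
        field = m.velocity_vectors(fit, layout)
        speeds = [field.speed[lab] for lab in field.labels]
        assert m.mean_conduction_velocity(field) == pytest.approx(np.mean(speeds))
        assert m.mean_conduction_velocity(field) == pytest.approx(
            np.mean(speeds[::-1]))


class TestEquivariance:
    @staticmethod
    def _fit_field(layout, times):
        amap = _map_from_times(layout, times)
        fit = m.fit_activation_surface(amap, layout)
        return m.velocity_vectors(fit, layout)

    def test_rotation_equivariance(self, layout, quadratic_truth_map):
        _, amap = quadratic_truth_map
        base = self._fit_field(layout, amap.times)
        phi = math.radians(37.0)
        R = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        rotated = layout.replace_positions(
            {lab: tuple(R @ np.array(p)) for lab, p in layout.positions.items()})
        rot = self._fit_field(rotated, amap.times)
        for lab in base.labels:
            v = R @ np.array([base.vx[lab], base.vy[lab]])
            assert rot.vx[lab] == pytest.approx(v[0], rel=1e-6, abs=1e-6)
            assert rot.vy[lab] == pytest.approx(v[1], rel=1e-6, abs=1e-6)

    def test_translation_invariance(self, layout, quadratic_truth_map):
        _, amap = quadratic_truth_map
        base = self._fit_field(layout, amap.times)
        moved = layout.replace_positions(
            {lab: (p[0] + 3210.0, p[1] - 987.0) for lab, p in layout.positions.items()})
        shifted = self._fit_field(moved, amap.times)
        for lab in base.labels:
            assert shifted.vx[lab] == pytest.approx(base.vx[lab], rel=1e-6, abs=1e-6)
            assert shifted.vy[lab] == pytest.approx(base.vy[lab], rel=1e-6, abs=1e-6)

    def test_subset_of_exact_quadratic_leaves_coefficients_unchanged(
            self, layout, quadratic_truth_map, rng):
        coeffs, amap = quadratic_truth_map
        full = m.fit_activation_surface(amap, layout)
        for n in (10, 30, 54):
            drop = rng.choice(layout.labels, size=n, replace=False)
            sub = m.fit_activation_surface(amap, layout, exclude=drop)
            np.testing.assert_allclose(sub.coefficients, full.coefficients,
                                       rtol=1e-9, atol=1e-16)


class TestResidualDiagnostics:
    def test_exact_model_gives_zero_residuals(self, layout, quadratic_truth_map):
        _, amap = quadratic_truth_map
        fit = m.fit_activation_surface(amap, layout)
        diag = m.residual_diagnostics(fit, layout)
        assert diag.mean == pytest.approx(0.0, abs=1e-12)
        assert diag.sd == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(diag.shapiro_w)

    def test_residual_mean_zero_with_constant_column(self, planar_map, layout):
        fit = m.fit_activation_surface(planar_map, layout)
        diag = m.residual_diagnostics(fit, layout)
        assert abs(diag.mean) <= 1e-9

    def test_residual_sd_tracks_noise_sigma(self, layout):
        # OLS residual SD underestimates sigma by sqrt((n-p)/n); 25% tolerance
        sigma = 0.2
        xy = layout.coords()
        sds = []
        rng = np.random.default_rng(777)
        for _ in range(200):
            times = {lab: 5 + x / 300 + y / 500 + rng.normal(0, sigma)
                     for lab, (x, y) in zip(layout.labels, xy)}
            fit = m.fit_activation_surface(_map_from_times(layout, times), layout)
            sds.append(m.residual_diagnostics(fit, layout).sd)
        assert abs(np.mean(sds) - sigma) <= 0.25 * sigma

    def test_pairs_expose_predicted_and_residual(self, planar_map, layout):
        fit = m.fit_activation_surface(planar_map, layout)
        diag = m.residual_diagnostics(fit, layout)
        assert len(diag.pairs) == fit.n_points
        lab, pred, res = diag.pairs[0]
        assert pred + res == pytest.approx(planar_map.times[lab], abs=1e-9)
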