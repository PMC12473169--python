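import warnings

import numpy as np
import pytest
from numpy.polynomial import polynomial as npoly

from hemisurf.errors import ExtrapolationWarning, FitError
from hemisurf.io import RadialSection, SectionSet
from hemisurf.reconstruction import (CONCAVE_BOUNDARY, CONVEX_BOUNDARY,
                                     RadialSurfaceModel, SurfaceModel,
                                     build_matrix_A, eval_boundary_poly,
                                     eval_surface, fit_coefficient_curves,
                                     fit_section, reconstruct)


def normal_equations_fit(t, z, order):
    """Independent brute-force least squares: solve (V'V) a = V'z."""
    V = np.vander(t, order + 1, increasing=True)
    return np.linalg.solve(V.T @ V, V.T @ z)


class TestFitSection:
    def test_exact_parabola_recovered_after_unscaling(self):
        xs = np.array([-1, -0.5, 0, 0.5, 1.0])
        sec = RadialSection(angle=0.0, xs=xs, zs=xs**2)
        fit = fit_section(sec, order_n=2)
        np.testing.assert_allclose(fit.coeffs_unscaled, [0, 0, 1], atol=1e-9)
        assert fit.rms_residual < 1e-12

    def test_constant_profile(self):
        xs = np.linspace(-2, 2, 5)
        fit = fit_section(RadialSection(angle=0.0, xs=xs, zs=np.full(5, 7.0)), 3)
        np.testing.assert_allclose(fit.coeffs_unscaled, [7, 0, 0, 0], atol=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        xs = np.sort(rng.uniform(-1, 1, 50))
        zs = 0.3 - xs + 0.5 * xs**3 + rng.normal(0, 0.1, 50)
        sec = RadialSection(angle=0.0, xs=xs, zs=zs)
        fit = fit_section(sec, order_n=4, x_scale=(0.0, 1.0))
        oracle = normal_equations_fit(xs, zs, 4)
        np.testing.assert_allclose(fit.coeffs, oracle, atol=1e-8)

    def test_underdetermined_rejected(self):
        sec = RadialSection(angle=0.0, xs=[-1, 0, 1], zs=[0, 1, 0])
        with pytest.raises(FitError, match="need >="):
            fit_section(sec, order_n=5)

    def test_unscaled_fitting_warns(self):
        xs = np.linspace(-1, 1, 30)
        sec = RadialSection(angle=0.0, xs=xs, zs=xs**2)
        with pytest.warns(UserWarning, match="unscaled"):
            fit_section(sec, order_n=2, scale=False)


class TestBuildMatrixA:
    def test_angle_invariant_surface_gives_equal_rows(self):
        xs = np.linspace(-1, 1, 9)
        secs = tuple(
            RadialSection(angle=a, xs=xs, zs=1 - xs**2)
            for a in np.arange(6) * np.pi / 6
        )
        A = build_matrix_A(SectionSet(sections=secs), order_n=2)
        for row in A.values[1:]:
            np.testing.assert_allclose(row, A.values[0], atol=1e-12)

    def test_shape_two_sections_order_one(self):
        secs = tuple(
            RadialSection(angle=a, xs=[-1.0, 1.0], zs=[0.0, 1.0])
            for a in (0.0, np.pi / 2)
        )
        A = build_matrix_A(SectionSet(sections=secs), order_n=1)
        assert A.values.shape == (2, 2)

    def test_constant_coefficient_tracks_angle(self):
        # z(x, y) = y + x^2: the constant term of each section equals y_k
        xs = np.linspace(-1, 1, 9)
        angles = np.arange(6) * np.pi / 6
        secs = tuple(RadialSection(angle=a, xs=xs, zs=a + xs**2) for a in angles)
        A = build_matrix_A(SectionSet(sections=secs), order_n=2)
        # constant term in raw x equals the scaled-basis value at xhat=0 since
        # the shared scale here is centered at 0
        const_terms = [npoly.polyval(0.0, row) for row in A.values]
        np.testing.assert_allclose(const_terms, angles, atol=1e-9)

    def test_failing_section_reports_index(self):
        secs = (
            RadialSection(angle=0.0, xs=np.linspace(-1, 1, 9), zs=np.zeros(9)),
            RadialSection(angle=1.0, xs=[-1.0, 1.0], zs=[0.0, 0.0]),
        )
        with pytest.raises(FitError, match="section 1"):
            build_matrix_A(SectionSet(sections=secs), order_n=4)


class TestFitCoefficientCurves:
    def _matrix_a(self, values, angles):
        from hemisurf.reconstruction import CoeffMatrixA

        values = np.asarray(values, dtype=float)
        return CoeffMatrixA(values=values, angles=np.asarray(angles, dtype=float),
                            x_scale=(0.0, 1.0), order_n=values.shape[1] - 1)

    def test_constant_columns_give_constant_rows(self):
        angles = np.arange(6) * np.pi / 6
        A = self._matrix_a(np.tile([[2.0, -1.0, 0.5]], (6, 1)), angles)
        model = fit_coefficient_curves(A, order_m=3)
        np.testing.assert_allclose(model.B[:, 0], [2.0, -1.0, 0.5], atol=1e-12)
        np.testing.assert_allclose(model.B[:, 1:], 0.0, atol=1e-12)

    def test_linear_column_exact_two_term_recovery(self):
        angles = np.linspace(0.0, 1.0, 5)
        A = self._matrix_a(np.column_stack([3.0 + 2.0 * angles]), angles)
        model = fit_coefficient_curves(A, order_m=1)
        # exact linear fit: evaluating a_0(y) must reproduce the generator
        for y in angles:
            got = float(eval_surface(model, 0.0, y))
            assert abs(got - (3.0 + 2.0 * y)) < 1e-12

    def test_rows_match_per_row_oracle(self, rng):
        angles = np.linspace(0.0, 2.0, 7)
        vals = rng.standard_normal((7, 3))
        A = self._matrix_a(vals, angles)
        model = fit_coefficient_curves(A, order_m=3)
        yhat = (angles - 1.0) / 1.0
        for i in range(3):
            oracle = normal_equations_fit(yhat, vals[:, i], 3)
            np.testing.assert_allclose(model.B[i], oracle, atol=1e-8)

    def test_underdetermined_second_layer(self):
        A = self._matrix_a(np.zeros((3, 2)), [0.0, 0.5, 1.0])
        with pytest.raises(FitError, match="second-layer"):
            fit_coefficient_curves(A, order_m=5)


class TestEvalSurface:
    def _model(self, B, n, m):
        return SurfaceModel(B=B, order_n=n, order_m=m,
                            x_scale=(0.0, 1.0), y_scale=(0.0, 1.0))

    def test_constant_model(self):
        m = self._model(np.array([[4.2]]), 0, 0)
        assert eval_surface(m, 0.3, -0.8) == pytest.approx(4.2, abs=1e-15)

    def test_roundtrip_on_sampled_polynomial(self, poly_surface_sections):
        ss, f = poly_surface_sections
        model = reconstruct(ss, order_n=12, order_m=5)
        for sec in ss:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ExtrapolationWarning)
                pred = eval_surface(model, sec.xs, np.full_like(sec.xs, sec.angle))
            np.testing.assert_allclose(pred, sec.zs, atol=1e-8)

    def test_matches_term_by_term_oracle(self, rng):
        B = rng.standard_normal((4, 3))
        model = self._model(B, 3, 2)
        x, y = 0.37, -0.58
        oracle = sum(
            B[i, k] * (y**k) * (x**i) for i in range(4) for k in range(3)
        )
        assert eval_surface(model, x, y) == pytest.approx(oracle, abs=1e-12)

    def test_extrapolation_flagged(self):
        m = self._model(np.ones((2, 2)), 1, 1)
        with pytest.warns(ExtrapolationWarning):
            eval_surface(m, 2.0, 0.0)


class TestReconstruct:
    def test_shape_contract_13x6(self, hemisphere_sections):
        model = reconstruct(hemisphere_sections, order_n=12, order_m=5)
        assert model.B.shape == (13, 6)

    def test_shape_contract_9x6(self, hemisphere_sections):
        model = reconstruct(hemisphere_sections, order_n=8, order_m=5)
        assert model.B.shape == (9, 6)

    def test_three_sections_order_five_underdetermined(self):
        xs = np.linspace(-1, 1, 20)
        secs = tuple(
            RadialSection(angle=a, xs=xs, zs=1 - xs**2)
            for a in (0.0, 1.0, 2.0)
        )
        with pytest.raises(FitError, match="second-layer"):
            reconstruct(SectionSet(sections=secs), order_n=4, order_m=5)

    def test_rms_monotone_in_order(self, hemisphere_sections):
        rms = []
        for n in (4, 8, 12):
            res = RadialSurfaceModel(hemisphere_sections, order_x=n, order_angle=5).fit()
            rms.append(res.rms_global)
        assert rms[0] >= rms[1] >= rms[2]

    def test_results_object_reports_residuals(self, hemisphere_sections):
        res = RadialSurfaceModel(hemisphere_sections).fit()
        assert len(res.rms_per_section) == 6
        assert res.rms_global >= 0
        txt = res.summary()
        assert "B matrix shape:      13 x 6" in txt

    def test_save_load_roundtrip(self, tmp_path, hemisphere_sections):
        from hemisurf.io import load_surface_model

        res = RadialSurfaceModel(hemisphere_sections).fit()
        res.save(tmp_path / "model")
        back = load_surface_model(tmp_path / "model")
        assert np.array_equal(back.B, res.surface.B)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            assert eval_surface(back, 3.0, 0.5) == pytest.approx(
                res.predict(3.0, 0.5), abs=1e-12)


class TestBoundaryPolynomials:
    @pytest.mark.parametrize(
        "poly,expected", [(CONCAVE_BOUNDARY, 0.023), (CONVEX_BOUNDARY, 0.011)]
    )
    def test_constant_terms_at_origin(self, poly, expected):
        assert eval_boundary_poly(poly, 0.0) == pytest.approx(expected, abs=1e-12)

    def test_additive_correction_G(self):
        from hemisurf.reconstruction import BoundaryPoly

        shifted = BoundaryPoly(coeffs=CONCAVE_BOUNDARY.coeffs, G=1.0)
        assert eval_boundary_poly(shifted, 0.0) == pytest.approx(1.023, abs=1e-12)

    def test_degrees(self):
        assert CONCAVE_BOUNDARY.degree == 3
        assert CONVEX_BOUNDARY.degree == 5
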