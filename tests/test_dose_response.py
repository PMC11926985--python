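"""Dose-response fitting: independent oracles, invariances, coverage."""

import numpy as np
import pytest
from scipy import optimize

from cytodose.dose_response import (
    DoseResponseCurve,
    DoseResponsePoint,
    chi2_goodness_of_fit,
    evaluate_curve,
    fit_dose_response,
    invert_curve,
    poisson_deviance,
    z_compare,
)
from cytodose.errors import DomainError
from cytodose.synthetic import CohortConfig, simulate_cohort
from cytodose.dose_response import points_from_distributions


def _points(doses, cells, yields):
    return [
        DoseResponsePoint(d, n, int(round(y * n)))
        for d, n, y in zip(doses, cells, yields)
    ]


class TestFit:
    def test_noiseless_linear_identifiability(self):
        c_true, a_true = 0.002, 0.45
        doses = [0.0, 0.1, 0.2, 0.4]
        # 10000 cells/point makes every exact yield an integer count
        exact = _points(doses, [10000] * 4,
                        [c_true + a_true * d for d in doses])
        curve, _ = fit_dose_response(exact, "linear")
        assert curve.c == pytest.approx(c_true, rel=1e-8)
        assert curve.alpha == pytest.approx(a_true, rel=1e-8)

    def test_matches_brute_force_deviance_minimizer(self):
        """4-point toy data: IRLS must agree with an independent
        grid-then-polish minimization of the Poisson deviance."""
        pts = [DoseResponsePoint(0.0, 500, 2),
               DoseResponsePoint(0.1, 400, 25),
               DoseResponsePoint(0.25, 450, 60),
               DoseResponsePoint(0.5, 300, 85)]
        curve, _ = fit_dose_response(pts, "linear")

        grid_c = np.linspace(0.0005, 0.02, 50)
        grid_a = np.linspace(0.2, 0.9, 50)
        best = min(
            ((c, a) for c in grid_c for a in grid_a),
            key=lambda p: poisson_deviance(pts, np.array(p), "linear"),
        )
        polished = optimize.minimize(
            lambda p: poisson_deviance(pts, p, "linear"),
            x0=np.array(best), method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
        )
        assert curve.c == pytest.approx(polished.x[0], abs=1e-6)
        assert curve.alpha == pytest.approx(polished.x[1], abs=1e-6)

    def test_deviance_optimal_against_local_grid(self):
        pts = [DoseResponsePoint(0.0, 300, 1), DoseResponsePoint(0.2, 300, 25),
               DoseResponsePoint(0.4, 300, 52)]
        curve, _ = fit_dose_response(pts, "linear")
        d_opt = poisson_deviance(pts, curve.coefficients, "linear")
        for dc in np.linspace(-0.002, 0.002, 50):
            for da in np.linspace(-0.05, 0.05, 50):
                trial = curve.coefficients + np.array([dc, da])
                if np.all(trial > 0):
                    assert d_opt <= poisson_deviance(pts, trial, "linear") + 1e-10

    def test_agrees_with_statsmodels_glm(self, dca_dists):
        """Independent route: identity-link Poisson GLM on the yields with
        cell-count variance weights (statsmodels)."""
        sm = pytest.importorskip("statsmodels.api")
        pts = points_from_distributions(dca_dists)
        curve, _ = fit_dose_response(pts, "linear")
        X = np.column_stack([np.ones(len(pts)), [p.dose_Gy for p in pts]])
        y = np.array([p.yield_per_cell for p in pts])
        w = np.array([p.cells for p in pts], dtype=float)
        fam = sm.families.Poisson(link=sm.families.links.Identity())
        res = sm.GLM(y, X, family=fam, var_weights=w).fit(
            start_params=[0.001, 0.4])
        assert curve.c == pytest.approx(res.params[0], abs=1e-7)
        assert curve.alpha == pytest.approx(res.params[1], abs=1e-7)
        assert curve.se_alpha == pytest.approx(res.bse[1], rel=1e-4)

    @pytest.mark.parametrize("k", [4, 16])
    def test_se_shrinks_as_sqrt_of_cell_scale(self, k):
        doses = [0.0, 0.1, 0.2, 0.4]
        yields = [0.002 + 0.5 * d for d in doses]
        base, _ = fit_dose_response(_points(doses, [2000] * 4, yields), "linear")
        scaled, _ = fit_dose_response(
            _points(doses, [2000 * k] * 4, yields), "linear")
        assert scaled.se_alpha == pytest.approx(base.se_alpha / np.sqrt(k), rel=1e-6)
        assert scaled.se_c == pytest.approx(base.se_c / np.sqrt(k), rel=1e-6)

    def test_wald_interval_coverage_on_synthetic_cohorts(self):
        """95% Wald intervals for alpha cover the truth in >= 90% of 200
        seeded replicates of the pooled-design compound-Poisson cohort."""
        alpha_true = 0.467
        hits = 0
        for rep in range(200):
            cohort = simulate_cohort(CohortConfig(seed=10_000 + rep))
            curve, _ = fit_dose_response(
                points_from_distributions(cohort), "linear")
            lo = curve.alpha - 1.96 * curve.se_alpha
            hi = curve.alpha + 1.96 * curve.se_alpha
            hits += lo <= alpha_true <= hi
        assert hits / 200 >= 0.90

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([DoseResponsePoint(0.1, 100, 5)], "linear")


class TestEvaluateInvert:
    def test_intercept_and_direct_arithmetic(self):
        lin = DoseResponseCurve("linear", c=0.0008, alpha=0.467)
        assert evaluate_curve(lin, 0.0) == pytest.approx(0.0008)
        assert evaluate_curve(lin, 0.408) == pytest.approx(0.0008 + 0.467 * 0.408)
        lq = DoseResponseCurve("linear_quadratic", c=0.0, alpha=1.0, beta=1.0)
        assert evaluate_curve(lq, 2.0) == pytest.approx(6.0)

    def test_linear_inversion_closed_form(self):
        lin = DoseResponseCurve("linear", c=0.0, alpha=0.5)
        assert invert_curve(lin, 0.1) == pytest.approx(0.2)

    def test_lq_root_verified_by_forward_evaluation(self):
        lq = DoseResponseCurve("linear_quadratic", c=0.0, alpha=0.07, beta=0.06)
        d = invert_curve(lq, 0.1)
        assert evaluate_curve(lq, d) == pytest.approx(0.1, abs=1e-12)

    def test_background_yield_maps_to_zero_dose(self):
        for curve in (DoseResponseCurve("linear", c=0.01, alpha=0.5),
                      DoseResponseCurve("linear_quadratic", c=0.01,
                                        alpha=0.07, beta=0.06)):
            assert invert_curve(curve, 0.01) == 0.0

    @pytest.mark.parametrize("dose", [1e-4, 0.05, 0.3, 2.0])
    @pytest.mark.parametrize("model,beta", [("linear", None),
                                            ("linear_quadratic", 0.06)])
    def test_round_trip(self, dose, model, beta):
        curve = DoseResponseCurve(model, c=0.001, alpha=0.47, beta=beta)
        assert invert_curve(curve, evaluate_curve(curve, dose)) == pytest.approx(
            dose, abs=1e-10)

    def test_yield_below_background_is_domain_error(self):
        with pytest.raises(DomainError):
            invert_curve(DoseResponseCurve("linear", c=0.01, alpha=0.5), 0.005)


class TestZCompare:
    @pytest.mark.parametrize("a1,s1,a2,s2,expected", [
        (0.789, 0.045, 0.467, 0.015, 6.79),   # DCA slopes, 64 vs 31 meV
        (0.615, 0.052, 0.298, 0.043, 4.70),   # micronucleus slopes
    ])
    def test_published_slope_comparisons(self, a1, s1, a2, s2, expected):
        z, p = z_compare(a1, s1, a2, s2)
        assert z == pytest.approx(expected, abs=0.005)
        assert p < 0.01

    def test_equal_estimates(self):
        z, p = z_compare(0.5, 0.1, 0.5, 0.2)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            z_compare(1.0, 0.0, 2.0, 0.1)


class TestChi2:
    def test_perfect_fit(self):
        curve = DoseResponseCurve("linear", c=0.01, alpha=0.5)
        pts = _points([0.0, 0.1, 0.2, 0.3], [1000] * 4,
                      [evaluate_curve(curve, d) for d in (0.0, 0.1, 0.2, 0.3)])
        chi2, dof, p = chi2_goodness_of_fit(pts, curve)
        assert chi2 == pytest.approx(0.0, abs=1e-18)
        assert dof == 2
        assert p == pytest.approx(1.0)

    def test_three_point_hand_computation(self):
        curve = DoseResponseCurve("linear", c=0.0, alpha=0.5)
        pts = [DoseResponsePoint(0.1, 100, 6),
               DoseResponsePoint(0.2, 200, 18),
               DoseResponsePoint(0.4, 100, 22)]
        expected = sum(
            n * (x / n - 0.5 * d) ** 2 / (0.5 * d)
            for d, n, x in [(0.1, 100, 6), (0.2, 200, 18), (0.4, 100, 22)]
        )
        chi2, dof, _ = chi2_goodness_of_fit(pts, curve)
        assert chi2 == pytest.approx(expected, rel=1e-12)
        assert dof == 1

    def test_saturated_dof_flagged(self):
        curve = DoseResponseCurve("linear", c=0.001, alpha=0.5)
        pts = _points([0.1, 0.2], [100, 100], [0.06, 0.11])
        _, dof, p = chi2_goodness_of_fit(pts, curve)
        assert dof == 0
        assert np.isnan(p)
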