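"""Mixture regression: design matrices, fitting, diagnostics, contours."""

import numpy as np
import pytest

from snedds_screen.fixtures import reference_responses
from snedds_screen.geometry import CENTROID, TernaryPoint
from snedds_screen.mixture_model import (
    ModelFit,
    TermSpec,
    WorstCasePolicy,
    build_design_matrix,
    contour_grid,
    fit,
    fit_terms,
    flag_outliers,
    impute_failed,
    observed_vs_predicted,
    parse_term,
    pseudo_components,
    refit_without,
    significance,
    standard_terms,
)

AXES = ("Mig", "Gel", "PS8")


def random_simplex(rng, n):
    return rng.dirichlet(np.ones(3), size=n)


class TestTerms:
    def test_parse(self):
        assert parse_term("Mig") == TermSpec("main", ("Mig",))
        assert parse_term("Mig*PS8") == TermSpec("interaction", ("Mig", "PS8"))
        assert parse_term("Mig*Mig") == TermSpec("quadratic", ("Mig",))

    def test_standard_terms(self):
        assert len(standard_terms(AXES)) == 6
        assert len(standard_terms(AXES, quadratic=True)) == 9

    def test_invalid_terms_rejected(self):
        with pytest.raises(ValueError):
            TermSpec("interaction", ("Mig", "Mig"))


class TestDesignMatrix:
    def test_centroid_rows(self):
        X = build_design_matrix(
            [CENTROID],
            [parse_term("Mig"), parse_term("Gel"), parse_term("PS8"),
             parse_term("Mig*PS8")],
            AXES,
        )
        assert X[0] == pytest.approx([1 / 3, 1 / 3, 1 / 3, 1 / 9])

    def test_vertex_quadratic(self):
        X = build_design_matrix(
            [TernaryPoint(1, 0, 0)], [parse_term("Mig*Mig")], AXES
        )
        assert X[0, 0] == pytest.approx(1.0)

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError, match="unknown axis"):
            build_design_matrix([CENTROID], [parse_term("Oil")], AXES)


class TestImputeFailed:
    def test_fills_exactly_the_nd_rows(self):
        responses = reference_responses("celecoxib")
        completed = impute_failed(responses)
        imputed = [o for o in completed if o.imputed]
        assert {o.sample_id for o in imputed} == {2, 3, 5}
        for o in imputed:
            assert (o.size_nm, o.transmittance_pct, o.grade) == (300.0, 70.0, 5)

    def test_identity_without_nd(self):
        responses = reference_responses("fenofibrate")
        assert impute_failed(responses) == list(responses)

    def test_policy_override(self):
        responses = reference_responses("celecoxib")
        policy = WorstCasePolicy(size_nm=500.0, transmittance_pct=50.0, grade=5)
        filled = impute_failed(responses, policy)
        nd = next(o for o in filled if o.sample_id == 2)
        assert (nd.size_nm, nd.transmittance_pct) == (500.0, 50.0)


def normal_equations(X, y):
    """Independent oracle: solve X'X b = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFit:
    def test_matches_normal_equations_on_random_instances(self, rng):
        for _ in range(100):
            n, p = rng.integers(8, 30), rng.integers(2, 6)
            X = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            model = fit(X, y)
            assert model.coefficients == pytest.approx(
                normal_equations(X, y), abs=1e-8
            )

    def test_zero_noise_recovery(self, rng):
        points = random_simplex(rng, 20)
        terms = standard_terms(AXES)
        beta = rng.uniform(-5, 5, size=len(terms))
        y = build_design_matrix(points, terms, AXES) @ beta
        model = fit_terms(points, y, terms, AXES)
        assert model.coefficients == pytest.approx(beta, abs=1e-8)
        assert model.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_saturated_model_interpolates(self, rng):
        X = rng.standard_normal((4, 4)) + np.eye(4) * 3
        y = rng.standard_normal(4)
        model = fit(X, y)
        assert model.residuals == pytest.approx(np.zeros(4), abs=1e-8)
        assert model.r_squared == pytest.approx(1.0)

    def test_constant_response_r2_zero(self, rng):
        X = rng.standard_normal((10, 2))
        model = fit(X, np.full(10, 3.3))
        assert model.r_squared == 0.0

    def test_underdetermined_rejected(self, rng):
        with pytest.raises(ValueError, match="remove terms|add"):
            fit(rng.standard_normal((3, 5)), rng.standard_normal(3))

    def test_confidence_intervals_bracket_estimates(self, rng):
        X = rng.standard_normal((25, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 0.1 * rng.standard_normal(25)
        model = fit(X, y, alpha=0.95)
        assert np.all(model.conf_int[:, 0] <= model.coefficients)
        assert np.all(model.coefficients <= model.conf_int[:, 1])


class TestSignificance:
    def test_interval_excludes_zero_rule(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        model = fit(X, y)
        crafted = ModelFit(
            terms=model.terms,
            coefficients=np.array([3.7, 1.5, -1.6]),
            conf_int=np.array([[2.1, 5.3], [-1.0, 4.0], [-3.0, -0.2]]),
            alpha=0.95,
            r_squared=0.9,
            residuals=model.residuals,
            fitted=model.fitted,
            axes=model.axes,
            X=model.X,
            y=model.y,
        )
        assert significance(crafted) == [True, False, True]


class TestObservedVsPredicted:
    def test_perfect_fit_on_diagonal(self, rng):
        points = random_simplex(rng, 15)
        terms = standard_terms(AXES)
        y = build_design_matrix(points, terms, AXES) @ rng.uniform(-2, 2, 6)
        pairs, r2 = observed_vs_predicted(fit_terms(points, y, terms, AXES))
        assert pairs[:, 0] == pytest.approx(pairs[:, 1], abs=1e-8)
        assert r2 == pytest.approx(1.0)

    def test_pure_noise_r2_near_zero(self, rng):
        points = random_simplex(rng, 100)
        terms = [TermSpec("main", (a,)) for a in AXES]
        y = rng.standard_normal(100)
        _, r2 = observed_vs_predicted(fit_terms(points, y, terms, AXES))
        assert r2 < 0.15

    def test_noise_column_degrades_r2_across_replicates(self, rng):
        """Replacing a signal-bearing term's column with noise loses
        explanatory power on average (individual replicates may fluctuate,
        so the check is over 30 seeded replicates)."""
        terms = standard_terms(AXES)
        r2_full, r2_noise = [], []
        violations = 0
        for _ in range(30):
            points = random_simplex(rng, 30)
            X = build_design_matrix(points, terms, AXES)
            beta = rng.uniform(-3, 3, len(terms))
            beta[3] = 25.0  # the column to be replaced carries real signal
            y = X @ beta + 0.2 * rng.standard_normal(30)
            full = fit(X, y)
            Xn = X.copy()
            Xn[:, 3] = rng.standard_normal(30) * X[:, 3].std()
            noisy = fit(Xn, y)
            r2_full.append(full.r_squared)
            r2_noise.append(noisy.r_squared)
            violations += noisy.r_squared > full.r_squared + 1e-9
        assert np.mean(r2_noise) < np.mean(r2_full)
        assert violations <= 3


class TestOutliers:
    def test_displaced_point_flagged(self, rng):
        points = random_simplex(rng, 25)
        terms = standard_terms(AXES)
        X = build_design_matrix(points, terms, AXES)
        y = X @ rng.uniform(-2, 2, 6) + 0.05 * rng.standard_normal(25)
        resid_sd = 0.05
        y[7] += 10 * resid_sd
        model = fit(X, y)
        ids = list(range(1, 26))
        assert 8 in flag_outliers(model, 2.5, ids)

    def test_infinite_threshold_flags_nothing(self, rng):
        points = random_simplex(rng, 20)
        terms = standard_terms(AXES)
        y = rng.standard_normal(20)
        model = fit_terms(points, y, terms, AXES)
        assert flag_outliers(model, np.inf) == []

    def test_refit_without_excludes_rows(self, rng):
        points = random_simplex(rng, 20)
        terms = standard_terms(AXES)
        y = rng.standard_normal(20)
        model = fit_terms(points, y, terms, AXES)
        slim = refit_without(model, [1, 2])
        assert slim.X.shape[0] == 18
        assert slim.excluded_ids == (1, 2)

    def test_too_few_rows_rejected(self, rng):
        points = random_simplex(rng, 7)
        terms = standard_terms(AXES)
        model = fit_terms(points, rng.standard_normal(7), terms, AXES)
        with pytest.raises(ValueError):
            flag_outliers(model)


class TestContourGrid:
    def _fit_constant(self, rng):
        points = random_simplex(rng, 10)
        terms = [TermSpec("main", (a,)) for a in AXES]
        y = np.full(10, 4.2)
        return fit_terms(points, y, terms, AXES)

    def test_constant_surface_single_bin(self, rng):
        grid = contour_grid(self._fit_constant(rng), resolution=6, n_bins=5)
        assert np.all(grid.bins == 0)

    def test_resolution_11_gives_66_points(self, rng):
        grid = contour_grid(self._fit_constant(rng), resolution=11, n_bins=4)
        assert len(grid.values) == 66
        assert grid.points.shape == (66, 3)

    def test_linear_surface_bins_monotone_along_axis(self, rng):
        points = random_simplex(rng, 12)
        terms = [TermSpec("main", (a,)) for a in AXES]
        y = build_design_matrix(points, terms, AXES) @ np.array([10.0, 0.0, 0.0])
        model = fit_terms(points, y, terms, AXES)
        grid = contour_grid(model, resolution=11, n_bins=10)
        order = np.argsort(grid.points[:, 0])
        assert np.all(np.diff(grid.bins[order]) >= 0)

    def test_boundaries_partition_range(self, rng):
        points = random_simplex(rng, 12)
        terms = standard_terms(AXES)
        y = rng.standard_normal(12)
        grid = contour_grid(fit_terms(points, y, terms, AXES), 8, 6)
        assert grid.boundaries[0] == pytest.approx(grid.values.min())
        assert grid.boundaries[-1] == pytest.approx(grid.values.max())
        assert len(grid.boundaries) == 7
        assert grid.bins.min() >= 0 and grid.bins.max() <= 5


class TestPseudoComponents:
    def test_transform_and_bounds(self):
        Z = pseudo_components([TernaryPoint(0.5, 0.3, 0.2)], [0.1, 0.1, 0.1])
        assert Z[0] == pytest.approx([(0.4) / 0.7, (0.2) / 0.7, (0.1) / 0.7])
        with pytest.raises(ValueError):
            pseudo_components([CENTROID], [0.5, 0.5, 0.5])
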