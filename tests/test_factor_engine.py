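import numpy as np
import pytest

from heatvuln import (
    CorrelationMatrix,
    SyntheticConfig,
    factor_scores,
    generate,
    pca_from_correlation,
    pearson_matrix,
    retain_factors,
    retention_tolerance,
    varimax,
)
from heatvuln.factor_engine import (
    ConditioningError,
    DegenerateRowError,
    NonPositiveSemidefiniteError,
    RetentionError,
    rotate_retained,
    varimax_criterion,
)


def grid_best_criterion(loadings: np.ndarray, resolution: float = 1e-5) -> float:
    """Exhaustive rotation-angle search for the 2-factor varimax optimum.

    For k = 2 every orthogonal rotation is a planar rotation; the criterion has
    period pi/2 in the angle (column swap and sign changes leave it fixed), so
    a grid over [0, pi/2) covers all rotations.
    """
    p = loadings.shape[0]
    thetas = np.arange(0.0, np.pi / 2, resolution)
    c, s = np.cos(thetas), np.sin(thetas)
    x, y = loadings[:, 0], loadings[:, 1]
    rx = np.outer(x, c) + np.outer(y, s)
    ry = -np.outer(x, s) + np.outer(y, c)
    v = (
        ((rx**4).sum(axis=0) + (ry**4).sum(axis=0)) / p
        - ((rx**2).sum(axis=0) / p) ** 2
        - ((ry**2).sum(axis=0) / p) ** 2
    )
    return float(v.max())


class TestPca:
    def test_identity_spectrum(self):
        corr = CorrelationMatrix(tuple(f"v{i}" for i in range(10)), np.eye(10), "pearson")
        pca = pca_from_correlation(corr)
        np.testing.assert_allclose(pca.eigenvalues, np.ones(10), atol=1e-12)
        np.testing.assert_allclose(pca.variance_shares, np.full(10, 0.1), atol=1e-12)
        with pytest.raises(RetentionError):
            retain_factors(pca)  # no eigenvalue strictly above 1

    def test_two_by_two_closed_form(self):
        corr = CorrelationMatrix(("a", "b"), np.array([[1.0, 0.6], [0.6, 1.0]]), "pearson")
        pca = pca_from_correlation(corr)
        np.testing.assert_allclose(pca.eigenvalues, [1.6, 0.4], atol=1e-12)
        # loadings scaled by sqrt(eigenvalue): column SS equals the eigenvalue
        np.testing.assert_allclose(
            (pca.loadings**2).sum(axis=0), [1.6, 0.4], atol=1e-12
        )

    @pytest.mark.parametrize("stratum_fixture", ["urban_corr", "rural_corr"])
    def test_fixture_spectrum_sums_to_ten(self, stratum_fixture, request):
        corr = request.getfixturevalue(stratum_fixture)
        pca = pca_from_correlation(corr)
        assert pca.eigenvalues.sum() == pytest.approx(10.0, abs=1e-9)
        assert np.all(np.diff(pca.eigenvalues) <= 0)

    def test_non_psd_input_rejected(self):
        values = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        corr = CorrelationMatrix(("a", "b", "c"), values, "pearson")
        with pytest.raises(NonPositiveSemidefiniteError):
            pca_from_correlation(corr)

    def test_sign_convention_largest_component_positive(self, urban_corr):
        pca = pca_from_correlation(urban_corr)
        for j in range(pca.p):
            col = pca.loadings[:, j]
            if np.any(col != 0):
                assert col[np.argmax(np.abs(col))] >= 0


class TestRetention:
    def test_urban_fixture_retains_four(self, urban_corr):
        pca = pca_from_correlation(urban_corr)
        assert retain_factors(pca) == 4  # strict rule suffices for urban

    def test_rural_fixture_retains_four_with_rounding_tolerance(self, rural_corr):
        pca = pca_from_correlation(rural_corr)
        tol = retention_tolerance(rural_corr)
        assert 0 < tol < 0.05  # Weyl bound for 2-decimal print rounding
        # the 4th rural eigenvalue sits just under 1 on the rounded transcription
        assert 1.0 - tol < pca.eigenvalues[3] < 1.0
        assert retain_factors(pca, eigenvalue_tol=tol) == 4

    def test_tolerance_is_zero_for_computed_matrices(self, random_table):
        assert retention_tolerance(pearson_matrix(random_table)) == 0.0

    def test_negative_tolerance_rejected(self, urban_corr):
        with pytest.raises(ValueError):
            retain_factors(pca_from_correlation(urban_corr), eigenvalue_tol=-0.1)


class TestVarimax:
    def test_single_factor_is_identity(self):
        loadings = np.linspace(0.2, 0.9, 8).reshape(8, 1)
        sol = varimax(loadings)
        np.testing.assert_array_equal(sol.rotation, np.eye(1))
        np.testing.assert_allclose(sol.rotated_loadings, loadings, atol=1e-12)

    def test_perfect_simple_structure_is_a_fixed_point(self):
        loadings = np.zeros((8, 2))
        loadings[:4, 0] = 0.8
        loadings[4:, 1] = 0.7
        sol = varimax(loadings, kaiser_normalize=False)
        assert varimax_criterion(sol.rotated_loadings) == pytest.approx(
            varimax_criterion(loadings), abs=1e-12
        )
        # rotation is identity up to sign and column permutation
        assert np.allclose(np.abs(sol.rotation), np.eye(2), atol=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_two_factor_solution_matches_angle_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        loadings = rng.uniform(-0.9, 0.9, size=(10, 2))
        sol = varimax(loadings, kaiser_normalize=False)
        oracle = grid_best_criterion(loadings)
        assert varimax_criterion(sol.rotated_loadings) >= oracle - 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_varimax_implementation(self, seed):
        sm = pytest.importorskip("statsmodels.multivariate.factor_rotation")
        rng = np.random.default_rng(seed)
        loadings = rng.uniform(-0.9, 0.9, size=(10, 3))
        sol = varimax(loadings, kaiser_normalize=False)
        rotated_sm, _ = sm.rotate_factors(loadings, "varimax")
        assert varimax_criterion(sol.rotated_loadings) >= (
            varimax_criterion(rotated_sm) - 1e-6
        )

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_criterion_monotone_and_rotation_orthogonal(self, seed):
        rng = np.random.default_rng(seed)
        loadings = rng.uniform(-0.9, 0.9, size=(12, 4))
        sol = varimax(loadings)
        assert np.all(np.diff(sol.criterion_history) >= -1e-12)
        np.testing.assert_allclose(
            sol.rotation.T @ sol.rotation, np.eye(4), atol=1e-10
        )
        assert sol.converged

    @pytest.mark.parametrize("kaiser_normalize", [True, False])
    def test_communalities_conserved(self, urban_corr, kaiser_normalize):
        pca = pca_from_correlation(urban_corr)
        before = (pca.loadings[:, :4] ** 2).sum(axis=1)
        sol = rotate_retained(pca, 4, kaiser_normalize=kaiser_normalize)
        np.testing.assert_allclose(sol.communalities, before, atol=1e-10)

    def test_explained_total_invariant_under_rotation(self, rural_corr):
        pca = pca_from_correlation(rural_corr)
        sol = rotate_retained(pca, 4)
        assert sol.explained_total == pytest.approx(
            pca.eigenvalues[:4].sum() / 10.0, abs=1e-10
        )
        assert sol.per_factor_variance.sum() == pytest.approx(
            sol.explained_total, abs=1e-10
        )
        assert np.all(np.diff(sol.per_factor_variance) <= 1e-12)  # ordered by variance

    def test_zero_communality_row_rejected_under_normalization(self):
        loadings = np.vstack([np.zeros((1, 2)), np.full((7, 2), 0.5)])
        with pytest.raises(DegenerateRowError):
            varimax(loadings, kaiser_normalize=True)
        varimax(loadings, kaiser_normalize=False)  # fine without normalization

    def test_salience_flags_use_half_threshold(self, urban_corr):
        sol = rotate_retained(pca_from_correlation(urban_corr), 4)
        np.testing.assert_array_equal(
            sol.salient_mask, np.abs(sol.rotated_loadings) > 0.5
        )
        assert sol.salient_mask.any(axis=0).all()  # every factor has a defining variable


class TestFactorScores:
    def test_columns_standardized_exactly(self, synthetic_table):
        table, _ = synthetic_table
        corr = pearson_matrix(table)
        sol = rotate_retained(pca_from_correlation(corr), 4)
        scores = factor_scores(table, sol, corr)
        np.testing.assert_allclose(scores.scores.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(scores.scores.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_low_noise_two_factor_model_recovers_latents(self, make_table):
        loadings = np.zeros((10, 2))
        loadings[:5, 0] = 0.9
        loadings[5:, 1] = 0.9
        table, latent = generate(
            SyntheticConfig(
                n_counties=200,
                true_loadings=loadings,
                uniqueness_sd=0.01,
                seed=9,
                clip_to_percent=False,
            )
        )
        corr = pearson_matrix(table)
        pca = pca_from_correlation(corr)
        assert retain_factors(pca) == 2
        scores = factor_scores(table, rotate_retained(pca, 2), corr)
        r = np.corrcoef(scores.scores.T, latent.T)[:2, 2:]
        matched = np.abs(r).max(axis=0)
        assert np.all(matched > 0.99)

    def test_duplicated_counties_get_identical_scores(self, synthetic_table, schema):
        from heatvuln import IndicatorTable

        table, _ = synthetic_table
        doubled = IndicatorTable(
            table.county_ids + [c + "_dup" for c in table.county_ids],
            np.vstack([table.values, table.values]),
            schema,
        )
        corr = pearson_matrix(doubled)
        sol = rotate_retained(pca_from_correlation(corr), 4)
        scores = factor_scores(doubled, sol, corr)
        n = table.n
        np.testing.assert_allclose(scores.scores[:n], scores.scores[n:], atol=1e-10)

    def test_singular_scoring_matrix_rejected(self, synthetic_table):
        table, _ = synthetic_table
        corr = pearson_matrix(table)
        sol = rotate_retained(pca_from_correlation(corr), 4)
        near_singular = corr.values.copy()
        near_singular[0, 1] = near_singular[1, 0] = 1.0 - 1e-12
        near_singular[0, 2:] = near_singular[2:, 0] = near_singular[1, 2:]
        bad = CorrelationMatrix(corr.labels, near_singular, "pearson")
        with pytest.raises(ConditioningError):
            factor_scores(table, sol, bad)
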