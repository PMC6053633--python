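"""Correlation PCA, component retention, varimax rotation, B_n weight."""

import numpy as np
import pytest

from sedqual import ValidationError, bn_weight, fit_pca, retain_components, standardize
from sedqual.pca import rotate_model, varimax_criterion, varimax_rotate


def brute_correlation_eigen(X):
    """Independent oracle: dense eigendecomposition of the explicit correlation matrix."""
    R = np.corrcoef(np.asarray(X, float), rowvar=False)
    w, v = np.linalg.eigh(R)
    return w[::-1], v[:, ::-1]


class TestStandardize:
    def test_z_score_with_sample_sd(self):
        Z = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert Z[:, 0] == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(7)
        Z = standardize(rng.normal(size=(20, 3)))
        assert standardize(Z) == pytest.approx(Z)

    def test_constant_column_error_names_metal(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValidationError, match="Cu"):
            standardize(X, metals=["Cd", "Cu"])


class TestFitPca:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_dense_eigendecomposition_oracle(self, seed):
        X = np.random.default_rng(seed).lognormal(size=(6, 5))
        model = fit_pca(X)
        w_ref, v_ref = brute_correlation_eigen(X)
        assert model.eigenvalues == pytest.approx(w_ref, abs=1e-10)
        # loadings match eigvec * sqrt(eigval) up to column sign
        L_ref = v_ref * np.sqrt(np.clip(w_ref, 0, None))
        for k in range(5):
            assert min(
                np.abs(model.loadings[:, k] - L_ref[:, k]).max(),
                np.abs(model.loadings[:, k] + L_ref[:, k]).max(),
            ) < 1e-8

    @pytest.mark.parametrize("seed", [10, 11])
    def test_eigenvalues_sum_to_p(self, seed):
        X = np.random.default_rng(seed).normal(size=(8, 5))
        model = fit_pca(X)
        assert model.eigenvalues.sum() == pytest.approx(5.0, abs=1e-8)
        assert model.variability_pct == pytest.approx(model.eigenvalues / 5 * 100)
        assert model.cumulative_pct[-1] == pytest.approx(100.0, abs=1e-8)

    def test_perfectly_correlated_pair_is_rank_one(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        model = fit_pca(np.column_stack([x, 3 * x]))
        assert model.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-10)

    def test_orthogonal_contrasts_give_unit_eigenvalues(self):
        X = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        model = fit_pca(X)
        assert model.eigenvalues == pytest.approx([1.0, 1.0, 1.0], abs=1e-10)

    def test_loadings_reproduce_correlation_matrix(self):
        X = np.random.default_rng(42).normal(size=(10, 4))
        model = fit_pca(X)
        R = np.corrcoef(X, rowvar=False)
        assert model.loadings @ model.loadings.T == pytest.approx(R, abs=1e-8)

    def test_sign_convention_largest_loading_positive(self):
        X = np.random.default_rng(5).normal(size=(9, 4))
        model = fit_pca(X)
        for k in range(model.n_components):
            col = model.loadings[:, k]
            assert col[np.argmax(np.abs(col))] >= 0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValidationError):
            fit_pca(np.ones((1, 3)))


class TestRetention:
    def test_kaiser_keeps_eigenvalues_above_one(self, reference_eigenvalues):
        X = np.random.default_rng(3).normal(size=(6, 5))
        model = fit_pca(X)
        kept = retain_components(model, rule="kaiser")
        assert kept.n_components == max(1, int(np.sum(model.eigenvalues > 1)))
        assert (kept.eigenvalues > 1).all() or kept.n_components == 1

    def test_two_component_structure_of_study_models(self):
        from sedqual.fixtures import reference_factor_models

        for site, model in reference_factor_models().items():
            # both printed components exceed the Kaiser threshold
            assert (model.eigenvalues > 1).all(), site

    def test_fixed_k(self):
        model = fit_pca(np.random.default_rng(0).normal(size=(7, 4)))
        assert retain_components(model, rule="fixed", k=2).n_components == 2

    def test_k_beyond_p_rejected(self):
        model = fit_pca(np.random.default_rng(0).normal(size=(7, 4)))
        with pytest.raises(ValidationError):
            retain_components(model, rule="fixed", k=9)


def grid_search_varimax(L, resolution=1e-4):
    """Oracle for 2-column rotation: scan angles for the best varimax criterion."""
    best_val, best_theta = -np.inf, 0.0
    for theta in np.arange(0.0, np.pi / 2, resolution):
        c, s = np.cos(theta), np.sin(theta)
        value = varimax_criterion(L @ np.array([[c, -s], [s, c]]))
        if value > best_val:
            best_val, best_theta = value, theta
    return best_val, best_theta


class TestVarimax:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_column_rotation_matches_grid_search_oracle(self, seed):
        L = np.random.default_rng(seed).normal(size=(5, 2))
        rotated = varimax_rotate(L, normalize=False)
        best_val, _ = grid_search_varimax(L)
        assert varimax_criterion(rotated) == pytest.approx(best_val, abs=1e-6)
        assert varimax_criterion(rotated) >= varimax_criterion(L) - 1e-12

    @pytest.mark.parametrize("normalize", [False, True])
    def test_communalities_preserved(self, normalize):
        L = np.random.default_rng(9).normal(size=(6, 3))
        rotated = varimax_rotate(L, normalize=normalize)
        assert (rotated**2).sum(axis=1) == pytest.approx((L**2).sum(axis=1), abs=1e-8)

    def test_simple_structure_is_a_fixed_point(self):
        L = np.array([[0.9, 0.0], [0.8, 0.0], [0.0, 0.7], [0.0, 0.6]])
        rotated = varimax_rotate(L, normalize=False)
        # unchanged up to column order/sign
        cols = {tuple(np.round(np.abs(rotated[:, k]), 10)) for k in range(2)}
        expected = {tuple(np.round(np.abs(L[:, k]), 10)) for k in range(2)}
        assert cols == expected

    def test_single_column_returns_input_with_warning(self):
        L = np.array([[0.5], [0.8]])
        with pytest.warns(UserWarning, match="single component"):
            rotated = varimax_rotate(L)
        assert rotated == pytest.approx(L)

    def test_rotate_model_preserves_total_variability(self):
        model = retain_components(
            fit_pca(np.random.default_rng(21).lognormal(size=(6, 5))), rule="fixed", k=2
        )
        rotated = rotate_model(model)
        assert rotated.rotation == "varimax"
        assert rotated.eigenvalues.sum() == pytest.approx(model.eigenvalues.sum(), abs=1e-8)
        assert rotated.cumulative_pct[-1] == pytest.approx(model.cumulative_pct[-1], abs=1e-8)


class TestBnWeight:
    @pytest.mark.parametrize("eig, expected", [(1.705, 0.58651), (1.0, 1.0), (2.268, 0.44092)])
    def test_reciprocal_eigenvalue(self, eig, expected):
        assert bn_weight(eig) == pytest.approx(expected, abs=5e-6)

    def test_component_selection_from_model(self):
        model = fit_pca(np.random.default_rng(2).lognormal(size=(6, 5)))
        assert bn_weight(model, component=1) == pytest.approx(1 / model.eigenvalues[0])
        assert bn_weight(model, component=2) == pytest.approx(1 / model.eigenvalues[1])

    def test_nonpositive_eigenvalue_rejected(self):
        with pytest.raises(ValidationError):
            bn_weight(0.0)
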