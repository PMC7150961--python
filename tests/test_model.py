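import numpy as np
import pytest

import psdkme as pk
from psdkme import KernelMeanEmbeddingRegressor, KernelSpec, ValidationError
from psdkme.kernels import cross_gram, gram
from psdkme.model import loocv_squared_error


def _toy_grid(n_bins=4):
    return pk.build_log_grid(n_bins, 10.0, 1000.0)


def _simplex_rows(rng, n, b):
    return rng.dirichlet(np.ones(b), size=n)


def loo_refit_oracle(K_b: np.ndarray, W: np.ndarray, lam: float) -> np.ndarray:
    """Explicit per-fold leave-one-out predictions.

    For each i, solve the ridge system on the remaining n−1 rows of the
    same biased Gram matrix and predict at x_i through the unbiased cross
    column (= the off-diagonal entries of K_b).
    """
    n = K_b.shape[0]
    A = np.empty_like(W)
    for i in range(n):
        keep = np.delete(np.arange(n), i)
        K_sub = K_b[np.ix_(keep, keep)]
        k_i = K_b[keep, i]
        beta = np.linalg.solve(K_sub + lam * np.eye(n - 1), k_i)
        A[i] = beta @ W[keep]
    return A


def _fit_toy(rng, n, lam=1e-3, bias=0.05, bandwidth_sq=1.0, n_bins=4):
    grid = _toy_grid(n_bins)
    X = rng.normal(size=(n, 3))
    W = _simplex_rows(rng, n, n_bins)
    model = KernelMeanEmbeddingRegressor(
        grid=grid,
        kernel_x_bandwidth_sq=bandwidth_sq,
        kernel_x_bias=bias,
        lam=lam,
        standardize=False,
    ).fit(X, W)
    return model, X, W


class TestFit:
    def test_two_point_system_matches_hand_solution(self):
        # two settings, two delta histograms; β for a query solves a 2×2 system
        grid = _toy_grid(2)
        X = np.array([[0.0], [1.0]])
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        lam, s2 = 0.1, 0.5
        model = KernelMeanEmbeddingRegressor(
            grid=grid,
            kernel_x_bandwidth_sq=s2,
            kernel_x_bias=0.0,
            lam=lam,
            standardize=False,
        ).fit(X, W)
        x_q = np.array([[0.25]])
        k = np.exp(-np.array([0.25**2, 0.75**2]) / (2 * s2))
        K = np.array([[1.0, np.exp(-1.0)], [np.exp(-1.0), 1.0]])
        beta = np.linalg.solve(K + lam * np.eye(2), k)
        assert np.allclose(model.predict_embedding(x_q)[0], beta @ W, atol=1e-12)

    def test_huge_lambda_shrinks_to_zero(self, rng):
        model, X, _ = _fit_toy(rng, 5, lam=1e9)
        A = model.predict_embedding(X)
        assert np.all(np.abs(A) < 1e-6)

    def test_mismatched_rows_rejected(self, rng):
        grid = _toy_grid()
        with pytest.raises(ValidationError):
            KernelMeanEmbeddingRegressor(grid=grid, lam=0.1).fit(
                rng.normal(size=(4, 3)), _simplex_rows(rng, 3, 4)
            )

    def test_non_simplex_rows_rejected(self, rng):
        grid = _toy_grid()
        W = _simplex_rows(rng, 4, 4) * 2.0
        with pytest.raises(ValidationError):
            KernelMeanEmbeddingRegressor(grid=grid, lam=0.1, standardize=False).fit(
                rng.normal(size=(4, 3)), W
            )

    def test_sklearn_params_round_trip(self):
        model = KernelMeanEmbeddingRegressor(kernel_x_bandwidth_sq=2.0)
        params = model.get_params()
        assert params["kernel_x_bandwidth_sq"] == 2.0
        clone = KernelMeanEmbeddingRegressor(**params)
        assert clone.get_params() == params


class TestPredictEmbedding:
    def test_single_training_point_reproduces_its_weights(self):
        # degenerate n=1 model, bias 0, tiny λ: β = k(x,x)/(k(x,x)+λ) ≈ 1
        grid = _toy_grid(3)
        X = np.array([[0.5, 0.5, 0.5]])
        W = np.array([[0.2, 0.3, 0.5]])
        model = KernelMeanEmbeddingRegressor(
            grid=grid, kernel_x_bias=0.0, lam=1e-12, standardize=False
        ).fit(X, W)
        assert np.allclose(model.predict_embedding(X)[0], W[0], atol=1e-9)

    def test_far_query_predicts_near_zero(self, rng):
        model, _, _ = _fit_toy(rng, 4, bandwidth_sq=0.1)
        a = model.predict_embedding(np.full((1, 3), 100.0))[0]
        assert np.all(np.abs(a) < 1e-12)

    def test_agrees_with_generic_linear_solve(self, rng):
        model, X, W = _fit_toy(rng, 3)
        x_q = rng.normal(size=(1, 3))
        k_x = cross_gram(X, x_q, model.kernel_x_spec_)[:, 0]
        beta = np.linalg.solve(model.K_ + model.lam_ * np.eye(3), k_x)
        assert np.allclose(model.predict_embedding(x_q)[0], beta @ W, atol=1e-10)

    def test_interpolation_as_lambda_vanishes(self, rng):
        # λ→0 with bias 0 and distinct points: training inputs reproduce
        # their own histograms
        grid = _toy_grid(5)
        X = rng.normal(size=(6, 3)) * 2
        W = _simplex_rows(rng, 6, 5)
        for lam, tol in [(1e-2, 0.5), (1e-6, 1e-3), (1e-10, 1e-6)]:
            model = KernelMeanEmbeddingRegressor(
                grid=grid, kernel_x_bias=0.0, lam=lam, standardize=False
            ).fit(X, W)
            err = np.abs(model.predict_embedding(X) - W).max()
            assert err < tol

    def test_shrinkage_monotone_in_lambda(self, rng):
        grid = _toy_grid(4)
        X = rng.normal(size=(5, 3))
        W = _simplex_rows(rng, 5, 4)
        x_q = rng.normal(size=(1, 3))
        norms = []
        for lam in [1e-4, 1e-2, 1.0, 1e2]:
            model = KernelMeanEmbeddingRegressor(
                grid=grid, lam=lam, standardize=False
            ).fit(X, W)
            norms.append(np.linalg.norm(model.predict_embedding(x_q)))
        assert all(a >= b for a, b in zip(norms, norms[1:]))


class TestHatMatrix:
    def test_orthogonal_inputs_give_scalar_form(self, rng):
        # mutually far-apart points: K ≈ I, so H = I/(1+λ)·1 = 0.5·I at λ=1
        grid = _toy_grid(3)
        X = np.eye(4)[:, :3] * 100.0
        W = _simplex_rows(rng, 4, 3)
        model = KernelMeanEmbeddingRegressor(
            grid=grid,
            kernel_x_bandwidth_sq=1.0,
            kernel_x_bias=0.0,
            lam=1.0,
            standardize=False,
        ).fit(X, W)
        assert np.allclose(model.hat_matrix(), 0.5 * np.eye(4), atol=1e-9)

    def test_lambda_to_zero_approaches_identity(self, rng):
        model, _, _ = _fit_toy(rng, 5, lam=1e-12)
        assert np.allclose(model.hat_matrix(), np.eye(5), atol=1e-9)

    def test_spectrum_in_unit_interval(self, rng):
        model, _, _ = _fit_toy(rng, 8, lam=0.1)
        eigs = np.linalg.eigvalsh(model.hat_matrix())
        assert np.all(eigs >= -1e-12) and np.all(eigs < 1.0)


class TestLoocvShortcut:
    @pytest.mark.parametrize("n", [3, 5, 10])
    def test_matches_explicit_refits(self, n):
        rng = np.random.default_rng(100 + n)
        model, X, W = _fit_toy(rng, n, lam=1e-3, n_bins=6)
        A = model.loocv_embeddings()
        A_oracle = loo_refit_oracle(model.K_, W, model.lam_)
        assert np.abs(A - A_oracle).max() < 1e-8

    def test_diagonal_gram_gives_zero_matrix(self, rng):
        # far-apart points: H has zero off-diagonals, so leave-one-out
        # predictions carry no information
        grid = _toy_grid(3)
        X = np.eye(5)[:, :3] * 50.0
        X[:, 2] = np.arange(5) * 50.0
        W = _simplex_rows(rng, 5, 3)
        model = KernelMeanEmbeddingRegressor(
            grid=grid, kernel_x_bandwidth_sq=0.5, lam=0.1, standardize=False
        ).fit(X, W)
        assert np.abs(model.loocv_embeddings()).max() < 1e-12

    def test_own_row_does_not_influence_own_prediction(self, rng):
        model, X, W = _fit_toy(rng, 6, n_bins=5)
        A = model.loocv_embeddings()
        W2 = W.copy()
        W2[2] = np.roll(W2[2], 1)
        model2 = KernelMeanEmbeddingRegressor(
            grid=model.grid_,
            kernel_x_bandwidth_sq=1.0,
            kernel_x_bias=0.05,
            lam=1e-3,
            standardize=False,
        ).fit(X, W2)
        assert np.allclose(model2.loocv_embeddings()[2], A[2], atol=1e-12)

    def test_row_permutation_equivariance(self, rng):
        model, X, W = _fit_toy(rng, 7, n_bins=4)
        perm = rng.permutation(7)
        model_p = KernelMeanEmbeddingRegressor(
            grid=model.grid_,
            kernel_x_bandwidth_sq=1.0,
            kernel_x_bias=0.05,
            lam=1e-3,
            standardize=False,
        ).fit(X[perm], W[perm])
        assert np.allclose(
            model_p.loocv_embeddings(), model.loocv_embeddings()[perm], atol=1e-10
        )

    def test_duplicated_point_without_regularization_is_singular(self):
        grid = _toy_grid(2)
        X = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [5.0, 5.0, 5.0]])
        W = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        with pytest.raises((ValidationError, np.linalg.LinAlgError)):
            model = KernelMeanEmbeddingRegressor(
                grid=grid, kernel_x_bias=0.0, lam=1e-15, standardize=False
            ).fit(X, W)
            model.loocv_embeddings()


class TestSelectLambda:
    def test_minimizer_property_on_fixture(self, dataset29, fitted29):
        design, histograms = dataset29
        model = fitted29
        W = model.W_
        J_star = loocv_squared_error(model.K_, W, model.L_, model.lam_)
        for lam in np.geomspace(model.search_lo, model.search_hi, 25):
            # relative slack: with the nugget, hat diagonals sit near 1 and
            # the leave-one-out ratios amplify float noise to ~1e-7 of J
            assert J_star <= loocv_squared_error(model.K_, W, model.L_, lam) * (
                1 + 1e-5
            )

    def test_objective_matches_refit_oracle(self, rng):
        model, X, W = _fit_toy(rng, 5, n_bins=6)
        for lam in [1e-4, 1e-2, 1.0]:
            A = loo_refit_oracle(model.K_, W, lam)
            R = W - A
            J_oracle = float(np.sum((R @ model.L_) * R))
            assert loocv_squared_error(model.K_, W, model.L_, lam) == pytest.approx(
                J_oracle, rel=1e-10
            )

    def test_interior_minimum_without_nugget_under_noise(self, design29, default_grid):
        # remove the K-nugget (the built-in regularization floor) and add
        # count noise: the leave-one-out objective becomes U-shaped and the
        # selected λ sits strictly inside the search window
        scen = pk.ScenarioParams(count_n=2000, seed=1)
        design, hists = pk.generate_dataset(design29, scen, default_grid)
        lam = pk.select_lambda(
            design,
            hists,
            KernelSpec("rbf", bandwidth_sq=5.0, diagonal_bias=0.0),
            KernelSpec(
                "rbf",
                bandwidth_sq=pk.median_heuristic(default_grid.bin_centers),
                diagonal_bias=0.1,
            ),
        )
        assert 1e-8 * 10 < lam < 1e2 / 10

    def test_invalid_bounds_rejected(self, design29, dataset29):
        design, hists = dataset29
        with pytest.raises(ValidationError):
            pk.select_lambda(
                design,
                hists,
                KernelSpec("rbf", bandwidth_sq=5.0, diagonal_bias=0.05),
                KernelSpec("rbf", bandwidth_sq=1.0, diagonal_bias=0.1),
                search_lo=1.0,
                search_hi=0.1,
            )


class TestSerialization:
    def test_fit_save_load_predict_round_trip(self, tmp_path, fitted29, design29):
        path = tmp_path / "model.json"
        fitted29.to_json(path)
        again = KernelMeanEmbeddingRegressor.load(path)
        X = design29.to_matrix()[:5]
        assert np.allclose(
            again.predict_embedding(X), fitted29.predict_embedding(X), atol=1e-12
        )
        assert again.lam_ == pytest.approx(fitted29.lam_)
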