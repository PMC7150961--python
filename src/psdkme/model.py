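"""Conditional mean embedding regression of histograms on process settings.

The learning core.  Given n training pairs (x_i, w_i) — standardized process
settings and histogram weight vectors on a fixed size grid — the conditional
mean embedding of the distribution at a query x is estimated by kernel ridge
regression:

    μ̂(x) = Σ_i β_i(x) Σ_j w_ij l(y_j, ·),    β(x) = (K + λI)⁻¹ k_x

with K the (nugget-biased) Gram matrix of the settings under an RBF kernel
k, k_x the unbiased train-query kernel vector, and λ > 0 a ridge parameter.
Because the estimator is a linear smoother with hat matrix
H = K (K + λI)⁻¹, all n leave-one-out predictions are available in closed
form, and λ is selected by minimizing the leave-one-out squared RKHS error.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``get_params``); ``predict`` returns valid histograms via the pre-image QP,
``predict_embedding`` returns the raw (possibly negative) coefficients.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data import (
    DesignTable,
    PSDHistogram,
    ProcessSettings,
    StandardizedDesign,
    standardize_matrix,
)
from .exceptions import ValidationError
from .grid import SizeGrid, build_log_grid
from .kernels import KernelSpec, cross_gram, gram, median_heuristic
from .preimage import DEFAULT_SOLVER_TOL, recover_histogram

#: default λ search window (effective regularizer, log-spaced scan)
DEFAULT_SEARCH_LO = 1e-8
DEFAULT_SEARCH_HI = 1e2
_N_GRID = 25
_GOLDEN_TOL_LOG10 = 1e-3


def loocv_squared_error(K_b: np.ndarray, W: np.ndarray, L_sel: np.ndarray, lam: float) -> float:
    """Leave-one-out embedding error J(λ) = Σ_i (w_i − â_i)ᵀ L (w_i − â_i).

    â_i are the closed-form leave-one-out coefficient predictions under
    ridge parameter λ.  Used both by :func:`select_lambda` and as the
    target of oracle-equivalence tests.
    """
    A = _loocv_matrix(K_b, W, lam)
    R = W - A
    return float(np.sum((R @ L_sel) * R))


def _loocv_matrix(K_b: np.ndarray, W: np.ndarray, lam: float) -> np.ndarray:
    H = K_b @ np.linalg.solve(K_b + lam * np.eye(K_b.shape[0]), np.eye(K_b.shape[0]))
    H = 0.5 * (H + H.T)
    d = np.diag(H)
    if np.any(d >= 1.0 - 1e-12):
        raise ValidationError(
            "leave-one-out system is singular (a hat-matrix diagonal reaches 1); "
            "increase λ or the diagonal bias"
        )
    return ((H - np.diag(d)) @ W) / (1.0 - d)[:, None]


def _golden_section(f, lo: float, hi: float, tol: float) -> float:
    """Deterministic golden-section minimizer on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return c if fc < fd else d


def _select_lambda_from_grams(
    K_b: np.ndarray,
    W: np.ndarray,
    L_sel: np.ndarray,
    search_lo: float = DEFAULT_SEARCH_LO,
    search_hi: float = DEFAULT_SEARCH_HI,
) -> float:
    if not 0 < search_lo < search_hi:
        raise ValidationError("need 0 < search_lo < search_hi")
    # eigendecomposition makes each J(λ) evaluation O(n²)
    eigvals, U = np.linalg.eigh(K_b)
    Wt = U.T @ W

    def J_log(x: float) -> float:
        lam = 10.0 ** x
        h = eigvals / (eigvals + lam)
        d = np.einsum("ij,j,ij->i", U, h, U)
        if np.any(d >= 1.0 - 1e-12):
            return np.inf
        HW = U @ (h[:, None] * Wt)
        A = (HW - d[:, None] * W) / (1.0 - d)[:, None]
        R = W - A
        return float(np.sum((R @ L_sel) * R))

    xs = np.linspace(np.log10(search_lo), np.log10(search_hi), _N_GRID)
    Js = np.array([J_log(x) for x in xs])
    if not np.any(np.isfinite(Js)):
        raise ValidationError("leave-one-out objective is not finite on the search grid")
    best = int(np.nanargmin(Js))
    lo = xs[max(best - 1, 0)]
    hi = xs[min(best + 1, _N_GRID - 1)]
    x_star = _golden_section(J_log, lo, hi, _GOLDEN_TOL_LOG10)
    if J_log(x_star) > Js[best]:
        x_star = xs[best]
    return float(10.0 ** x_star)


class KernelMeanEmbeddingRegressor(RegressorMixin, BaseEstimator):
    """Distribution-output kernel ridge regression with closed-form LOOCV.

    Parameters
    ----------
    grid : SizeGrid, optional
        Size grid carrying the histogram bins; defaults to the 35-bin
        log-spaced grid between 8.46 and 6765.36 μm.
    kernel_x_bandwidth_sq : float, default 5.0
        σ² of the RBF kernel exp(−‖x−x'‖²/(2σ²)) on the standardized
        settings.  The default equals an exponential coefficient
        γ = 1/(2σ²) = 0.1, i.e. a kernel smooth across the whole
        standardized design; see docs/methods.md for why this calibration
        is required for usable leave-one-out predictions on three-level
        designs.
    kernel_x_bias : float, default 0.05
        Diagonal nugget on the settings Gram matrix.
    kernel_y_bandwidth : "median" or float, default "median"
        σ² of the RBF kernel on log10 grid centers, or ``"median"`` for the
        median heuristic over pairwise squared log10 distances.
    kernel_y_bias : float, default 0.1
        Diagonal nugget on the size-grid Gram matrix (stabilizes the
        pre-image QP in particular).
    lam : "loocv" or float, default "loocv"
        Ridge parameter; ``"loocv"`` selects it by minimizing the
        leave-one-out squared embedding error.
    search_lo, search_hi : float
        λ search window for the LOOCV selection.
    selection_use_biased_l : bool, default True
        Whether the selection objective measures embedding error with the
        biased size-grid Gram matrix (the bias is applied before
        calibration) or the unbiased one.
    preimage_regularizer : float or None, default None
        Ridge term of the pre-image QP; ``None`` uses ``kernel_y_bias`` so
        the QP's quadratic equals the biased Gram matrix.
    solver_tol : float, default 1e-8
        KKT tolerance of the pre-image solver.
    standardize : bool, default True
        Z-score the settings columns before building the Gram matrix.
        Disable only for controlled experiments on pre-scaled inputs.

    Attributes
    ----------
    X_mean_, X_scale_ : ndarray
        Standardization constants (population SD).
    Z_ : ndarray of shape (n, p)
        Standardized training settings.
    K_ : ndarray of shape (n, n)
        Biased settings Gram matrix.
    L_, L_unbiased_ : ndarray of shape (n_bins, n_bins)
        Size-grid Gram matrix with and without the diagonal bias.
    kernel_y_bandwidth_sq_ : float
        Resolved σ² of the size-grid kernel.
    lam_ : float
        Resolved ridge parameter.
    W_ : ndarray of shape (n, n_bins)
        Training histogram weights.
    """

    def __init__(
        self,
        grid: SizeGrid | None = None,
        kernel_x_bandwidth_sq: float = 5.0,
        kernel_x_bias: float = 0.05,
        kernel_y_bandwidth="median",
        kernel_y_bias: float = 0.1,
        lam="loocv",
        search_lo: float = DEFAULT_SEARCH_LO,
        search_hi: float = DEFAULT_SEARCH_HI,
        selection_use_biased_l: bool = True,
        preimage_regularizer: float | None = None,
        solver_tol: float = DEFAULT_SOLVER_TOL,
        standardize: bool = True,
    ):
        self.grid = grid
        self.kernel_x_bandwidth_sq = kernel_x_bandwidth_sq
        self.kernel_x_bias = kernel_x_bias
        self.kernel_y_bandwidth = kernel_y_bandwidth
        self.kernel_y_bias = kernel_y_bias
        self.lam = lam
        self.search_lo = search_lo
        self.search_hi = search_hi
        self.selection_use_biased_l = selection_use_biased_l
        self.preimage_regularizer = preimage_regularizer
        self.solver_tol = solver_tol
        self.standardize = standardize

    # ------------------------------------------------------------------
    def fit(self, X, Y):
        """Fit on raw settings X (n × p) and histogram weights Y (n × n_bins)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValidationError(
                f"X and Y must be 2-D with matching rows, got {X.shape} and {Y.shape}"
            )
        if np.any(Y < -1e-12) or np.any(np.abs(Y.sum(axis=1) - 1.0) > 1e-6):
            raise ValidationError("each row of Y must be a histogram on the simplex")

        grid = self.grid if self.grid is not None else build_log_grid()
        if Y.shape[1] != grid.n_bins:
            raise ValidationError(
                f"Y has {Y.shape[1]} columns but the grid has {grid.n_bins} bins"
            )

        if self.standardize:
            std = standardize_matrix(X)
        else:
            std = StandardizedDesign(
                X.copy(), np.zeros(X.shape[1]), np.ones(X.shape[1])
            )

        spec_k = KernelSpec(
            "rbf",
            bandwidth_sq=self.kernel_x_bandwidth_sq,
            diagonal_bias=self.kernel_x_bias,
        )
        if self.kernel_y_bandwidth == "median":
            sigma_sq_l = median_heuristic(grid.bin_centers)
        else:
            sigma_sq_l = float(self.kernel_y_bandwidth)
        spec_l = KernelSpec(
            "rbf", bandwidth_sq=sigma_sq_l, diagonal_bias=self.kernel_y_bias
        )

        K_b = gram(std.matrix, spec_k)
        L_b = gram(grid.log10_centers, spec_l)

        if self.lam == "loocv":
            if X.shape[0] < 2:
                raise ValidationError("λ selection by LOOCV needs n >= 2")
            L_sel = L_b.values if self.selection_use_biased_l else L_b.unbiased
            lam = _select_lambda_from_grams(
                K_b.values, Y, L_sel, self.search_lo, self.search_hi
            )
        else:
            lam = float(self.lam)
            if lam < 0 or (lam == 0 and self.kernel_x_bias == 0):
                raise ValidationError("need λ > 0 or a positive diagonal bias")

        M = K_b.values + lam * np.eye(X.shape[0])
        try:
            factor = cho_factor(M)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - needs exotic input
            raise ValidationError(f"singular regression system: {exc}") from exc

        self.grid_ = grid
        self.n_features_in_ = X.shape[1]
        self.std_ = std
        self.X_mean_ = std.feature_means
        self.X_scale_ = std.feature_scales
        self.Z_ = std.matrix
        self.kernel_x_spec_ = spec_k
        self.kernel_y_spec_ = spec_l
        self.kernel_y_bandwidth_sq_ = sigma_sq_l
        self.K_ = K_b.values
        self.L_ = L_b.values
        self.L_unbiased_ = L_b.unbiased
        self.lam_ = lam
        self.W_ = Y.copy()
        self._factor = factor
        return self

    # ------------------------------------------------------------------
    def _standardize_queries(self, X) -> np.ndarray:
        if isinstance(X, ProcessSettings):
            X = X.as_vector()[None, :]
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :] if X.size == self.n_features_in_ else X[:, None]
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"query has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return (X - self.X_mean_) / self.X_scale_

    def predict_embedding(self, X) -> np.ndarray:
        """Predicted embedding coefficients Wᵀ(K+λI)⁻¹k_x, one row per query.

        Rows are unconstrained reals; use :meth:`predict` for valid
        histograms.
        """
        check_is_fitted(self, "K_")
        Zq = self._standardize_queries(X)
        k_x = cross_gram(self.Z_, Zq, self.kernel_x_spec_)  # n × m, unbiased
        beta = cho_solve(self._factor, k_x)  # n × m
        return beta.T @ self.W_

    def predict(self, X) -> np.ndarray:
        """Predicted histograms (simplex rows), via the pre-image QP."""
        A = self.predict_embedding(X)
        reg = (
            self.kernel_y_bias
            if self.preimage_regularizer is None
            else self.preimage_regularizer
        )
        out = np.empty_like(A)
        for i, a in enumerate(A):
            out[i] = recover_histogram(
                a, self.L_unbiased_, regularizer=reg, solver_tol=self.solver_tol
            ).weights
        return out

    def hat_matrix(self) -> np.ndarray:
        """Ridge smoother H = K (K + λI)⁻¹ on the (biased) settings Gram."""
        check_is_fitted(self, "K_")
        H = self.K_ @ cho_solve(self._factor, np.eye(self.K_.shape[0]))
        return 0.5 * (H + H.T)

    def loocv_embeddings(self) -> np.ndarray:
        """All n leave-one-out coefficient predictions at once.

        Row i equals the embedding prediction at x_i of a model refit
        without row i: A = (I − diag H)⁻¹ (H − diag H) W.
        """
        check_is_fitted(self, "K_")
        if self.W_.shape[0] < 2:
            raise ValidationError("leave-one-out needs n >= 2")
        return _loocv_matrix(self.K_, self.W_, self.lam_)

    # ------------------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the fitted model (parameters + matrices) to JSON."""
        check_is_fitted(self, "K_")
        payload = {
            "format": "psdkme-model",
            "version": 1,
            "params": {
                "kernel_x_bandwidth_sq": self.kernel_x_bandwidth_sq,
                "kernel_x_bias": self.kernel_x_bias,
                "kernel_y_bandwidth": self.kernel_y_bandwidth,
                "kernel_y_bias": self.kernel_y_bias,
                "lam": self.lam,
                "search_lo": self.search_lo,
                "search_hi": self.search_hi,
                "selection_use_biased_l": self.selection_use_biased_l,
                "preimage_regularizer": self.preimage_regularizer,
                "solver_tol": self.solver_tol,
                "standardize": self.standardize,
            },
            "grid_edges": self.grid_.bin_edges.tolist(),
            "X_mean": self.X_mean_.tolist(),
            "X_scale": self.X_scale_.tolist(),
            "Z": self.Z_.tolist(),
            "W": self.W_.tolist(),
            "lam_": self.lam_,
            "kernel_y_bandwidth_sq_": self.kernel_y_bandwidth_sq_,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def load(cls, path: str | Path) -> "KernelMeanEmbeddingRegressor":
        """Rebuild a fitted model from a file written by :meth:`to_json`."""
        return cls.from_json(Path(path).read_text())

    @classmethod
    def from_json(cls, text: str) -> "KernelMeanEmbeddingRegressor":
        """Rebuild a fitted model from :meth:`to_json` output."""
        payload = json.loads(text)
        if payload.get("format") != "psdkme-model":
            raise ValidationError("not a serialized psdkme model")
        params = payload["params"]
        grid = SizeGrid(np.array(payload["grid_edges"]))
        model = cls(grid=grid, **params)
        # refit deterministically from the stored standardized design/weights
        model.lam = payload["lam_"]
        model.kernel_y_bandwidth = payload["kernel_y_bandwidth_sq_"]
        model.standardize = False
        model.fit(np.array(payload["Z"]), np.array(payload["W"]))
        model.X_mean_ = np.array(payload["X_mean"])
        model.X_scale_ = np.array(payload["X_scale"])
        # restore user-facing parameters
        model.lam = params["lam"]
        model.kernel_y_bandwidth = params["kernel_y_bandwidth"]
        model.standardize = params["standardize"]
        return model


# ---------------------------------------------------------------------------
# thin functional layer over the estimator
# ---------------------------------------------------------------------------

def fit_conditional_model(
    design: DesignTable,
    histograms: Sequence[PSDHistogram],
    **params,
) -> KernelMeanEmbeddingRegressor:
    """Fit the regressor from a design table and histogram list."""
    if len(histograms) != len(design):
        raise ValidationError(
            f"{len(design)} design rows but {len(histograms)} histograms"
        )
    grids = {h.grid for h in histograms}
    if len(grids) != 1:
        raise ValidationError("all histograms must share one grid")
    grid = histograms[0].grid
    W = np.array([h.weights for h in histograms])
    model = KernelMeanEmbeddingRegressor(grid=grid, **params)
    return model.fit(design.to_matrix(), W)


def select_lambda(
    design: DesignTable,
    histograms: Sequence[PSDHistogram],
    spec_k: KernelSpec,
    spec_l: KernelSpec,
    search_lo: float = DEFAULT_SEARCH_LO,
    search_hi: float = DEFAULT_SEARCH_HI,
    use_biased_l: bool = True,
) -> float:
    """Select λ by minimizing the leave-one-out squared embedding error.

    Grid scan (25 log-spaced candidates) followed by golden-section
    refinement around the best candidate; deterministic.
    """
    std = standardize_matrix(design.to_matrix())
    grid = histograms[0].grid
    W = np.array([h.weights for h in histograms])
    K_b = gram(std.matrix, spec_k).values
    L_b = gram(grid.log10_centers, spec_l)
    L_sel = L_b.values if use_biased_l else L_b.unbiased
    return _select_lambda_from_grams(K_b, W, L_sel, search_lo, search_hi)
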