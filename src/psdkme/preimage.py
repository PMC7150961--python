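"""Distributional pre-image: recover a histogram from a predicted embedding.

A predicted conditional embedding is a coefficient vector a over the grid
atoms that need not be a probability vector.  The pre-image step finds the
histogram whose embedding is closest in RKHS norm, i.e. it minimizes the
maximum mean discrepancy to the prediction over the probability simplex:

    minimize_α   αᵀ (L + r·I) α − 2 αᵀ L a      subject to α ≥ 0, Σα = 1

with L the (unbiased) Gram matrix of the atoms and r ≥ 0 a ridge
regularizer.  Up to a constant the objective equals
‖μ_α − μ_a‖²_L + r‖α‖².  The problem is a small convex QP; it is solved by
accelerated projected gradient (FISTA with Euclidean projection onto the
simplex) and certified by a KKT stationarity residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PSDHistogram
from .embedding import EmbeddingCoefficients
from .exceptions import SolverError, ValidationError
from .grid import SizeGrid
from .kernels import GramMatrix

#: default KKT / feasibility tolerance
DEFAULT_SOLVER_TOL = 1e-8
#: iteration cap for the projected-gradient loop
MAX_ITERATIONS = 10_000
#: ridge floor applied automatically when the QP is numerically degenerate
DEGENERACY_FLOOR = 1e-10


@dataclass(frozen=True)
class PreimageResult:
    """Solution of the simplex-constrained pre-image QP."""

    weights: np.ndarray  # on the simplex, within solver tolerance
    objective_value: float
    kkt_residual: float
    iterations: int
    converged: bool

    def as_histogram(self, grid: SizeGrid) -> PSDHistogram:
        """The recovered weights as a histogram on `grid` (exactly renormalized)."""
        w = np.clip(self.weights, 0.0, None)
        return PSDHistogram(grid, w / w.sum())


def project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sort-based)."""
    v = np.asarray(v, dtype=float)
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.flatnonzero(u * np.arange(1, v.size + 1) > css)[-1]
    theta = css[rho] / (rho + 1.0)
    return np.clip(v - theta, 0.0, None)


def clip_renormalize(a: np.ndarray) -> np.ndarray:
    """Baseline heuristic: clip negatives and renormalize to unit sum."""
    w = np.clip(np.asarray(a, dtype=float), 0.0, None)
    total = w.sum()
    if total <= 0:
        return np.full(w.size, 1.0 / w.size)
    return w / total


def _kkt_residual(alpha: np.ndarray, grad: np.ndarray) -> float:
    # multiplier of the equality constraint under stationarity
    nu = float(grad @ alpha)
    dual_infeas = float(np.maximum(nu - grad, 0.0).max(initial=0.0))
    comp_slack = float(np.abs(alpha * (grad - nu)).max(initial=0.0))
    return max(dual_infeas, comp_slack)


def recover_histogram(
    a_pred,
    L,
    regularizer: float = 0.0,
    solver_tol: float = DEFAULT_SOLVER_TOL,
    max_iter: int = MAX_ITERATIONS,
    x0: np.ndarray | None = None,
) -> PreimageResult:
    """Solve the pre-image QP for a predicted embedding.

    Parameters
    ----------
    a_pred : EmbeddingCoefficients or array-like
        Predicted coefficient vector over the atoms of `L`.
    L : GramMatrix or ndarray
        Unbiased, positive semidefinite Gram matrix of the atoms.  Pass the
        regularizer separately rather than a pre-biased matrix so the linear
        term stays c = L·a_pred.
    regularizer : float
        Ridge term r ≥ 0 on ‖α‖².  When the size-grid kernel carries a
        diagonal bias for stability, passing that bias here reproduces a QP
        whose quadratic is the biased Gram matrix.
    solver_tol : float
        Required KKT stationarity residual (also bounds the feasibility
        violation of the returned weights).
    x0 : ndarray, optional
        Starting point (projected onto the simplex); defaults to the
        projection of `a_pred`.

    Raises
    ------
    SolverError
        If the KKT residual does not reach `solver_tol` within `max_iter`
        iterations; the best feasible iterate is attached to the exception.
    """
    a = a_pred.coeffs if isinstance(a_pred, EmbeddingCoefficients) else np.asarray(a_pred, float)
    Lv = L.unbiased if isinstance(L, GramMatrix) else np.asarray(L, dtype=float)
    n = a.size
    if Lv.shape != (n, n):
        raise ValidationError(f"Gram shape {Lv.shape} does not match {n} atoms")
    if regularizer < 0:
        raise ValidationError("regularizer must be nonnegative")

    eigs = np.linalg.eigvalsh(Lv)
    if eigs.min() < -1e-8 * max(1.0, eigs.max()):
        raise ValidationError("L must be positive semidefinite")
    reg = float(regularizer)
    if eigs.min() + reg < 1e-12:
        reg = max(reg, DEGENERACY_FLOOR)  # near-degenerate QP: apply ridge floor

    c = Lv @ a
    Q = Lv + reg * np.eye(n)
    lipschitz = 2.0 * (eigs.max() + reg)
    step = 1.0 / lipschitz

    def objective(x):
        return float(x @ Q @ x - 2.0 * c @ x)

    def gradient(x):
        return 2.0 * (Q @ x - c)

    alpha = project_to_simplex(a if x0 is None else np.asarray(x0, float))
    momentum = alpha.copy()
    t = 1.0
    best = (alpha, objective(alpha), _kkt_residual(alpha, gradient(alpha)))
    iterations = 0
    for iterations in range(1, max_iter + 1):
        alpha_next = project_to_simplex(momentum - step * gradient(momentum))
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        momentum = alpha_next + ((t - 1.0) / t_next) * (alpha_next - alpha)
        # restart the momentum when it points uphill
        if (alpha_next - alpha) @ (momentum - alpha_next) < 0:
            momentum = alpha_next.copy()
            t_next = 1.0
        alpha, t = alpha_next, t_next
        res = _kkt_residual(alpha, gradient(alpha))
        obj = objective(alpha)
        if res < best[2]:
            best = (alpha, obj, res)
        if res <= solver_tol:
            return PreimageResult(alpha, obj, res, iterations, True)

    result = PreimageResult(best[0], best[1], best[2], iterations, False)
    raise SolverError(
        f"pre-image QP did not reach KKT residual {solver_tol:g} in "
        f"{max_iter} iterations (best {best[2]:.3g})",
        result=result,
    )
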