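"""Kernel evaluation, Gram matrices, and bandwidth heuristics.

Two kernels drive the method: a Gaussian RBF kernel k on standardized
process settings and a kernel l on the log10 size grid, whose bandwidth is
chosen by the median heuristic.  For numerical stability a small bias
(nugget) may be added to the diagonal of a square Gram matrix; cross-Gram
matrices between training points and queries never carry a bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .exceptions import ValidationError

_FAMILIES = ("rbf", "polynomial")


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family with its hyperparameters.

    Parameters
    ----------
    family : {"rbf", "polynomial"}
    bandwidth_sq : float, optional
        σ² of the Gaussian kernel exp(−‖x−y‖² / (2σ²)); required and > 0 for
        the RBF family.
    degree : int, optional
        Order p of the inhomogeneous polynomial kernel (⟨x,y⟩ + 1)^p;
        required and ≥ 1 for the polynomial family.
    diagonal_bias : float
        Nonnegative nugget added to the diagonal of square Gram matrices.
    """

    family: str = "rbf"
    bandwidth_sq: float | None = None
    degree: int | None = None
    diagonal_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"unknown kernel family {self.family!r}")
        if self.family == "rbf":
            if self.bandwidth_sq is None or self.bandwidth_sq <= 0:
                raise ValidationError("rbf kernel needs bandwidth_sq > 0")
        else:
            if self.degree is None or int(self.degree) < 1:
                raise ValidationError("polynomial kernel needs degree >= 1")
        if self.diagonal_bias < 0:
            raise ValidationError("diagonal_bias must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "bandwidth_sq": self.bandwidth_sq,
            "degree": self.degree,
            "diagonal_bias": self.diagonal_bias,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(
            family=d.get("family", "rbf"),
            bandwidth_sq=d.get("bandwidth_sq"),
            degree=d.get("degree"),
            diagonal_bias=d.get("diagonal_bias", 0.0),
        )


@dataclass(frozen=True)
class GramMatrix:
    """A square symmetric kernel matrix K_ij = k(x_i, x_j) (+ bias on the diagonal)."""

    values: np.ndarray
    bias_applied: float = 0.0
    point_count: int = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("Gram matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0):
            raise ValidationError("Gram matrix must be symmetric")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "point_count", v.shape[0])

    @property
    def unbiased(self) -> np.ndarray:
        """The matrix with the diagonal nugget removed."""
        return self.values - self.bias_applied * np.eye(self.point_count)


def _as_points(points) -> np.ndarray:
    P = np.asarray(points, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if P.ndim != 2 or P.shape[0] == 0:
        raise ValidationError("need a non-empty 2-D array of points")
    if not np.all(np.isfinite(P)):
        raise ValidationError("points must be finite")
    return P


def _check_pair(x, y) -> tuple:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValidationError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return x, y


def eval_rbf(x, y, bandwidth_sq: float) -> float:
    """Gaussian kernel exp(−‖x−y‖² / (2σ²)); equals 1 iff x = y."""
    if bandwidth_sq <= 0:
        raise ValidationError("bandwidth_sq must be positive")
    x, y = _check_pair(x, y)
    return float(np.exp(-np.sum((x - y) ** 2) / (2.0 * bandwidth_sq)))


def eval_polynomial(x, y, degree: int) -> float:
    """Inhomogeneous polynomial kernel (⟨x,y⟩ + 1)^p."""
    if int(degree) < 1:
        raise ValidationError("degree must be >= 1")
    x, y = _check_pair(x, y)
    return float((np.dot(x, y) + 1.0) ** int(degree))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, spec: KernelSpec) -> np.ndarray:
    if spec.family == "rbf":
        D = cdist(A, B, metric="sqeuclidean")
        return np.exp(-D / (2.0 * spec.bandwidth_sq))
    return (A @ B.T + 1.0) ** int(spec.degree)


def gram(points, spec: KernelSpec) -> GramMatrix:
    """Square Gram matrix of a point set with itself, plus the diagonal nugget."""
    P = _as_points(points)
    K = _kernel_matrix(P, P, spec)
    K = 0.5 * (K + K.T)  # enforce exact symmetry
    if spec.diagonal_bias:
        K = K + spec.diagonal_bias * np.eye(P.shape[0])
    return GramMatrix(values=K, bias_applied=spec.diagonal_bias)


def cross_gram(points_a, points_b, spec: KernelSpec) -> np.ndarray:
    """|a| × |b| kernel matrix between two point sets.

    No diagonal bias is ever applied: the nugget is a property of the
    training set with itself, not of train-query similarities.
    """
    A, B = _as_points(points_a), _as_points(points_b)
    if A.shape[1] != B.shape[1]:
        raise ValidationError(
            f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    return _kernel_matrix(A, B, spec)


def median_heuristic(values) -> float:
    """Bandwidth σ² = median of squared pairwise log10 distances.

    The median runs over the unordered pairs i < j (self-pairs excluded:
    including the n zero distances would deflate the median).  Intended for
    the size-grid kernel, hence the base-10 log transform — the grid spans
    more than three orders of magnitude.
    """
    v = np.asarray(values, dtype=float).ravel()
    if np.any(v <= 0):
        raise ValidationError("median heuristic needs strictly positive values")
    if np.unique(v).size < 2:
        raise ValidationError("median heuristic needs at least 2 distinct values")
    d2 = pdist(np.log10(v)[:, None], metric="sqeuclidean")
    sigma_sq = float(np.median(d2))
    if sigma_sq <= 0:
        raise ValidationError("median pairwise distance is zero (too many ties)")
    return sigma_sq


def check_positive_definite(values, tol: float = 1e-8) -> bool:
    """True iff the smallest eigenvalue is ≥ −tol (relative to the spectral scale)."""
    M = np.asarray(values, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValidationError("matrix must be square")
    if not np.allclose(M, M.T, atol=1e-12, rtol=0):
        raise ValidationError("matrix must be symmetric")
    eigs = np.linalg.eigvalsh(M)
    scale = max(1.0, float(np.abs(eigs).max(initial=0.0)))
    return bool(eigs.min() >= -tol * scale)
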