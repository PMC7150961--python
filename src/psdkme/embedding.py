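"""Finite-sample kernel mean embeddings in coefficient form.

A probability distribution with mass w_i on atoms y_i embeds in the RKHS of
a kernel l as μ = Σ_i w_i l(y_i, ·).  Everything downstream (regression,
pre-imaging, MMD) is a linear or quadratic form in the coefficient vector,
evaluated through the Gram matrix of the atoms — the feature map itself is
never materialized.  Predicted coefficients may be negative; only measured
histograms are constrained to the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PSDHistogram
from .exceptions import ValidationError
from .kernels import GramMatrix, KernelSpec, cross_gram


@dataclass(frozen=True)
class EmbeddingCoefficients:
    """An RKHS element Σ_j coeffs[j] · l(atoms[j], ·), in coefficient form.

    ``atoms`` are particle sizes in μm (grid bin centers, or the distinct
    values of a raw sample).  Coefficients are unconstrained reals.
    """

    atoms: np.ndarray
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        atoms = np.asarray(self.atoms, dtype=float)
        coeffs = np.asarray(self.coeffs, dtype=float)
        if atoms.ndim != 1 or coeffs.shape != atoms.shape:
            raise ValidationError("atoms and coeffs must be 1-D and equal length")
        if not np.all(np.isfinite(coeffs)):
            raise ValidationError("coefficients must be finite")
        atoms.setflags(write=False)
        coeffs.setflags(write=False)
        object.__setattr__(self, "atoms", atoms)
        object.__setattr__(self, "coeffs", coeffs)


def embed_histogram(h: PSDHistogram) -> EmbeddingCoefficients:
    """Embed a histogram: coefficients are its weights over grid-center atoms."""
    return EmbeddingCoefficients(atoms=h.grid.bin_centers, coeffs=h.weights)


def embed_sample(values) -> EmbeddingCoefficients:
    """Embed an iid sample of sizes: the empirical mean (1/n) Σ_i l(x_i, ·).

    Duplicate values are merged, so the atom set is the distinct sample
    values and each coefficient is multiplicity / n.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValidationError("cannot embed an empty sample")
    atoms, counts = np.unique(v, return_counts=True)
    return EmbeddingCoefficients(atoms=atoms, coeffs=counts / v.size)


def _matching_gram(a: EmbeddingCoefficients, b: EmbeddingCoefficients, L) -> np.ndarray:
    if not np.array_equal(a.atoms, b.atoms):
        raise ValidationError("embeddings are defined over different atoms")
    Lv = L.values if isinstance(L, GramMatrix) else np.asarray(L, dtype=float)
    if Lv.shape != (a.atoms.size, a.atoms.size):
        raise ValidationError(
            f"Gram matrix shape {Lv.shape} does not match {a.atoms.size} atoms"
        )
    return Lv


def inner_product(a: EmbeddingCoefficients, b: EmbeddingCoefficients, L) -> float:
    """RKHS inner product ⟨μ_a, μ_b⟩ = aᵀ L b over shared atoms."""
    Lv = _matching_gram(a, b, L)
    return float(a.coeffs @ Lv @ b.coeffs)


def evaluate_at(a: EmbeddingCoefficients, y: float, spec_l: KernelSpec) -> float:
    """Evaluate the embedded function at size y (μm): Σ_j coeffs[j] l(y_j, y).

    The kernel acts on log10 sizes, the same transform used when the model's
    size-grid Gram matrix is built.
    """
    if y <= 0:
        raise ValidationError("size must be strictly positive")
    row = cross_gram(np.log10(a.atoms), np.array([np.log10(y)]), spec_l)
    return float(a.coeffs @ row[:, 0])
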