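"""Containers and CSV interchange for designs and size distributions.

The experimental unit is one granulation run: a triple of process settings
(throughput in kg/h, screw speed in rpm, liquid-to-solid mass ratio) and the
measured particle size distribution, stored as a histogram on a fixed
:class:`~psdkme.grid.SizeGrid`.  Plain CSV is the interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .grid import SizeGrid

#: canonical feature order used everywhere in the package
FEATURE_NAMES = ("throughput_kg_h", "screw_speed_rpm", "ls_ratio")

_DESIGN_COLUMNS = ("experiment",) + FEATURE_NAMES

#: tolerance on the unit-sum constraint of a histogram
SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class PSDHistogram:
    """A particle size distribution: nonnegative weights summing to one.

    The weights w live on the probability simplex Δ^{n_bins-1}; bin i carries
    the mass fraction of granules whose size falls in
    [edges[i], edges[i+1]).
    """

    grid: SizeGrid
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size != self.grid.n_bins:
            raise ValidationError(
                f"expected {self.grid.n_bins} weights, got shape {w.shape}"
            )
        if not np.all(np.isfinite(w)):
            raise ValidationError("histogram weights must be finite")
        if np.any(w < 0):
            raise ValidationError("histogram weights must be nonnegative")
        if abs(w.sum() - 1.0) > SIMPLEX_TOL:
            raise ValidationError(
                f"histogram weights must sum to 1 (got {w.sum():.12g})"
            )
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    def mean_size(self) -> float:
        """Weight-averaged bin-center size in μm."""
        return float(self.weights @ self.grid.bin_centers)


@dataclass(frozen=True)
class ProcessSettings:
    """One granulator operating point."""

    throughput: float  # kg/h
    screw_speed: float  # rpm
    ls_ratio: float  # liquid-to-solid mass ratio, dimensionless

    def __post_init__(self) -> None:
        for name in ("throughput", "screw_speed", "ls_ratio"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValidationError(f"{name} must be strictly positive, got {value}")

    def as_vector(self) -> np.ndarray:
        """Settings in the canonical (throughput, screw_speed, ls_ratio) order."""
        return np.array([self.throughput, self.screw_speed, self.ls_ratio])


@dataclass(frozen=True)
class DesignTable:
    """A design of experiments: unique ids and one settings triple per run."""

    experiment_ids: tuple
    settings: tuple

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.experiment_ids)
        settings = tuple(self.settings)
        if len(ids) == 0:
            raise ValidationError("design table must be non-empty")
        if len(ids) != len(settings):
            raise ValidationError("ids and settings must have equal length")
        if len(set(ids)) != len(ids):
            raise ValidationError("experiment ids must be unique")
        object.__setattr__(self, "experiment_ids", ids)
        object.__setattr__(self, "settings", settings)

    def __len__(self) -> int:
        return len(self.experiment_ids)

    def to_matrix(self) -> np.ndarray:
        """n × 3 matrix in canonical feature order."""
        return np.array([s.as_vector() for s in self.settings])


@dataclass(frozen=True)
class StandardizedDesign:
    """A design z-scored column-wise with population standard deviations."""

    matrix: np.ndarray
    feature_means: np.ndarray
    feature_scales: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        means = np.asarray(self.feature_means, dtype=float)
        scales = np.asarray(self.feature_scales, dtype=float)
        if m.ndim != 2 or means.shape != (m.shape[1],) or scales.shape != means.shape:
            raise ValidationError("inconsistent standardized-design shapes")
        if np.any(scales <= 0):
            raise ValidationError("feature scales must be strictly positive")
        for a in (m, means, scales):
            a.setflags(write=False)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "feature_means", means)
        object.__setattr__(self, "feature_scales", scales)


def standardize_matrix(X: np.ndarray) -> StandardizedDesign:
    """Z-score the columns of an n × p matrix (population SD)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("standardization needs a 2-D matrix with n >= 2 rows")
    means = X.mean(axis=0)
    scales = X.std(axis=0)  # population (divide-by-n) SD
    if np.any(scales <= 0):
        bad = np.flatnonzero(scales <= 0)
        raise ValidationError(f"zero-variance feature column(s) {bad.tolist()}")
    return StandardizedDesign((X - means) / scales, means, scales)


def standardize(design: DesignTable) -> StandardizedDesign:
    """Standardize a design table: remove the mean, scale to unit variance."""
    return standardize_matrix(design.to_matrix())


def apply_standardization(
    settings: ProcessSettings | np.ndarray, std: StandardizedDesign
) -> np.ndarray:
    """Map raw settings into the trained feature scale, (x − mean) / scale."""
    x = settings.as_vector() if isinstance(settings, ProcessSettings) else np.asarray(settings, float)
    return (x - std.feature_means) / std.feature_scales


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def read_design_csv(path: str | Path) -> DesignTable:
    """Read a design table.

    Expected header: ``experiment,throughput_kg_h,screw_speed_rpm,ls_ratio``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"design CSV missing column(s) {missing}")
    for col in FEATURE_NAMES:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValidationError(f"non-numeric values in column {col!r}")
        if df[col].isna().any():
            raise ValidationError(f"missing values in column {col!r}")
    settings = [
        ProcessSettings(row.throughput_kg_h, row.screw_speed_rpm, row.ls_ratio)
        for row in df.itertuples()
    ]
    return DesignTable(tuple(df["experiment"].astype(str)), tuple(settings))


def write_design_csv(table: DesignTable, path: str | Path) -> None:
    df = pd.DataFrame(table.to_matrix(), columns=list(FEATURE_NAMES))
    df.insert(0, "experiment", list(table.experiment_ids))
    df.to_csv(path, index=False)


def _bin_columns(n_bins: int) -> list:
    width = max(2, len(str(n_bins)))
    return [f"bin_{i + 1:0{width}d}" for i in range(n_bins)]


def read_histograms_csv(
    path: str | Path, grid: SizeGrid, renormalize: bool = False
) -> tuple:
    """Read per-experiment histograms.

    One row per experiment: an ``experiment`` id column followed by
    ``grid.n_bins`` numeric weight columns.  With ``renormalize=True``,
    nonnegative rows with positive sum are rescaled to sum to one.

    Returns
    -------
    (experiment_ids, histograms) : (tuple of str, list of PSDHistogram)
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "experiment" not in df.columns:
        raise ValidationError("histograms CSV must have an 'experiment' column")
    value_cols = [c for c in df.columns if c != "experiment"]
    if len(value_cols) != grid.n_bins:
        raise ValidationError(
            f"expected {grid.n_bins} weight columns, found {len(value_cols)}"
        )
    values = df[value_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("histogram CSV contains non-finite values")
    histograms = []
    for i, row in enumerate(values):
        if np.any(row < 0):
            raise ValidationError(f"negative weight in histogram row {i}")
        if renormalize:
            total = row.sum()
            if total <= 0:
                raise ValidationError(f"zero-sum histogram row {i}")
            row = row / total
        histograms.append(PSDHistogram(grid, row))
    return tuple(df["experiment"].astype(str)), histograms


def write_histograms_csv(
    histograms: Sequence[PSDHistogram],
    path: str | Path,
    experiment_ids: Iterable | None = None,
) -> None:
    if not histograms:
        raise ValidationError("nothing to write")
    n_bins = histograms[0].grid.n_bins
    ids = (
        list(map(str, experiment_ids))
        if experiment_ids is not None
        else [f"E{i + 1}" for i in range(len(histograms))]
    )
    if len(ids) != len(histograms):
        raise ValidationError("experiment_ids length must match histograms")
    df = pd.DataFrame(
        np.array([h.weights for h in histograms]), columns=_bin_columns(n_bins)
    )
    df.insert(0, "experiment", ids)
    df.to_csv(path, index=False, float_format="%.17g")
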