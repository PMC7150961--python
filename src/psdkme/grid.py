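"""Logarithmic particle-size grids.

Granule sizes span three orders of magnitude (a few μm to a few mm), so
histograms are binned on a geometrically spaced grid.  The default grid has
35 bins between 8.46 μm and 6765.36 μm, matching the bin layout of the
dynamic image-analysis instrument the method was designed around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

#: default grid layout: 35 log-spaced bins between 8.46 and 6765.36 μm
DEFAULT_N_BINS = 35
DEFAULT_LO_UM = 8.46
DEFAULT_HI_UM = 6765.36


@dataclass(frozen=True)
class SizeGrid:
    """A geometrically spaced size grid in μm.

    Parameters
    ----------
    bin_edges : ndarray of shape (n_bins + 1,)
        Strictly increasing, strictly positive bin edges in μm.  The ratio
        between consecutive edges must be constant (log spacing).

    Attributes
    ----------
    bin_centers : ndarray of shape (n_bins,)
        Geometric means of adjacent edges.
    log10_centers : ndarray of shape (n_bins,)
        Base-10 logarithms of the centers; equally spaced.
    """

    bin_edges: np.ndarray
    bin_centers: np.ndarray = field(init=False, repr=False)
    log10_centers: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValidationError("bin_edges must be a 1-D array of length >= 2")
        if edges[0] <= 0:
            raise ValidationError("bin edges must be strictly positive")
        if not np.all(np.diff(edges) > 0):
            raise ValidationError("bin edges must be strictly increasing")
        ratios = edges[1:] / edges[:-1]
        if np.ptp(ratios) > 1e-10 * ratios[0]:
            raise ValidationError("bin edges must be geometrically (log) spaced")
        edges.setflags(write=False)
        object.__setattr__(self, "bin_edges", edges)
        centers = np.sqrt(edges[:-1] * edges[1:])
        centers.setflags(write=False)
        object.__setattr__(self, "bin_centers", centers)
        log10c = np.log10(centers)
        log10c.setflags(write=False)
        object.__setattr__(self, "log10_centers", log10c)

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    def __eq__(self, other) -> bool:
        return isinstance(other, SizeGrid) and np.array_equal(
            self.bin_edges, other.bin_edges
        )

    def __hash__(self) -> int:
        return hash(self.bin_edges.tobytes())


def build_log_grid(
    n_bins: int = DEFAULT_N_BINS,
    lo: float = DEFAULT_LO_UM,
    hi: float = DEFAULT_HI_UM,
    mode: str = "edges",
) -> SizeGrid:
    """Construct a log-spaced :class:`SizeGrid`.

    Parameters
    ----------
    n_bins : int
        Number of bins (intervals).
    lo, hi : float
        Grid extent in μm, ``0 < lo < hi``.
    mode : {"edges", "centers"}
        With ``"edges"`` (default) `lo` and `hi` are the outermost bin
        *edges*; with ``"centers"`` they are the outermost bin *centers*
        and the edges are extrapolated half a log-step beyond them.
    """
    if n_bins < 1:
        raise ValidationError(f"n_bins must be >= 1, got {n_bins}")
    if not 0 < lo < hi:
        raise ValidationError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if mode == "edges":
        edges = np.geomspace(lo, hi, n_bins + 1)
    elif mode == "centers":
        if n_bins < 2:
            raise ValidationError("mode='centers' requires n_bins >= 2")
        step = (hi / lo) ** (1.0 / (n_bins - 1))
        edges = np.geomspace(lo / np.sqrt(step), hi * np.sqrt(step), n_bins + 1)
    else:
        raise ValidationError(f"unknown grid mode {mode!r}")
    return SizeGrid(bin_edges=edges)
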