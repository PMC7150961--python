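"""Synthetic granulation datasets with known ground truth.

No public dataset pairs twin-screw wet-granulation settings with measured
particle size distributions, so this module generates them: each operating
point produces a two-component lognormal mixture on the log size grid — a
fines mode and a coarse (granule) mode — whose coarse fraction and coarse
median depend smoothly on the standardized settings.  This reproduces the
shape repertoire seen in practice (monomodal, strongly skewed, bimodal) and
gives every other module a ground truth to recover.  Optional multinomial
count noise emulates finite counting statistics of an image-analysis
sensor.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .data import (
    DesignTable,
    ProcessSettings,
    PSDHistogram,
    StandardizedDesign,
    read_design_csv,
    standardize,
)
from .exceptions import ValidationError
from .grid import SizeGrid


@dataclass(frozen=True)
class ScenarioParams:
    """Ground-truth response surface of the synthetic granulator.

    The histogram at standardized settings z is the bin mass of the mixture

        π(z)·LogNormal(m_c(z), s_c) + (1 − π(z))·LogNormal(m_f, s_f)

    in log10 μm, renormalized over the grid support, with
    π(z) = logistic(c₀ + c·z) and m_c(z) = m_c⁰ + b·z.  Defaults place the
    fines mode at 50 μm and the coarse mode near 1 mm, with the
    liquid-to-solid ratio the dominant driver of both the coarse fraction
    and the coarse median (wetter granulation → larger granules), and mild
    negative throughput / screw-speed effects.

    count_n = 0 means noise-free bin masses; count_n ≥ 1 draws that many
    multinomial counts per experiment.
    """

    fines_log10_median: float = np.log10(50.0)
    fines_log10_sd: float = 0.35
    coarse_log10_median_base: float = 3.0
    coarse_log10_sd: float = 0.25
    #: intercept + slopes on standardized (throughput, screw_speed, ls_ratio)
    coarse_fraction_coeffs: tuple = (-0.2, -0.15, -0.10, 0.8)
    #: slopes of the coarse log10 median on the standardized settings
    coarse_shift_coeffs: tuple = (0.05, -0.05, 0.20)
    count_n: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fines_log10_sd <= 0 or self.coarse_log10_sd <= 0:
            raise ValidationError("lognormal sds must be strictly positive")
        if len(self.coarse_fraction_coeffs) != 4 or len(self.coarse_shift_coeffs) != 3:
            raise ValidationError("need 4 fraction and 3 shift coefficients")
        if self.count_n < 0:
            raise ValidationError("count_n must be >= 0 (0 = noise-free)")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScenarioParams":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            p = Path(source)
            text = p.read_text() if p.exists() else str(source)
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"invalid scenario JSON: {exc}") from exc
        d["coarse_fraction_coeffs"] = tuple(d["coarse_fraction_coeffs"])
        d["coarse_shift_coeffs"] = tuple(d["coarse_shift_coeffs"])
        return cls(**d)


def load_table1_design() -> DesignTable:
    """The packaged 29-run design: a 3³ factorial over throughput
    {5, 12.5, 25} kg/h, screw speed {450, 675, 900} rpm, L/S
    {0.3, 0.45, 0.6}, plus four star points on the L/S axis."""
    with resources.as_file(
        resources.files("psdkme.datasets") / "design_29run.csv"
    ) as path:
        return read_design_csv(path)


def generate_factorial_design(
    throughput_levels: Sequence,
    screw_speed_levels: Sequence,
    ls_levels: Sequence,
    id_prefix: str = "F",
) -> DesignTable:
    """Full-factorial Cartesian product in deterministic (nested-loop) order."""
    if not (len(throughput_levels) and len(screw_speed_levels) and len(ls_levels)):
        raise ValidationError("all level lists must be non-empty")
    ids, settings = [], []
    i = 0
    for t in throughput_levels:
        for s in screw_speed_levels:
            for ls in ls_levels:
                i += 1
                ids.append(f"{id_prefix}{i}")
                settings.append(ProcessSettings(float(t), float(s), float(ls)))
    return DesignTable(tuple(ids), tuple(settings))


def true_histogram(
    settings: ProcessSettings,
    scenario: ScenarioParams,
    grid: SizeGrid,
    std: StandardizedDesign,
) -> PSDHistogram:
    """Noise-free ground-truth histogram at one operating point."""
    z = (settings.as_vector() - std.feature_means) / std.feature_scales
    c0, *slopes = scenario.coarse_fraction_coeffs
    pi = float(expit(c0 + np.dot(slopes, z)))
    coarse_median = scenario.coarse_log10_median_base + float(
        np.dot(scenario.coarse_shift_coeffs, z)
    )
    log_edges = np.log10(grid.bin_edges)
    coarse_cdf = norm.cdf(log_edges, loc=coarse_median, scale=scenario.coarse_log10_sd)
    fines_cdf = norm.cdf(
        log_edges, loc=scenario.fines_log10_median, scale=scenario.fines_log10_sd
    )
    mass = pi * np.diff(coarse_cdf) + (1.0 - pi) * np.diff(fines_cdf)
    mass = np.clip(mass, 0.0, None)
    total = mass.sum()
    if total <= 0:
        raise ValidationError("scenario puts no mass on the grid support")
    return PSDHistogram(grid, mass / total)


def sample_histogram(true_h: PSDHistogram, count_n: int, seed) -> PSDHistogram:
    """Multinomial count noise: draw count_n particles from the true bin masses."""
    if count_n < 1:
        raise ValidationError("count_n must be >= 1 when sampling")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(count_n), true_h.weights)
    return PSDHistogram(true_h.grid, counts / float(count_n))


def _stream_seed(scenario_seed: int, experiment_id: str):
    # tie the noise stream to the experiment id, not the row position, so
    # reordering the design reproduces the same per-experiment draws
    return np.random.SeedSequence([scenario_seed, zlib.crc32(experiment_id.encode())])


def generate_dataset(
    design: DesignTable,
    scenario: ScenarioParams,
    grid: SizeGrid,
) -> tuple:
    """One histogram per design row; noise-free when scenario.count_n == 0.

    Returns ``(design, histograms)``.  Standardization constants for the
    response surface are computed from this design, so the scenario
    coefficients act on z-scores of the supplied design.
    """
    std = standardize(design)
    histograms = []
    for exp_id, settings in zip(design.experiment_ids, design.settings):
        h = true_histogram(settings, scenario, grid, std)
        if scenario.count_n > 0:
            h = sample_histogram(h, scenario.count_n, _stream_seed(scenario.seed, exp_id))
        histograms.append(h)
    return design, histograms


def interior_mask(design: DesignTable) -> np.ndarray:
    """True for rows whose every setting lies strictly inside the design range."""
    X = design.to_matrix()
    lo, hi = X.min(axis=0), X.max(axis=0)
    return np.all((X > lo) & (X < hi), axis=1)
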