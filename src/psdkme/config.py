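"""Run configuration: a validated, serializable bundle of hyperparameters."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ValidationError
from .grid import DEFAULT_HI_UM, DEFAULT_LO_UM, DEFAULT_N_BINS, SizeGrid, build_log_grid

_SECTIONS = {"grid", "kernel_k", "kernel_l", "lambda", "preimage", "metrics", "seed"}


@dataclass
class RunConfig:
    """All tunables of a pipeline run, with the calibration defaults.

    Mirrors the config file schema: sections ``grid``, ``kernel_k``,
    ``kernel_l``, ``lambda``, ``preimage``, ``metrics`` and a top-level
    ``seed``.
    """

    grid_n_bins: int = DEFAULT_N_BINS
    grid_lo_um: float = DEFAULT_LO_UM
    grid_hi_um: float = DEFAULT_HI_UM
    grid_mode: str = "edges"
    # equals exp(-0.1·d²): the settings-kernel coefficient γ = 1/(2σ²) = 0.1
    kernel_k_bandwidth_sq: float = 5.0
    kernel_k_bias: float = 0.05
    kernel_l_bandwidth: object = "median"  # "median" or a σ² value
    kernel_l_bias: float = 0.1
    lambda_mode: str = "loocv"  # "loocv" or "fixed"
    lambda_value: float = 1e-4
    lambda_search_lo: float = 1e-8
    lambda_search_hi: float = 1e2
    preimage_regularizer: float | None = None
    preimage_solver_tol: float = 1e-8
    metrics_use_biased_l: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_mode not in ("edges", "centers"):
            raise ValidationError(f"grid_mode must be edges|centers, got {self.grid_mode!r}")
        if self.lambda_mode not in ("loocv", "fixed"):
            raise ValidationError(f"lambda mode must be loocv|fixed, got {self.lambda_mode!r}")
        if self.kernel_l_bandwidth != "median" and float(self.kernel_l_bandwidth) <= 0:
            raise ValidationError("kernel_l bandwidth must be 'median' or > 0")
        if self.kernel_k_bandwidth_sq <= 0:
            raise ValidationError("kernel_k bandwidth_sq must be > 0")
        if self.kernel_k_bias < 0 or self.kernel_l_bias < 0:
            raise ValidationError("diagonal biases must be nonnegative")

    def build_grid(self) -> SizeGrid:
        return build_log_grid(self.grid_n_bins, self.grid_lo_um, self.grid_hi_um, self.grid_mode)

    def estimator_params(self) -> dict:
        """Keyword arguments for KernelMeanEmbeddingRegressor."""
        return {
            "kernel_x_bandwidth_sq": self.kernel_k_bandwidth_sq,
            "kernel_x_bias": self.kernel_k_bias,
            "kernel_y_bandwidth": self.kernel_l_bandwidth,
            "kernel_y_bias": self.kernel_l_bias,
            "lam": "loocv" if self.lambda_mode == "loocv" else self.lambda_value,
            "search_lo": self.lambda_search_lo,
            "search_hi": self.lambda_search_hi,
            "preimage_regularizer": self.preimage_regularizer,
            "solver_tol": self.preimage_solver_tol,
        }

    def to_dict(self) -> dict:
        return {
            "grid": {
                "n_bins": self.grid_n_bins,
                "lo_um": self.grid_lo_um,
                "hi_um": self.grid_hi_um,
                "grid_mode": self.grid_mode,
            },
            "kernel_k": {
                "bandwidth_sq": self.kernel_k_bandwidth_sq,
                "diagonal_bias": self.kernel_k_bias,
            },
            "kernel_l": {
                "bandwidth": self.kernel_l_bandwidth,
                "diagonal_bias": self.kernel_l_bias,
            },
            "lambda": {
                "mode": self.lambda_mode,
                "value": self.lambda_value,
                "search_lo": self.lambda_search_lo,
                "search_hi": self.lambda_search_hi,
            },
            "preimage": {
                "regularizer": self.preimage_regularizer,
                "solver_tol": self.preimage_solver_tol,
            },
            "metrics": {"use_biased_l": self.metrics_use_biased_l},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _SECTIONS
        if unknown:
            raise ValidationError(f"unknown config section(s) {sorted(unknown)}")
        g = d.get("grid", {})
        kk = d.get("kernel_k", {})
        kl = d.get("kernel_l", {})
        la = d.get("lambda", {})
        pre = d.get("preimage", {})
        met = d.get("metrics", {})
        defaults = cls()
        return cls(
            grid_n_bins=g.get("n_bins", defaults.grid_n_bins),
            grid_lo_um=g.get("lo_um", defaults.grid_lo_um),
            grid_hi_um=g.get("hi_um", defaults.grid_hi_um),
            grid_mode=g.get("grid_mode", defaults.grid_mode),
            kernel_k_bandwidth_sq=kk.get("bandwidth_sq", defaults.kernel_k_bandwidth_sq),
            kernel_k_bias=kk.get("diagonal_bias", defaults.kernel_k_bias),
            kernel_l_bandwidth=kl.get("bandwidth", defaults.kernel_l_bandwidth),
            kernel_l_bias=kl.get("diagonal_bias", defaults.kernel_l_bias),
            lambda_mode=la.get("mode", defaults.lambda_mode),
            lambda_value=la.get("value", defaults.lambda_value),
            lambda_search_lo=la.get("search_lo", defaults.lambda_search_lo),
            lambda_search_hi=la.get("search_hi", defaults.lambda_search_hi),
            preimage_regularizer=pre.get("regularizer", defaults.preimage_regularizer),
            preimage_solver_tol=pre.get("solver_tol", defaults.preimage_solver_tol),
            metrics_use_biased_l=met.get("use_biased_l", defaults.metrics_use_biased_l),
            seed=d.get("seed", defaults.seed),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ValidationError("config file must contain a mapping")
        return cls.from_dict(data)
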