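"""Run configuration: YAML schema, validation, and stage-seed derivation."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .dvh import DEFAULT_ALPHA_BETA, DEFAULT_DX_GRID
from .errors import ConfigurationError, SchemaError
from .lasso import LambdaRule
from .screen import DEFAULT_ALWAYS_INCLUDE

#: Which structures' dosimetric variables feed each endpoint's model.
DEFAULT_ENDPOINT_STRUCTURES: dict[str, tuple[str, ...]] = {
    "esophagitis": ("esophagus",),
    "pneumonitis": ("lung", "heart"),
}

#: Clinical variables dropped before modeling because they duplicate the
#: treatment-days information.
DEFAULT_EXCLUDE = ("dose_per_fraction", "fraction_number")


@dataclass
class RunConfig:
    endpoint: str = "esophagitis"
    seed: int = 0
    n_boot: int = 1000
    screening_alpha: float = 0.1
    correlation_threshold: float = 0.75
    split_fractions: tuple[float, float] = (2 / 3, 1 / 3)
    lambda_rule: LambdaRule = field(default_factory=LambdaRule)
    alpha_beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHA_BETA))
    dx_grid: tuple[int, ...] = DEFAULT_DX_GRID
    always_include: tuple[str, ...] = DEFAULT_ALWAYS_INCLUDE
    exclude_features: tuple[str, ...] = DEFAULT_EXCLUDE
    endpoint_structures: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ENDPOINT_STRUCTURES)
    )
    fractional_on_physical: bool = True
    calibration_bins: int = 6
    synthetic_n_patients: int | None = None  # set -> simulate instead of reading files
    dvh_csv: str | None = None
    clinical_csv: str | None = None

    def __post_init__(self) -> None:
        if not self.endpoint:
            raise SchemaError("config missing endpoint")
        if not 0 <= self.screening_alpha <= 1:
            raise ConfigurationError("screening_alpha must lie in [0, 1]")
        if not 0 <= self.correlation_threshold <= 1:
            raise ConfigurationError("correlation_threshold must lie in [0, 1]")
        if abs(sum(self.split_fractions) - 1.0) > 1e-6:
            raise ConfigurationError("split_fractions must sum to 1")
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")
        if self.calibration_bins < 2:
            raise ConfigurationError("calibration_bins must be >= 2")
        if self.synthetic_n_patients is None:
            for name in ("dvh_csv", "clinical_csv"):
                path = getattr(self, name)
                if path is None:
                    raise SchemaError(f"config needs {name} (or a synthetic section)")
                if not Path(path).exists():
                    raise ConfigurationError(f"{name} does not exist: {path}")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big")

    @property
    def run_id(self) -> str:
        return f"{self.endpoint}-seed{self.seed}"


def load_config(path: str | Path, seed_override: int | None = None) -> RunConfig:
    """Load a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"config file {path} must contain a mapping")
    return config_from_dict(raw, seed_override=seed_override)


def config_from_dict(raw: Mapping, seed_override: int | None = None) -> RunConfig:
    raw = dict(raw)
    kwargs: dict = {}
    for key in (
        "endpoint",
        "seed",
        "n_boot",
        "screening_alpha",
        "correlation_threshold",
        "fractional_on_physical",
        "calibration_bins",
        "dvh_csv",
        "clinical_csv",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "split_fractions" in raw:
        kwargs["split_fractions"] = tuple(float(v) for v in raw["split_fractions"])
    if "lambda_rule" in raw:
        kwargs["lambda_rule"] = LambdaRule(**raw["lambda_rule"])
    if "alpha_beta" in raw:
        kwargs["alpha_beta"] = {str(k): float(v) for k, v in raw["alpha_beta"].items()}
    if "dx_grid" in raw:
        kwargs["dx_grid"] = tuple(int(v) for v in raw["dx_grid"])
    if "always_include" in raw:
        kwargs["always_include"] = tuple(raw["always_include"])
    if "exclude_features" in raw:
        kwargs["exclude_features"] = tuple(raw["exclude_features"])
    if "endpoint_structures" in raw:
        kwargs["endpoint_structures"] = {
            str(k): tuple(v) for k, v in raw["endpoint_structures"].items()
        }
    if "synthetic" in raw and raw["synthetic"] is not None:
        synth = raw["synthetic"]
        kwargs["synthetic_n_patients"] = int(synth.get("n_patients", 258))
    if seed_override is not None:
        kwargs["seed"] = int(seed_override)
    unknown = set(raw) - {
        "endpoint",
        "seed",
        "n_boot",
        "screening_alpha",
        "correlation_threshold",
        "fractional_on_physical",
        "calibration_bins",
        "dvh_csv",
        "clinical_csv",
        "split_fractions",
        "lambda_rule",
        "alpha_beta",
        "dx_grid",
        "always_include",
        "exclude_features",
        "endpoint_structures",
        "synthetic",
    }
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**kwargs)
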