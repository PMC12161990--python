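"""Run configuration: one object carries every tunable of the pipeline."""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("resort")

NEIGHBOR_SCHEMES = ("grid4", "grid8", "hex6")
DOWNSAMPLE_MODES = ("binomial",)


class ConfigError(ValueError):
    """Raised when a configuration value is out of range."""


@dataclass
class RunConfig:
    """All tunables of the simulate → regions → deconvolve pipeline.

    Attributes
    ----------
    rng_seed
        Seed for every source of randomness in a run.
    downsample_rate
        Per-read retention probability when thinning sampled cells' counts
        (default 0.10, keeping simulated spot libraries at the depth of a
        typical Visium spot).
    cells_per_spot
        Number of cells captured per spot (default 10).
    infiltration_fraction, infiltration_mu, infiltration_sigma
        Fraction of pure tumour spots receiving artificial immune cells, and
        the Gaussian parameters of the injected immune proportion
        (defaults 0.10, 0.5, 0.2).
    k_pcs
        Number of principal components for the spot-similarity embedding.
    min_region_size
        Minimum connected-component size ``m`` for a molecular region
        (default 40, the Visium-scale default).
    epsilon
        Optional manual edge-weight threshold; ``None`` selects it
        automatically.
    neighbor_scheme
        Grid adjacency: ``grid4`` (rook), ``grid8`` (queen) or ``hex6``.
    infiltration_call_threshold
        Estimated immune proportion above which a tumour spot is called
        infiltrated (default 0.05).
    noise_sd
        SD of the Gaussian affinity noise δ in the layout simulator.
    downsample_mode
        Read-thinning model; ``binomial`` retains each read independently.
    sample_with_replacement
        Allow re-drawing reference cells when a spot requests more cells of a
        type than the reference holds.
    """

    rng_seed: int = 0
    downsample_rate: float = 0.10
    cells_per_spot: int = 10
    infiltration_fraction: float = 0.10
    infiltration_mu: float = 0.5
    infiltration_sigma: float = 0.2
    k_pcs: int = 10
    min_region_size: int = 40
    epsilon: float | None = None
    neighbor_scheme: str = "grid4"
    infiltration_call_threshold: float = 0.05
    noise_sd: float = 0.05
    downsample_mode: str = "binomial"
    sample_with_replacement: bool = False

    def __post_init__(self) -> None:
        for name in (
            "downsample_rate",
            "infiltration_fraction",
            "infiltration_mu",
            "infiltration_sigma",
            "infiltration_call_threshold",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.cells_per_spot < 1:
            raise ConfigError("cells_per_spot must be >= 1")
        if self.min_region_size < 1:
            raise ConfigError("min_region_size m must be >= 1")
        if self.k_pcs < 1:
            raise ConfigError("k_pcs must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.neighbor_scheme not in NEIGHBOR_SCHEMES:
            raise ConfigError(
                f"neighbor_scheme must be one of {NEIGHBOR_SCHEMES}, "
                f"got {self.neighbor_scheme!r}"
            )
        if self.downsample_mode not in DOWNSAMPLE_MODES:
            raise ConfigError(
                f"downsample_mode must be one of {DOWNSAMPLE_MODES}, "
                f"got {self.downsample_mode!r}"
            )
        if self.epsilon is not None and not -1.0 <= self.epsilon <= 1.0:
            raise ConfigError("epsilon must lie in [-1, 1]")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a TOML or YAML config file; keyword overrides win."""
        path = Path(path)
        if path.suffix.lower() == ".toml":
            data = tomllib.loads(path.read_text())
        elif path.suffix.lower() in {".yaml", ".yml"}:
            data = yaml.safe_load(path.read_text()) or {}
        else:
            raise ConfigError(f"unsupported config format: {path.suffix!r}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config keys in {path}: {unknown}")
        data.update(overrides)
        return cls(**data)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)

    def log_resolved(self) -> None:
        """Log every resolved field so a run is reproducible from its log."""
        fields = ", ".join(
            f"{f.name}={getattr(self, f.name)!r}" for f in dataclasses.fields(self)
        )
        logger.info("resolved config: %s", fields)
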