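"""Run configuration: one validated object drives the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .models import STANDARD_MODELS


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    A single `seed` feeds every stochastic stage through named substreams;
    the config is echoed verbatim into the run manifest.
    """

    outdir: str = "rsfavasc_out"
    seed: int = 0

    # cohort
    n_subjects: int = 250
    grid_dims: tuple[int, int, int] = (16, 16, 16)
    n_sources: int = 4
    direct_age_effect: float = 0.0
    bold_subjects: int = 2  # subjects for the BOLD round-trip demonstration

    # RSFA estimation
    band: tuple[float, float] = (0.0078, 0.1)
    normalization: str = "mean"
    nuisance_tissue_threshold: float = 0.7

    # factors / ICA
    n_factors: int = 3
    ica_order: int | str = "mdl"

    # models
    models: tuple[str, ...] = ("I", "II", "III", "IV", "V", "VI")
    q: float = 0.05
    robust: bool = True
    level: str = "voxel"

    # permutation test
    permutations: int = 199
    alpha: float = 0.05
    permtest_models: tuple[str, ...] = ("I", "IV")
    analysis_tissue_threshold: float = 0.4

    def __post_init__(self) -> None:
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        self.models = tuple(self.models)
        self.permtest_models = tuple(self.permtest_models)
        self.band = tuple(float(b) for b in self.band)
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError(f"invalid band {self.band}")
        if self.normalization not in ("mean", "raw"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        for m in self.models + self.permtest_models:
            if m not in STANDARD_MODELS:
                raise ValueError(f"unknown model id {m!r}")
        if not 0 < self.q < 1 or not 0 < self.alpha < 1:
            raise ValueError("q and alpha must lie in (0, 1)")
        if self.permutations < 19:
            raise ValueError("need at least 19 permutations")
        if self.level not in ("voxel", "component"):
            raise ValueError(f"unknown level {self.level!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_dims"] = list(self.grid_dims)
        d["band"] = list(self.band)
        d["models"] = list(self.models)
        d["permtest_models"] = list(self.permtest_models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path
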