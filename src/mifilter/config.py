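"""Run configuration: defaults, YAML round-trip and provenance metadata."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .loss import default_quantile_grid
from .network import default_tau_grid

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline settings, serialisable into every artifact's header.

    Defaults: equal-width Sturges binning, τ grid 0.05–0.95 (step 0.05),
    quantile grid 0.01–0.96 (step 0.05), 500 permutations and bootstrap
    resamples, α = 0.05.
    """

    discretization_method: str = "equal_width"
    n_bins: int | str = "sturges"
    tau_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(float(t) for t in default_tau_grid())
    )
    quantile_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(float(q) for q in default_quantile_grid())
    )
    n_permutations: int = 500
    n_bootstrap: int = 500
    alpha: float = 0.05
    seed: int = 0
    trad1_thresholds: tuple[float, ...] = (0.001, 0.01, 0.05)
    trad2_min_reads: int = 5
    trad2_min_samples: int = 3
    trad3_min_prevalence: int = 5

    def scheme(self):
        from .mi import DiscretizationScheme

        return DiscretizationScheme(self.discretization_method, self.n_bins)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key in ("tau_grid", "quantile_grid", "trad1_thresholds"):
            if key in data:
                data[key] = tuple(float(v) for v in data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        data = self.to_dict()
        data = {
            k: list(v) if isinstance(v, tuple) else v for k, v in data.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)
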