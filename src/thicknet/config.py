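"""Run configuration: parameters of a full pipeline run, YAML round-trippable."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import SpecError
from .graphs import CostGrid

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    Defaults use desk-scale permutation and null-ensemble counts (200 and
    100); the full-scale study values (2000 permutations, 1000 null networks
    per cost) are available by overriding ``n_permutations`` and
    ``n_null_networks``.
    """

    thickness_path: str = ""
    atlas_path: str = ""
    output_dir: str = "thicknet_run"
    cost_min: float = 0.01
    cost_max: float = 0.50
    cost_step: float = 0.01
    n_permutations: int = 200
    n_null_networks: int = 100
    alpha: float = 0.05
    covariates: tuple[str, ...] = ("age", "gender", "mean_thickness")
    seed: int = 0
    nbr_convention: str = "paper"

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)
        if not 0 < self.cost_min < self.cost_max < 1:
            raise SpecError(
                f"need 0 < cost_min < cost_max < 1, got {self.cost_min}, {self.cost_max}"
            )
        if self.cost_step <= 0:
            raise SpecError("cost_step must be positive")
        if self.n_permutations < 1:
            raise SpecError("n_permutations must be at least 1")
        if self.n_null_networks < 1:
            raise SpecError("n_null_networks must be at least 1")
        if not 0 < self.alpha < 1:
            raise SpecError("alpha must lie in (0, 1)")
        if self.nbr_convention not in ("paper", "neighbors_only"):
            raise SpecError(
                f"nbr_convention must be 'paper' or 'neighbors_only', got {self.nbr_convention!r}"
            )

    def cost_grid(self) -> CostGrid:
        return CostGrid.from_range(self.cost_min, self.cost_max, self.cost_step)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        return d

    def config_hash(self) -> str:
        """Stable short hash identifying the parameter set (echoed in outputs)."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise SpecError(f"config file {path} is not a key-value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise SpecError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
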