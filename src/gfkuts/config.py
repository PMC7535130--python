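"""Run configuration: YAML file with CLI override precedence."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All stage parameters of the segmentation + estimation workflow."""

    # trimap / GrabCut
    l: int = 1000
    n: int = 5
    K: int = 5
    gamma: float = 50.0
    # guided filter + threshold
    r: int = 8
    epsilon: float = 1e-3
    threshold_method: str = "otsu"
    # evaluation
    region: int = 10
    # biomass models
    hidden: int = 15
    split: float = 0.6
    alpha: float = 1e-3
    r_mix: float = 0.5
    per_stage: bool = False
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l < 2:
            raise ValueError("l must be >= 2")
        if self.n < 1 or self.K < 1 or self.r < 1 or self.region < 1 or self.hidden < 1:
            raise ValueError("n, K, r, region and hidden must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if not 0 < self.split < 1:
            raise ValueError("split must lie in (0, 1)")
        if self.alpha < 0 or not 0 <= self.r_mix <= 1:
            raise ValueError("alpha must be >= 0 and r_mix in [0, 1]")
        if self.threshold_method not in ("otsu", "local"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        """Build from an optional YAML file; keyword overrides win.

        Unknown keys in either source are rejected by name.
        """
        data: dict = {}
        if path is not None:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: config must be a mapping")
            data.update(loaded)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
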