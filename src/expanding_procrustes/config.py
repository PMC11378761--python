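"""Run configuration with the study's defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunables of an end-to-end run.

    Defaults reproduce the published analysis settings: dissimilarity
    threshold tau = 0.15, sliding window = 10% of the curve, extremum
    prominence = 10% of the series range, trials averaged at the rounded
    mean trial length.
    """

    tau: float = 0.15
    window_frac: float = 0.10
    resample_policy: str = "mean_length"  # or "fixed:<N>"
    prominence_frac: float = 0.10
    min_separation: int = 5
    allow_reflection: bool = True
    epsilon: float = 1e-6
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie in (0, 1)")
        if not 0.0 < self.window_frac <= 1.0:
            raise ValueError("window_frac must lie in (0, 1]")
        if not 0.0 < self.prominence_frac <= 1.0:
            raise ValueError("prominence_frac must lie in (0, 1]")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.resample_policy != "mean_length":
            tag, _, num = self.resample_policy.partition(":")
            if tag != "fixed" or not num.isdigit() or int(num) < 2:
                raise ValueError(
                    "resample_policy must be 'mean_length' or 'fixed:<N>' with N >= 2"
                )

    @property
    def fixed_length(self) -> int | None:
        if self.resample_policy.startswith("fixed:"):
            return int(self.resample_policy.split(":")[1])
        return None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)
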