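"""Run configuration: one serialisable object drives a full analysis."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig"]

_VALID_VARIANTS = {"ridge", "quadratic", "sex_before_pca", "oos_stacking"}


@dataclass
class RunConfig:
    """Everything a run needs; copied verbatim into its output directory.

    ``cohort`` selects the input: ``{"preset": "demo"|"study", ...}``
    generates a synthetic cohort (extra keys are passed to the preset),
    while ``{"manifest": "path/to/manifest.json"}`` loads user-supplied
    tables. ``grid`` is "full" (70 x 25) or "reduced" (7 x 5).
    """

    seed: int = 0
    cohort: dict = field(default_factory=lambda: {"preset": "demo"})
    grid: str = "reduced"
    n_components: int = 20
    variants: list = field(default_factory=list)
    importance: bool = True
    out_dir: str = "run"

    def __post_init__(self) -> None:
        if self.grid not in ("full", "reduced"):
            raise ValueError("grid must be 'full' or 'reduced'")
        bad = set(self.variants) - _VALID_VARIANTS
        if bad:
            raise ValueError(f"unknown variants {sorted(bad)}; valid: {sorted(_VALID_VARIANTS)}")
        if "preset" not in self.cohort and "manifest" not in self.cohort:
            raise ValueError("cohort must give a 'preset' or a 'manifest'")

    def has(self, variant: str) -> bool:
        return variant in self.variants

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(raw)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
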