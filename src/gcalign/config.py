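"""Runtime configuration: defaults, YAML config files, CLI overrides."""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import ParameterError
from .io import Dialect

__all__ = ["AlignConfig", "load_config"]


@dataclass
class AlignConfig:
    """Operating point of the alignment method.

    Stock values: mixture weight w = 0.1, candidate threshold h = 40 on the
    angle score scale, posterior cutoff 0.9.
    """

    w: float = 0.1
    h_threshold: float = 40.0
    cutoff: float = 0.9
    score_scale: str = "angle"
    pairing: str = "consecutive"
    normalize_ranks: bool = False
    f_F_components: int = 1
    seed: Optional[int] = None
    dialect: Optional[dict] = None

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ParameterError(f"w must lie in [0, 1], got {self.w}")
        if not 0.0 <= self.cutoff <= 1.0:
            raise ParameterError(f"cutoff must lie in [0, 1], got {self.cutoff}")
        if self.score_scale not in ("angle", "normalized"):
            raise ParameterError(f"unknown score scale {self.score_scale!r}")

    def make_dialect(self) -> Optional[Dialect]:
        return Dialect.from_mapping(self.dialect) if self.dialect else None

    def override(self, **kwargs) -> "AlignConfig":
        """New config with non-None overrides applied (CLI beats file)."""
        clean = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **clean)


def load_config(path: Optional[Union[str, Path]] = None, **overrides) -> AlignConfig:
    """Load YAML config (keys mirror CLI flags) and apply overrides."""
    base: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ParameterError(f"{path}: config must be a mapping")
        known = set(AlignConfig.__dataclass_fields__)
        unknown = set(loaded) - known
        if unknown:
            raise ParameterError(f"{path}: unknown config keys {sorted(unknown)}")
        base = loaded
    cfg = AlignConfig(**base)
    return cfg.override(**overrides)
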