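"""Run configuration (YAML-backed) for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .dose_response import MCID

__all__ = ["RunConfig", "load_config"]

_DEFAULT_CERTAINTY = {
    "AT": "moderate",
    "RT": "moderate",
    "CT": "moderate",
    "HIIT": "very_low",
    "MBT": "very_low",
}


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, resolved before any stage starts."""

    out_dir: str = "results/run"
    input_csv: str | None = None  # None -> use the synthetic generator
    seed: int = 0
    r: float = 0.5  # pre-post correlation assumption
    mcid: float = MCID
    chains: int = 4
    draws: int = 2000
    warmup: int = 1000
    grid_step: float = 50.0
    grid_max: float = 1500.0
    met_lookup: str | None = None  # None -> bundled table
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    certainty: dict = field(default_factory=lambda: dict(_DEFAULT_CERTAINTY))

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; missing keys take defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if cfg.input_csv is not None and not Path(cfg.input_csv).exists():
        raise FileNotFoundError(cfg.input_csv)
    return cfg
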