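"""Run configuration: defaults, YAML loading and seed derivation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, InputError

__all__ = ["RunConfig", "load_config", "derive_seeds"]


@dataclass
class RunConfig:
    """Everything an end-to-end run needs.

    The analytical defaults are the standard ones for this index:
    scaling constant k = 8, priority threshold 0.5, 70% training
    fraction, features-per-split tuning with step factor 2 and improve
    rate 0.05, and 100 accumulation-curve permutations.  All randomness
    flows from the single root ``seed``.
    """

    occurrences: str = ""
    registry: str = ""
    status: str = ""
    overrides: str | None = None
    outdir: str = "cpirank_out"
    delimiter: str | None = None

    k: float = 8.0
    threshold: float = 0.5
    seed: int = 0

    train_fraction: float = 0.7
    tune_step_factor: float = 2.0
    improve: float = 0.05
    rf_trees: int = 500
    gbt_rounds: int = 100
    n_accumulation_permutations: int = 100
    run_models: bool = True

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ConfigError(f"k must be positive, got {self.k}")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must lie strictly between 0 and 1")
        if self.rf_trees < 1 or self.gbt_rounds < 1:
            raise ConfigError("model sizes must be positive")
        if self.n_accumulation_permutations < 1:
            raise ConfigError("n_accumulation_permutations must be >= 1")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML config; keyword arguments override file values."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise InputError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw)


def derive_seeds(root_seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2**31) spawned from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]
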