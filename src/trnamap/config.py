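"""Pipeline configuration: defaults, flat key=value files, seed derivation.

Precedence is CLI flag > config file > built-in default.  All randomness
flows from the single ``seed``; each pipeline stage derives its own
sub-seed deterministically from the stage name, so reruns with the same
configuration are byte-identical and stages stay independent.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from .simulate import DEFAULT_ADAPTER


@dataclass
class PipelineConfig:
    # thresholds
    min_depth: int = 1000  # per-position sequencing-depth floor
    site_threshold: float = 0.01  # modified-site / substrate call
    loss_threshold: float = 0.05  # variant activity loss
    min_total: int = 100  # per-member exact-count floor
    # alignment scoring
    match: int = 1
    mismatch: int = -1
    gap: int = -2
    min_score_fraction: float = 0.6
    # simulator
    n_reads: int = 100_000
    error_rate: float = 0.001
    misincorporation_rate: float = 0.79
    stop_rate: float = 0.0
    adapter: str = DEFAULT_ADAPTER
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("site_threshold", "loss_threshold", "error_rate", "min_score_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.min_total < 1:
            raise ValueError("min_total must be >= 1")

    def derive_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed (stable across runs, < 2^31)."""
        return (self.seed * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31)

    def echo(self, path: str | Path) -> None:
        """Write a machine-readable config echo enabling exact replay."""
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}


def _coerce(name: str, raw: str) -> Any:
    kind = _FIELD_TYPES[name]
    if kind == "int":
        return int(raw)
    if kind == "float":
        return float(raw)
    return raw


def load_config(path: str | Path | None = None, **overrides: Any) -> PipelineConfig:
    """Build a config from an optional flat ``key = value`` file plus overrides.

    Lines starting with ``#`` and blank lines are ignored; unknown keys are
    a hard error (typos should not silently fall back to defaults).
    Overrides with value ``None`` are ignored, so CLI flags can pass
    through unset options.
    """
    values: dict[str, Any] = {}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in _FIELD_TYPES:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = _coerce(key, raw.strip())
    for key, value in overrides.items():
        if value is None:
            continue
        if key not in _FIELD_TYPES:
            raise ValueError(f"unknown config option {key!r}")
        values[key] = value
    return PipelineConfig(**values)
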