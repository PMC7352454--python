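"""Layered pipeline configuration: defaults < TOML file < explicit overrides.

Every analysis constant is a named, validated parameter; the defaults are the
values the analyses were designed around (fixed totals of 50,000/20,000 for
the inhibition/overexpression pools, a 50-read representation floor, IQR
multiplier 1, the 25th-percentile expression filter, IP/T ratio >= 2,
enrichment fold change >= 2, adjusted p < 0.001 and CRISPR fold change
< -5.0).
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any, Mapping

from .types import ValidationError


@dataclass
class PipelineConfig:
    """All tunable analysis parameters, with their standard defaults."""

    # screen stage
    target_total_mirzip: float = 50_000.0
    target_total_pcdh: float = 20_000.0
    min_reads: float = 50.0
    iqr_k: float = 1.0
    # RIP-chip stage
    percentile: float = 25.0
    min_ratio: float = 2.0
    min_fc: float = 2.0
    probe_collapse: str = "max"
    # prioritization stage
    p_max: float = 0.001
    fc_cutoff: float = -5.0

    def validate(self) -> "PipelineConfig":
        if self.target_total_mirzip <= 0 or self.target_total_pcdh <= 0:
            raise ValidationError("target totals must be positive")
        if self.min_reads < 0:
            raise ValidationError("min_reads must be >= 0")
        if self.iqr_k <= 0:
            raise ValidationError("iqr_k must be positive")
        if not 0 <= self.percentile < 100:
            raise ValidationError("percentile must be in [0, 100)")
        if self.min_ratio < 1:
            raise ValidationError("min_ratio must be >= 1")
        if self.min_fc < 1:
            raise ValidationError("min_fc must be >= 1")
        if self.probe_collapse not in ("max", "mean"):
            raise ValidationError("probe_collapse must be 'max' or 'mean'")
        if not 0 < self.p_max <= 1:
            raise ValidationError("p_max must be in (0, 1]")
        return self


def load_config(
    path: str | Path | None = None, overrides: Mapping[str, Any] | None = None
) -> PipelineConfig:
    """Build a config from defaults, an optional TOML file, then overrides.

    The TOML file may hold parameters at top level or under a ``[pipeline]``
    table.  Unknown keys are rejected.  Overrides with value ``None`` are
    ignored so CLI flags can pass through unset options.
    """
    values: dict[str, Any] = {}
    known = {f.name for f in fields(PipelineConfig)}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "pipeline" in data and isinstance(data["pipeline"], dict):
            data = data["pipeline"]
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        values.update(data)
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if key not in known:
            raise ValidationError(f"unknown config key: {key!r}")
        values[key] = val
    return PipelineConfig(**values).validate()


def config_dict(cfg: PipelineConfig) -> dict[str, Any]:
    return asdict(cfg)
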