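"""Run configuration: one schema holding every tunable default.

CLI flags override config-file values, which override the built-ins.
Unknown keys and out-of-range values are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml


@dataclass
class RunConfig:
    pseudocount: float = 1.0
    bp_min_distance: int = 14
    bp_typical_max: int = 50
    bp_hard_max: int = 350
    ppt_min_length: int = 10
    ppt_min_pyrimidine_fraction: float = 0.7
    ppt_search_span: int = 50
    ppt_gap_to_ag: int = 2
    boundary_gc_window: int = 25
    psi_inclusion_rule: str = "mean"
    major_minor_cutoff: float = 0.5
    include_end_variation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if not (0 < self.bp_min_distance < self.bp_typical_max <= self.bp_hard_max):
            raise ValueError("need 0 < bp_min_distance < bp_typical_max <= bp_hard_max")
        if not (0.0 <= self.ppt_min_pyrimidine_fraction <= 1.0):
            raise ValueError("ppt_min_pyrimidine_fraction must be in [0, 1]")
        if self.ppt_min_length < 1 or self.ppt_search_span < self.ppt_min_length:
            raise ValueError("invalid PPT length/search-span settings")
        if self.ppt_gap_to_ag < 0:
            raise ValueError("ppt_gap_to_ag must be >= 0")
        if self.boundary_gc_window < 1:
            raise ValueError("boundary_gc_window must be >= 1")
        if self.psi_inclusion_rule not in ("mean", "min", "sum"):
            raise ValueError("psi_inclusion_rule must be mean, min or sum")
        if not (0.0 < self.major_minor_cutoff < 1.0):
            raise ValueError("major_minor_cutoff must be in (0, 1)")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a key-value mapping")
        return cls.from_mapping(data)

    def override(self, **kwargs: Any) -> "RunConfig":
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return RunConfig.from_mapping({**dataclasses.asdict(self), **updates})

    def dump_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
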