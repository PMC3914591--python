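"""Run configuration: one config fully determines one run.

Configs are loaded from YAML or JSON mappings and validated fail-fast:
unknown keys raise immediately, listing the offenders, so a typo in a config
file cannot silently fall back to a default.  The resolved config is echoed
into every output artifact (feature CSVs, CV reports) for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import features as feat

__all__ = ["RunConfig", "load_config_mapping"]


@dataclass
class RunConfig:
    """Parameters of one feature-extraction / cross-validation run."""

    window_length: int = 512
    window_lengths: Optional[list] = None   # grid for `cv`; falls back to [window_length]
    scheme: str = feat.PCPEM
    n_components: int = feat.DEFAULT_N_COMPONENTS
    n_pcs: int = feat.DEFAULT_N_PCS
    truncation: Optional[int] = None        # None -> floor(l/2)
    k: int = 10
    seed: int = 0
    standardize: Optional[bool] = None      # None -> scheme default
    data_dir: Optional[str] = None
    label_map: dict = field(default_factory=dict)  # raw label -> group label
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.scheme not in (feat.FFPC, feat.PCPEM):
            raise ValueError(
                f"scheme must be {feat.FFPC!r} or {feat.PCPEM!r}, "
                f"got {self.scheme!r}"
            )
        if self.window_lengths is None:
            self.window_lengths = [self.window_length]
        self.window_lengths = [int(l) for l in self.window_lengths]

    @classmethod
    def field_names(cls) -> set:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        unknown = sorted(set(mapping) - cls.field_names())
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**mapping)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config_mapping(path: Union[str, Path]) -> dict:
    """Load a YAML or JSON config file into a plain mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(data).__name__}")
    return data
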