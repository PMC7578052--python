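"""Pipeline configuration: documented defaults, YAML loading, hashing.

Every knob of the four stages lives here with its default; unknown keys in
a YAML file are rejected so that typos cannot silently fall back to
defaults.  CLI flags override file values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .selection import DEFAULT_SUBSET_SIZES
from .association import DEFAULT_L1_RATIOS

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """All tunables of simulate -> extract -> select -> associate."""

    # texture stage
    n_levels: int = 9
    glcm_distance: int = 1
    lbp_P: int = 24
    lbp_R: float = 3.0
    first_order_on_raw: bool = False
    # split + selection stage
    test_size: float = 0.25          # fraction, or an int subject count
    rfe_sizes: list[int] = field(
        default_factory=lambda: list(DEFAULT_SUBSET_SIZES)
    )
    cv_folds: int = 10
    cv_repeats: int = 10
    n_trees: int = 500
    one_se: bool = True
    # association stage
    enet_l1_ratios: list[float] = field(
        default_factory=lambda: list(DEFAULT_L1_RATIOS)
    )
    enet_n_alphas: int = 50
    enet_cv_folds: int = 10
    # synthetic cohort overrides (keys of cohort.CohortSpec)
    cohort: dict = field(default_factory=dict)
    # global
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    Unknown keys (file or overrides) raise ``ValueError``.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**data)
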