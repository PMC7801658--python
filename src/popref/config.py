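"""Run configuration: every threshold with a documented default.

Defaults follow the construction protocol the toolkit implements:
SVs are indels >= 51 bp; majority share is ⌊N/2⌋+1 (2 of 3); SV merge
distance 1000 bp inclusive on both breakpoints, type-aware; pseudo-
molecule gaps 10,000 N; genetic maps weigh 5 and RH maps 1 in anchoring;
depth accessibility is [5, mean + 2SD] per chromosome; representativeness
thresholds are AF = 1.0, >= 0.99 and >= 0.90.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    sv_min_len: int = 51
    min_share: int | None = None  # None -> ⌊N/2⌋+1
    merge_max_dist: int = 1000
    merge_type_aware: bool = True
    gap_size: int = 10_000
    map_weights: dict = field(default_factory=lambda: {"genetic": 5, "RH": 1})
    epcr_max_mismatch: int = 1
    epcr_three_prime_exact: int = 3
    epcr_size_tolerance: float = 0.5
    depth_min: float = 5.0
    depth_sd_mult: float = 2.0
    af_thresholds: tuple = (1.0, 0.99, 0.90)
    lift_min_overlap_variants: float = 1.0
    lift_min_overlap_features: float = 0.95
    lift_policy: str = "strict"
    include_backbone_candidate: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise KeyError(f"unknown config key {k!r}")
            setattr(cfg, k, v)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["af_thresholds"] = list(self.af_thresholds)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
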