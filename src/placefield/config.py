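"""Session configuration: every analysis constant with its default.

Conventions used throughout the package: time in seconds, positions in
cm, angles in radians, bins 0-based, time intervals half-open
[start, end).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field


@dataclass
class SessionConfig:
    # track geometry
    outer_diameter: float = 50.0
    width: float = 5.0
    n_bins: int = 20
    fps: float = 20.0
    # event detection
    sensor: str = "gcamp6s"
    gof_min: float = 0.8
    # place fields
    sigma_bins: float = 1.25
    map_threshold: float = 0.5
    score_sigma: float = 1.0
    score_threshold: float = 0.5
    min_relevant_run: int = 3
    debounce_s: float = 1.0
    # manifold
    w: int = 8
    k: int | None = None  # None: choose smallest passing candidate
    m: int = 2
    min_events: int = 5
    rv_window_s: float = 250.0
    rv_stride_s: float = 25.0
    # randomness
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SessionConfig":
        data = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
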