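"""Run configuration: one dataclass holding every user-tunable parameter,
with JSON round-tripping.  Defaults are the advised settings: a 100 x 100
histogram, 10 + 3 cubic B-splines per direction, third-order difference
penalty with lambda = 10, EM seed split at contrast -0.2 / 0.2, and no
NoCall threshold."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from .exceptions import ConfigError


@dataclass
class RunConfig:
    # histogram
    nx: int = 100
    ny: int = 100
    pad_fraction: float = 0.01
    x_limits: tuple | None = None
    y_limits: tuple | None = None
    # basis & penalty
    nseg: int = 10
    degree: int = 3
    penalty_order: int = 3
    lam: float = 10.0
    lam_c: float | None = None
    # EM seed split and stopping rules
    split_lo: float = -0.2
    split_hi: float = 0.2
    em_tol: float = 1e-4
    em_maxit: int = 50
    irls_tol: float = 1e-8
    irls_maxit: int = 50
    # calling
    nocall_threshold: float | None = None
    clip_floor: float = 1.0
    # simulation only
    seed: int = 0

    def __post_init__(self):
        if not self.split_lo < self.split_hi:
            raise ConfigError("split_lo must be < split_hi")
        if self.clip_floor <= 0:
            raise ConfigError("clip_floor must be > 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("x_limits", "y_limits"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)
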