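"""Run configuration: thresholds, windows, transform parameters, seeds.

A :class:`RunConfig` is a plain dataclass round-trippable through YAML, and
hashable (sha256 over its canonical JSON form) for provenance records.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .constants import NIOSH_THRESHOLD_C, WBGT_QUADRATIC

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    The exceedance threshold defaults to the 28 degC NIOSH limit
    (alternates 26 and 30 used for sensitivity); the exposure window is a
    5-year analogue of 2016-2020 and the trend window the full 39-year
    analogue of 1982-2020.
    """

    threshold_c: float = NIOSH_THRESHOLD_C
    strict_exceedance: bool = True
    exposure_window: tuple[int, int] = (2016, 2020)
    trend_window: tuple[int, int] = (1982, 2020)
    quad_a: float = WBGT_QUADRATIC["a"]
    quad_b: float = WBGT_QUADRATIC["b"]
    quad_c: float = WBGT_QUADRATIC["c"]
    valid_hi_range: tuple[float, float] = tuple(WBGT_QUADRATIC["valid_hi_range_f"])
    tmax_var: str = "tmax"
    vpdmax_var: str = "vpdmax"
    increasing_rule: str = "slope"  # or "significant"
    alpha: float = 0.05
    min_days_headline: float = 75.0
    seed: int = 0
    # synthetic-scenario knobs (used only when the run simulates its inputs)
    n_lat: int = 12
    n_lon: int = 12
    n_states: int = 3
    n_facilities: int = 60
    group_by: tuple[str, ...] = ("state", "facility_type")

    def __post_init__(self):
        if self.threshold_c <= 0:
            raise ValueError("threshold must be positive")
        for name in ("exposure_window", "trend_window"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be (first, last) with first <= last")

    def wbgt_params(self):
        from .wbgt import WbgtTransformParams

        return WbgtTransformParams(
            quad_a=self.quad_a,
            quad_b=self.quad_b,
            quad_c=self.quad_c,
            valid_hi_range=tuple(self.valid_hi_range),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("exposure_window", "trend_window", "valid_hi_range", "group_by"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("exposure_window", "trend_window", "valid_hi_range", "group_by"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()
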