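"""Analysis configuration: season windows, thresholds, and treatment constants.

All thresholds used by the phenometric detectors and the model-selection
layer live here so a run is fully described by one config object (plus the
input tables and the random seed).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from datetime import date
from hashlib import sha256
import json
from typing import IO

import yaml


@dataclass(frozen=True)
class SeasonWindow:
    """Half-open calendar interval [start, end)."""

    start: date
    end: date

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty window {self.start}..{self.end}")

    def contains(self, d) -> bool:
        d = _as_date(d)
        return self.start <= d < self.end

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days


def _as_date(d) -> date:
    if isinstance(d, date):
        return d
    return date.fromisoformat(str(d)[:10])


def annual_window(start_year: int) -> SeasonWindow:
    """The Jul-15 -> Jul-15 annual window used for climate summaries."""
    return SeasonWindow(date(start_year, 7, 15), date(start_year + 1, 7, 15))


def winter_window(start_year: int) -> SeasonWindow:
    """Dec-1 through Feb-28 inclusive, encoded half-open as [Dec-1, Mar-1)."""
    return SeasonWindow(date(start_year, 12, 1), date(start_year + 1, 3, 1))


def spring_window(year: int) -> SeasonWindow:
    """Mar-1 through May-31 inclusive, encoded half-open as [Mar-1, Jun-1)."""
    return SeasonWindow(date(year, 3, 1), date(year, 6, 1))


@dataclass(frozen=True)
class AnalysisConfig:
    # wilting point and phenometric thresholds
    wilting_point_kPa: float = -1500.0
    senescence_fraction: float = 0.80
    greenup_fraction: float = 1.25
    greenup_min_floor: float = 0.05      # below this the x1.25 rule is replaced ...
    greenup_offset: float = 0.05         # ... by min + offset (flagged)
    senescence_window_points: int = 3    # 2 allowed where senescence is very rapid
    # statistics
    collapse_alpha: float = 0.10
    delta_aicc_equiv: float = 2.0
    # treatment constants
    warming_delta_C: float = 2.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.wilting_point_kPa >= 0:
            raise ValueError("wilting_point_kPa must be < 0")
        for name in ("senescence_fraction", "greenup_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 2:
                raise ValueError(f"{name} must lie in (0, 2], got {v}")
        if self.senescence_window_points not in (2, 3):
            raise ValueError("senescence_window_points must be 2 or 3")

    def digest(self) -> str:
        """Stable hash of the configuration, for output provenance."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, stream: IO | str) -> "AnalysisConfig":
        raw = yaml.safe_load(stream) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)
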