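"""Shared domain containers for the sporulation-modelling pipeline.

Units throughout: temperature in °C, relative humidity (RH) in percent,
exposure durations and threshold-exceedance hours in hours, conidia as
integer counts per cadaver.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConidiaRecord",
    "TimedConidiaRecord",
    "WeatherSeries",
    "WeeklyTrial",
    "SurfaceParams",
    "Thresholds",
    "records_to_frame",
]


@dataclass(frozen=True)
class ConidiaRecord:
    """One cadaver's conidia counts under a temperature × RH condition."""

    unit_id: str
    temperature: float
    rh: float
    primary_count: int
    capilli_count: int

    def __post_init__(self) -> None:
        if self.primary_count < 0 or self.capilli_count < 0:
            raise ValueError(
                f"record {self.unit_id!r}: counts must be non-negative "
                f"(got primary={self.primary_count}, capilli={self.capilli_count})"
            )

    @property
    def total_count(self) -> int:
        return self.primary_count + self.capilli_count


@dataclass(frozen=True)
class TimedConidiaRecord(ConidiaRecord):
    """A conidia record with an exposure duration (time-course assay)."""

    duration_h: float = 0.0


@dataclass(frozen=True)
class WeatherSeries:
    """Ordered hourly (timestamp, temperature, RH) records for one window.

    Timestamps are naive local time at strict 1 h spacing; RH in [0, 100].
    """

    window_id: str
    timestamps: pd.DatetimeIndex
    temperature: np.ndarray
    rh: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        if len(self.temperature) != n or len(self.rh) != n:
            raise ValueError(f"window {self.window_id!r}: column lengths differ")
        rh = np.asarray(self.rh, dtype=float)
        if rh.size and (rh.min() < 0 or rh.max() > 100):
            raise ValueError(f"window {self.window_id!r}: RH outside [0, 100]")

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "temperature_c": np.asarray(self.temperature, float),
                "rh_pct": np.asarray(self.rh, float),
            }
        )


@dataclass(frozen=True)
class WeeklyTrial:
    """One semi-field week: duration covariates and the binomial outcome."""

    week_id: str
    h_rh: float
    h_temp: float
    n_cadavers: int
    n_sporulated: int

    def __post_init__(self) -> None:
        if not (0 <= self.h_rh <= 24 and 0 <= self.h_temp <= 24):
            raise ValueError(f"week {self.week_id!r}: duration covariates outside [0, 24]")
        if self.n_cadavers < 1:
            raise ValueError(f"week {self.week_id!r}: n_cadavers must be positive")
        if not 0 <= self.n_sporulated <= self.n_cadavers:
            raise ValueError(
                f"week {self.week_id!r}: n_sporulated={self.n_sporulated} "
                f"outside [0, {self.n_cadavers}]"
            )


@dataclass(frozen=True)
class SurfaceParams:
    """Logit-scale coefficients of the sporulation response surface.

    logit p = beta0 + beta_rh·h_rh + beta_temp·h_temp + beta_int·h_rh·h_temp,
    with h_rh = hours above the RH threshold and h_temp = hours above the
    temperature threshold within a 24 h window.
    """

    beta0: float
    beta_rh: float
    beta_temp: float
    beta_int: float

    def __post_init__(self) -> None:
        vals = (self.beta0, self.beta_rh, self.beta_temp, self.beta_int)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"surface coefficients must be finite, got {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta_rh, self.beta_temp, self.beta_int])


@dataclass(frozen=True)
class Thresholds:
    """Exceedance thresholds for the duration covariates (strict '>')."""

    rh_threshold: float = 90.0
    temp_threshold: float = 21.0
    window: int = 24

    def __post_init__(self) -> None:
        if not (np.isfinite(self.rh_threshold) and np.isfinite(self.temp_threshold)):
            raise ValueError("thresholds must be finite")
        if self.window < 1:
            raise ValueError("window must be a positive number of hours")


def records_to_frame(records: list) -> pd.DataFrame:
    """Tabulate conidia records (timed or not) into a tidy DataFrame."""
    rows = []
    for r in records:
        rows.append(
            {
                "unit_id": r.unit_id,
                "temperature_c": r.temperature,
                "rh_pct": r.rh,
                "duration_h": getattr(r, "duration_h", np.nan),
                "primary_conidia": r.primary_count,
                "capilliconidia": r.capilli_count,
            }
        )
    return pd.DataFrame(rows)
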