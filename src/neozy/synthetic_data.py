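"""Synthetic-data generators for every stage of the sporulation pipeline.

The laboratory and semi-field datasets behind the fitted models are not
publicly deposited, so the pipeline is exercised on simulated data with the
same statistical structure:

* a temperature × RH factorial of overdispersed conidia counts, with no
  sporulation at 80/85% RH and counts rising with temperature and RH;
* a time-course assay whose cumulative log-mean is a broken stick with a
  breakpoint near 10 h of exposure and a flat post-break segment;
* weekly semi-field trials where hourly weather drives a logistic response
  surface in (hours RH>90%, hours T>21 °C), calibrated so that 6 h of high
  humidity with 10 h of warmth — or 15 h with 6 h — give 90% sporulation
  probability.

Overdispersion is generated as gamma-Poisson mixing (negative binomial with
shape ``k``: variance μ + μ²/k), which is mean-correct for the
quasi-likelihood fits downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .sporulation_dss import extract_durations, predict_probability
from .types import (
    ConidiaRecord,
    SurfaceParams,
    Thresholds,
    TimedConidiaRecord,
    WeatherSeries,
    WeeklyTrial,
)

__all__ = [
    "DEFAULT_ANCHORS",
    "FactorialGenConfig",
    "TimeCourseGenConfig",
    "SemiFieldGenConfig",
    "calibrate_surface",
    "default_surface",
    "simulate_factorial",
    "simulate_timecourse",
    "simulate_semifield",
]

#: (h_rh, h_temp, probability) anchors pinning the default response surface:
#: the two printed 0.9-contour points plus near-zero and near-one corners.
DEFAULT_ANCHORS: tuple[tuple[float, float, float], ...] = (
    (6.0, 10.0, 0.90),
    (15.0, 6.0, 0.90),
    (0.0, 0.0, 0.01),
    (24.0, 24.0, 0.999),
)

TEMP_CENTER_C = 19.0  # centering used by the factorial log-linear means


def calibrate_surface(
    anchors: Sequence[tuple[float, float, float]] = DEFAULT_ANCHORS,
) -> SurfaceParams:
    """Solve the 4-parameter logistic surface through four anchor points.

    Each anchor ``(h_rh, h_temp, p)`` contributes one linear equation in
    logit space; the unique interpolating coefficients are returned.
    """
    if len(anchors) != 4:
        raise ValueError(f"exactly 4 anchors required, got {len(anchors)}")
    probs = np.array([a[2] for a in anchors], float)
    if np.any(probs <= 0) or np.any(probs >= 1):
        raise ValueError("anchor probabilities must lie strictly in (0, 1)")
    A = np.array([[1.0, hr, ht, hr * ht] for hr, ht, _ in anchors])
    if np.linalg.matrix_rank(A) < 4:
        raise ValueError(
            "anchor design is singular (collinear anchors): "
            + "; ".join(f"({hr}, {ht})" for hr, ht, _ in anchors)
        )
    beta = np.linalg.solve(A, logit(probs))
    return SurfaceParams(*map(float, beta))


def default_surface() -> SurfaceParams:
    """The calibrated default surface through :data:`DEFAULT_ANCHORS`."""
    return calibrate_surface(DEFAULT_ANCHORS)


def _gamma_poisson(rng: np.random.Generator, mu: float, k: float) -> int:
    """Overdispersed count: Poisson(Z·mu) with Z ~ Gamma(k, mean 1)."""
    z = rng.gamma(shape=k, scale=1.0 / k)
    return int(rng.poisson(z * mu))


def _slope_map(d, levels) -> dict[float, float]:
    if isinstance(d, Mapping):
        return {float(l): float(d[l]) for l in levels}
    return {float(l): float(d) for l in levels}


@dataclass(frozen=True)
class FactorialGenConfig:
    """Generator settings for the temperature × RH factorial assay.

    Counts at RH levels in ``zero_rh`` are identically zero (no sporulation
    below ~87.5% RH); elsewhere the per-cadaver total is gamma-Poisson with
    log mean ``a_rh[rh] + b_rh[rh]·(T − 19)`` and the capilliconidia share
    of the total is binomial with logit ``c_rh[rh] + d[rh]·(T − 19)``.
    Defaults reproduce the qualitative factorial pattern: counts and the
    capilliconidia proportion rise with temperature, are higher at ≥95% RH
    than at 90%, and the proportion at 90% RH is flat in temperature.
    """

    rh_levels: tuple[float, ...] = (80.0, 85.0, 90.0, 95.0, 100.0)
    temperatures: tuple[float, ...] = (13.0, 17.0, 21.0, 25.0)
    zero_rh: frozenset = frozenset({80.0, 85.0})
    a_rh: Mapping[float, float] = field(
        default_factory=lambda: {90.0: 3.2, 95.0: 4.0, 100.0: 4.2}
    )
    b_rh: Mapping[float, float] = field(
        default_factory=lambda: {90.0: 0.10, 95.0: 0.12, 100.0: 0.12}
    )
    c_rh: Mapping[float, float] = field(
        default_factory=lambda: {90.0: -1.4, 95.0: -0.4, 100.0: -0.3}
    )
    d: float | Mapping[float, float] = field(
        default_factory=lambda: {90.0: 0.0, 95.0: 0.15, 100.0: 0.15}
    )
    k: float = 2.0
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"gamma-frailty shape k must be positive, got {self.k}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def simulate_factorial(config: FactorialGenConfig) -> list[ConidiaRecord]:
    """Simulate per-cadaver conidia counts for the full factorial design."""
    rng = np.random.default_rng(config.seed)
    sporulating = [r for r in config.rh_levels if r not in config.zero_rh]
    d = _slope_map(config.d, sporulating)
    records: list[ConidiaRecord] = []
    for rh in config.rh_levels:
        for temp in config.temperatures:
            for rep in range(config.replicates):
                uid = f"F-rh{rh:g}-t{temp:g}-{rep + 1:02d}"
                if rh in config.zero_rh:
                    records.append(ConidiaRecord(uid, temp, rh, 0, 0))
                    continue
                mu = np.exp(config.a_rh[rh] + config.b_rh[rh] * (temp - TEMP_CENTER_C))
                total = _gamma_poisson(rng, mu, config.k)
                p_cap = expit(config.c_rh[rh] + d[rh] * (temp - TEMP_CENTER_C))
                capilli = int(rng.binomial(total, p_cap)) if total > 0 else 0
                records.append(ConidiaRecord(uid, temp, rh, total - capilli, capilli))
    return records


@dataclass(frozen=True)
class TimeCourseGenConfig:
    """Generator settings for the exposure-duration (time-course) assay.

    Cumulative counts follow a broken-stick log mean
    ``a + offsets + b1·min(t, psi) + b2·max(0, t − psi)`` with a breakpoint
    ``psi_true`` (default 10 h, the midpoint of the observed 8–12 h
    discharge window) and a flat post-break segment (``b2 = 0``: discharge
    plateaus after the breakpoint).  The default baseline keeps the 4 h mean
    below 0.5 conidia (no discharge in the first hours) while the plateau
    reaches a few hundred conidia per unit.  Capilliconidia formation is
    near-absent at 13 °C.

    Each record is one experimental unit pooling four cadavers, so the
    default frailty shape is k = 8: the sum of four independent per-cadaver
    Gamma(2) frailties (the factorial assay's cadaver-level default).
    """

    a: float = -7.0
    b1: float = 1.3
    b2: float = 0.0
    psi_true: float = 10.0
    times: tuple[float, ...] = (4.0, 8.0, 12.0, 24.0, 36.0)
    rh_levels: tuple[float, ...] = (90.0, 95.0, 100.0)
    temperatures: tuple[float, ...] = (13.0, 25.0)
    rh_offset: Mapping[float, float] = field(
        default_factory=lambda: {90.0: 0.0, 95.0: 0.4, 100.0: 0.5}
    )
    temp_offset: Mapping[float, float] = field(
        default_factory=lambda: {13.0: -1.0, 25.0: 0.0}
    )
    cap_logit: Mapping[float, float] = field(
        default_factory=lambda: {13.0: -4.0, 25.0: -0.5}
    )
    k: float = 8.0
    replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"gamma-frailty shape k must be positive, got {self.k}")
        if not min(self.times) < self.psi_true < max(self.times):
            raise ValueError(
                f"psi_true={self.psi_true} must lie strictly inside the "
                f"sampling-time range [{min(self.times)}, {max(self.times)}]"
            )

    def mean_at(self, t: float, rh: float, temp: float) -> float:
        """Theoretical cumulative mean count at time t for one cell."""
        eta = (
            self.a
            + self.rh_offset[rh]
            + self.temp_offset[temp]
            + self.b1 * min(t, self.psi_true)
            + self.b2 * max(0.0, t - self.psi_true)
        )
        return float(np.exp(eta))


def simulate_timecourse(config: TimeCourseGenConfig) -> list[TimedConidiaRecord]:
    """Simulate cumulative conidia counts over exposure durations."""
    rng = np.random.default_rng(config.seed)
    records: list[TimedConidiaRecord] = []
    for rh in config.rh_levels:
        for temp in config.temperatures:
            for t in config.times:
                mu = config.mean_at(t, rh, temp)
                p_cap = expit(config.cap_logit[temp])
                for rep in range(config.replicates):
                    uid = f"T-rh{rh:g}-t{temp:g}-h{t:g}-{rep + 1:02d}"
                    total = _gamma_poisson(rng, mu, config.k)
                    capilli = int(rng.binomial(total, p_cap)) if total > 0 else 0
                    records.append(
                        TimedConidiaRecord(
                            uid, temp, rh, total - capilli, capilli, duration_h=t
                        )
                    )
    return records


@dataclass(frozen=True)
class SemiFieldGenConfig:
    """Generator settings for the weekly semi-field screen-house trials.

    Each week gets a 24 h hourly weather window: a diel sinusoid (afternoon
    temperature peak, opposite-phase RH) plus a week-level shift and hourly
    Gaussian noise.  Week-level shifts are laid out on an evenly spaced grid
    over ±shift range (temperature in order, RH independently permuted), so
    the realized (h_rh, h_temp) covariates sweep the full [0, 24]² square
    the way a year of seasons would.  Sporulation per cadaver is Bernoulli
    with probability given by ``surface`` at the week's covariates.
    """

    n_weeks: int = 28
    n_cadavers: int = 10
    temp_mean: float = 21.0
    temp_amplitude: float = 5.0
    temp_shift_range: float = 7.0
    rh_mean: float = 90.0
    rh_amplitude: float = 7.0
    rh_shift_range: float = 8.0
    noise_sd: float = 1.0
    thresholds: Thresholds = Thresholds()
    surface: SurfaceParams | None = None
    start: str = "2010-08-02 00:00"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_weeks < 5:
            raise ValueError("n_weeks must be >= 5")
        if self.n_cadavers < 1:
            raise ValueError("n_cadavers must be >= 1")


def simulate_semifield(
    config: SemiFieldGenConfig,
) -> tuple[list[WeatherSeries], list[WeeklyTrial]]:
    """Simulate weekly weather windows and binomial sporulation outcomes."""
    rng = np.random.default_rng(config.seed)
    surface = config.surface if config.surface is not None else default_surface()
    hours = np.arange(24)
    diel = np.sin(2 * np.pi * (hours - 9) / 24.0)  # peak mid-afternoon
    temp_shifts = np.linspace(-config.temp_shift_range, config.temp_shift_range,
                              config.n_weeks)
    rh_shifts = rng.permutation(
        np.linspace(-config.rh_shift_range, config.rh_shift_range, config.n_weeks)
    )
    start = pd.Timestamp(config.start)

    weather: list[WeatherSeries] = []
    trials: list[WeeklyTrial] = []
    for w in range(config.n_weeks):
        ts = pd.date_range(start + pd.Timedelta(days=7 * w), periods=24, freq="h")
        temp = (
            config.temp_mean
            + config.temp_amplitude * diel
            + temp_shifts[w]
            + rng.normal(0.0, config.noise_sd, 24)
        )
        rh = np.clip(
            config.rh_mean
            - config.rh_amplitude * diel
            + rh_shifts[w]
            + rng.normal(0.0, config.noise_sd, 24),
            0.0,
            100.0,
        )
        series = WeatherSeries(f"W{w + 1:02d}", ts, temp, rh)
        h_rh, h_temp = extract_durations(series, config.thresholds)
        p = predict_probability(surface, h_rh, h_temp)
        n_spor = int(rng.binomial(config.n_cadavers, p))
        weather.append(series)
        trials.append(WeeklyTrial(f"W{w + 1:02d}", h_rh, h_temp,
                                  config.n_cadavers, n_spor))
    return weather, trials
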