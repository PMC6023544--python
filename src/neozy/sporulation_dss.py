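"""Semi-field response surface and decision-support layer.

From hourly weather logs, counts the hours per 24 h window spent above an RH
threshold (default 90%) and a temperature threshold (default 21 °C), fits a
quasi-binomial response surface (intercept, h_rh, h_temp, interaction) to
weekly sporulation proportions, extracts iso-probability contours, and turns
fitted surfaces into per-window sporulation advice.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .quasi_glm import BINOMIAL, DesignMatrix, FTestResult, GLMFit, f_test, fit
from .types import SurfaceParams, Thresholds, WeatherSeries, WeeklyTrial

__all__ = [
    "SporulationCategory",
    "SurfaceFit",
    "ContourSolution",
    "WindowAdvice",
    "categorize",
    "extract_durations",
    "fit_surface",
    "surface_params_from_fit",
    "predict_probability",
    "iso_contour",
    "sporulation_advice",
]

SporulationCategory = Literal["zero", "low", "high"]

#: conidia count above which a cadaver is scored 'high'
HIGH_COUNT = 500

SURFACE_TERMS = ("intercept", "h_rh", "h_temp", "h_rh:h_temp")


def categorize(total_count: int) -> SporulationCategory:
    """Score a cadaver's total conidia count on the zero/low/high scale.

    0 → 'zero'; 1–500 → 'low'; >500 → 'high'.  The binary sporulation
    indicator used by the surface model is ``category != 'zero'``.
    """
    if total_count != int(total_count) or total_count < 0:
        raise ValueError(f"total_count must be a non-negative integer, got {total_count}")
    n = int(total_count)
    if n == 0:
        return "zero"
    if n <= HIGH_COUNT:
        return "low"
    return "high"


def extract_durations(
    weather: WeatherSeries, thresholds: Thresholds = Thresholds()
) -> tuple[int, int]:
    """Hours within the window spent strictly above each threshold.

    Returns ``(h_rh, h_temp)``; both are integer hour counts in
    ``[0, thresholds.window]``.  The series must cover exactly one window of
    contiguous hourly records.
    """
    ts = pd.DatetimeIndex(weather.timestamps)
    if len(ts) != thresholds.window:
        raise ValueError(
            f"window {weather.window_id!r}: expected {thresholds.window} hourly "
            f"records, got {len(ts)}"
        )
    diffs = np.diff(ts.asi8) / 3.6e12  # hours
    bad = np.nonzero(diffs != 1.0)[0]
    if bad.size:
        offending = [str(ts[i + 1]) for i in bad]
        kind = "duplicate" if np.any(diffs[bad] == 0) else "gap or irregular spacing"
        raise ValueError(
            f"window {weather.window_id!r}: {kind} at timestamps {offending}"
        )
    h_rh = int(np.sum(np.asarray(weather.rh, float) > thresholds.rh_threshold))
    h_temp = int(np.sum(np.asarray(weather.temperature, float) > thresholds.temp_threshold))
    return h_rh, h_temp


def _surface_design(h_rh: np.ndarray, h_temp: np.ndarray, trials: np.ndarray) -> DesignMatrix:
    X = np.column_stack([np.ones_like(h_rh), h_rh, h_temp, h_rh * h_temp])
    return DesignMatrix(X=X, names=SURFACE_TERMS, trials=trials)


@dataclass
class SurfaceFit:
    """Fitted response surface plus its sequential analysis-of-deviance."""

    glm: GLMFit
    anova: list[FTestResult]

    @property
    def params(self) -> SurfaceParams:
        return surface_params_from_fit(self)

    def anova_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.as_row() for t in self.anova])


def fit_surface(trials: Sequence[WeeklyTrial]) -> SurfaceFit:
    """Quasi-binomial response surface over (h_rh, h_temp) with interaction.

    The sequential ladder adds h_temp, then h_rh, then the interaction, each
    F-test referencing the larger model of its pair, mirroring the
    2-/3-/4-parameter model sequence on the weekly proportions.
    """
    trials = list(trials)
    if len(trials) < 6:
        raise ValueError(f"need at least 6 weekly trials, got {len(trials)}")
    h_rh = np.array([t.h_rh for t in trials], float)
    h_temp = np.array([t.h_temp for t in trials], float)
    if np.ptp(h_rh) == 0 or np.ptp(h_temp) == 0:
        raise ValueError("no variation in h_rh and/or h_temp; surface not identifiable")
    y = np.array([t.n_sporulated for t in trials], float)
    n = np.array([t.n_cadavers for t in trials], float)
    ones = np.ones_like(h_rh)

    designs = {
        "1": DesignMatrix(ones[:, None], ("intercept",), trials=n),
        "t": DesignMatrix(np.column_stack([ones, h_temp]), ("intercept", "h_temp"), trials=n),
        "t+r": DesignMatrix(
            np.column_stack([ones, h_temp, h_rh]), ("intercept", "h_temp", "h_rh"), trials=n
        ),
        "full": _surface_design(h_rh, h_temp, n),
    }
    fits = {k: fit(y, d, BINOMIAL) for k, d in designs.items()}
    anova = [
        f_test(fits["1"], fits["t"], label="h_temp"),
        f_test(fits["t"], fits["t+r"], label="h_rh"),
        f_test(fits["t+r"], fits["full"], label="h_rh:h_temp"),
    ]
    return SurfaceFit(glm=fits["full"], anova=anova)


def surface_params_from_fit(sf: SurfaceFit) -> SurfaceParams:
    c = sf.glm.coef_table()
    return SurfaceParams(
        beta0=c["intercept"],
        beta_rh=c["h_rh"],
        beta_temp=c["h_temp"],
        beta_int=c["h_rh:h_temp"],
    )


def predict_probability(params: SurfaceParams, h_rh: float, h_temp: float) -> float:
    """Sporulation probability at (h_rh, h_temp) hours of threshold exceedance."""
    eta = (
        params.beta0
        + params.beta_rh * h_rh
        + params.beta_temp * h_temp
        + params.beta_int * h_rh * h_temp
    )
    return float(expit(eta))


@dataclass(frozen=True)
class ContourSolution:
    """Solution of an iso-probability contour query along one axis.

    ``value`` is the in-range solution (hours) when ``feasible``; ``root``
    always carries the unconstrained solution of the linear equation (NaN
    when the surface is flat or decreasing in the free variable).
    """

    p: float
    free_axis: str
    fixed_axis: str
    fixed_value: float
    feasible: bool
    value: float | None
    root: float
    reason: str = ""


def iso_contour(
    params: SurfaceParams,
    p: float,
    fixed_axis: Literal["h_rh", "h_temp"],
    fixed_value: float,
) -> ContourSolution:
    """Solve logit(p) = η for the free duration axis at a fixed other axis.

    The linear predictor is linear in the free variable, with effective slope
    beta_free + beta_int·fixed_value; a non-positive slope yields an
    infeasible result (reason 'non-increasing surface'), and an out-of-range
    root an infeasible result carrying the root.
    """
    if not 0 < p < 1:
        raise ValueError(f"contour probability must be in (0, 1), got {p}")
    if fixed_axis == "h_temp":
        free_axis, slope = "h_rh", params.beta_rh + params.beta_int * fixed_value
        const = params.beta0 + params.beta_temp * fixed_value
    elif fixed_axis == "h_rh":
        free_axis, slope = "h_temp", params.beta_temp + params.beta_int * fixed_value
        const = params.beta0 + params.beta_rh * fixed_value
    else:
        raise ValueError(f"fixed_axis must be 'h_rh' or 'h_temp', got {fixed_axis!r}")

    if slope <= 0:
        return ContourSolution(
            p=p, free_axis=free_axis, fixed_axis=fixed_axis, fixed_value=fixed_value,
            feasible=False, value=None, root=float("nan"),
            reason="non-increasing surface",
        )
    root = (float(logit(p)) - const) / slope
    if 0 <= root <= 24:
        return ContourSolution(
            p=p, free_axis=free_axis, fixed_axis=fixed_axis, fixed_value=fixed_value,
            feasible=True, value=float(root), root=float(root),
        )
    return ContourSolution(
        p=p, free_axis=free_axis, fixed_axis=fixed_axis, fixed_value=fixed_value,
        feasible=False, value=None, root=float(root),
        reason="solution outside [0, 24] h",
    )


@dataclass(frozen=True)
class WindowAdvice:
    """DSS verdict for one 24 h weather window."""

    window_id: str
    h_rh: int
    h_temp: int
    probability: float
    favorable: bool


def sporulation_advice(
    weather_windows: Iterable[WeatherSeries],
    params: SurfaceParams,
    p_star: float = 0.9,
    thresholds: Thresholds = Thresholds(),
) -> list[WindowAdvice]:
    """Per-window sporulation probability and a flag probability >= p_star."""
    out = []
    for w in weather_windows:
        h_rh, h_temp = extract_durations(w, thresholds)
        prob = predict_probability(params, h_rh, h_temp)
        out.append(
            WindowAdvice(
                window_id=w.window_id,
                h_rh=h_rh,
                h_temp=h_temp,
                probability=prob,
                favorable=prob >= p_star,
            )
        )
    return out
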