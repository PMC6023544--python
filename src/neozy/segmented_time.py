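"""Stage 2: segmented quasi-Poisson regression of conidia discharge over time.

The cumulative conidia count over exposure duration t follows a broken-stick
log mean with common segment slopes on s1(t) = min(t, ψ) and
s2(t) = max(0, t − ψ) plus a free intercept per RH × temperature cell (the
"maximal" linear predictor: 6 cell intercepts + 2 slopes).  The breakpoint ψ
is estimated by maximizing the profile log-likelihood of the pure Poisson
model (dispersion fixed at 1) over a candidate grid; the quasi-Poisson fit
and its analysis-of-deviance are then computed at the selected ψ̂.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quasi_glm import (
    POISSON,
    ConvergenceError,
    DesignMatrix,
    FTestResult,
    GLMFit,
    f_test,
    fit,
)
from .types import TimedConidiaRecord

__all__ = [
    "SegmentedSpec",
    "ProfileTrace",
    "SegmentedFit",
    "profile_breakpoint",
    "fit_segmented",
    "discharge_window",
]


@dataclass(frozen=True)
class SegmentedSpec:
    """Candidate-breakpoint grid for the profile-likelihood search."""

    grid_min: float = 4.5
    grid_max: float = 35.5
    grid_step: float = 0.1

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.grid_max <= self.grid_min:
            raise ValueError("grid_max must exceed grid_min")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step))
        return self.grid_min + self.grid_step * np.arange(n + 1)


@dataclass
class ProfileTrace:
    """Profile log-likelihood ℓ(ψ) over the candidate grid.

    Candidates whose Poisson fit failed carry NaN and are excluded from the
    argmax; ties break toward the smallest ψ.
    """

    psi: np.ndarray
    loglik: np.ndarray

    @property
    def argmax_index(self) -> int:
        finite = np.where(np.isfinite(self.loglik), self.loglik, -np.inf)
        return int(np.argmax(finite))  # first max → smallest psi on ties

    @property
    def psi_hat(self) -> float:
        return float(self.psi[self.argmax_index])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"psi": self.psi, "loglik": self.loglik})


@dataclass
class SegmentedFit:
    """Quasi-Poisson segmented fit at the selected breakpoint."""

    psi_hat: float
    glm: GLMFit
    anova: list[FTestResult]
    design_times: np.ndarray

    def anova_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.as_row() for t in self.anova])


def _segment_basis(t: np.ndarray, psi: float) -> tuple[np.ndarray, np.ndarray]:
    return np.minimum(t, psi), np.maximum(0.0, t - psi)


def _cells(records) -> tuple[np.ndarray, list[tuple[float, float]]]:
    keys = np.array([(r.rh, r.temperature) for r in records])
    labels = sorted({(r.rh, r.temperature) for r in records})
    return keys, labels


def _maximal_design(records, psi: float) -> DesignMatrix:
    """Cell intercepts (one per RH × temperature) plus common s1/s2 slopes."""
    t = np.array([r.duration_h for r in records], float)
    s1, s2 = _segment_basis(t, psi)
    keys, labels = _cells(records)
    cols = [np.all(keys == np.array(lab), axis=1).astype(float) for lab in labels]
    names = [f"cell_rh{lab[0]:g}_t{lab[1]:g}" for lab in labels]
    cols += [s1, s2]
    names += ["s1_pre_break", "s2_post_break"]
    return DesignMatrix(np.column_stack(cols), tuple(names))


def _response(records, response: str = "total") -> np.ndarray:
    if response == "total":
        return np.array([r.total_count for r in records], float)
    if response == "primary":
        return np.array([r.primary_count for r in records], float)
    if response == "capilli":
        return np.array([r.capilli_count for r in records], float)
    raise ValueError(f"unknown response {response!r}")


def profile_breakpoint(
    records: list[TimedConidiaRecord],
    spec: SegmentedSpec = SegmentedSpec(),
    response: str = "total",
) -> ProfileTrace:
    """Profile the Poisson log-likelihood over candidate breakpoints.

    For each grid value ψ the maximal-linear-predictor Poisson model is
    refitted (dispersion fixed at 1) and its log-likelihood recorded; the
    maximizing ψ (smallest on ties) estimates the breakpoint.
    """
    times = sorted({r.duration_h for r in records})
    if len(times) < 3:
        raise ValueError(f"need >= 3 distinct exposure times, got {times}")
    grid = spec.grid()
    if grid[0] <= min(times) - 1e-9 or grid[-1] >= max(times) + 1e-9:
        # profiling outside the data range is allowed to touch, not exceed it
        if grid[0] < min(times) or grid[-1] > max(times):
            raise ValueError(
                f"grid [{grid[0]}, {grid[-1]}] extends beyond the observed "
                f"time range [{min(times)}, {max(times)}]"
            )
    y = _response(records, response)
    ll = np.full(grid.shape, np.nan)
    n_failed = 0
    for i, psi in enumerate(grid):
        try:
            ll[i] = fit(y, _maximal_design(records, float(psi)), POISSON).loglik
        except (ConvergenceError, ValueError):
            n_failed += 1
    if n_failed == len(grid):
        raise RuntimeError("profile failed: no candidate breakpoint fit converged")
    if n_failed:
        warnings.warn(
            f"{n_failed} of {len(grid)} candidate breakpoints failed to fit "
            "and were excluded from the profile",
            RuntimeWarning,
        )
    return ProfileTrace(psi=grid, loglik=ll)


def _additive_design(records, psi: float) -> DesignMatrix:
    """Main-effects-only intercept structure (no RH × temperature interaction)."""
    t = np.array([r.duration_h for r in records], float)
    s1, s2 = _segment_basis(t, psi)
    rh = np.array([r.rh for r in records], float)
    temp = np.array([r.temperature for r in records], float)
    rh_levels = sorted(set(rh))
    temp_levels = sorted(set(temp))
    cols = [np.ones(len(records))]
    names = ["intercept"]
    for lv in rh_levels[1:]:
        cols.append((rh == lv).astype(float))
        names.append(f"rh{lv:g}")
    for lv in temp_levels[1:]:
        cols.append((temp == lv).astype(float))
        names.append(f"temp{lv:g}")
    cols += [s1, s2]
    names += ["s1_pre_break", "s2_post_break"]
    return DesignMatrix(np.column_stack(cols), tuple(names))


def _collapsed_design(records, psi: float, collapse_temp: float = 25.0) -> DesignMatrix:
    """Maximal design with the two highest-RH cells merged at one temperature."""
    full = _maximal_design(records, psi)
    rh_levels = sorted({r.rh for r in records})
    top_two = rh_levels[-2:]
    merge = [f"cell_rh{lv:g}_t{collapse_temp:g}" for lv in top_two]
    if not all(m in full.names for m in merge):
        raise ValueError(f"cells {merge} not present in the design")
    idx = [full.names.index(m) for m in merge]
    keep = [j for j in range(full.n_terms) if j not in idx]
    merged_col = full.X[:, idx].sum(axis=1)
    merged_name = f"cell_rh{top_two[0]:g}+{top_two[1]:g}_t{collapse_temp:g}"
    X = np.column_stack([full.X[:, keep], merged_col])
    names = tuple(full.names[j] for j in keep) + (merged_name,)
    return DesignMatrix(X, names)


def fit_segmented(
    records: list[TimedConidiaRecord],
    psi: float,
    response: str = "total",
) -> SegmentedFit:
    """Quasi-Poisson segmented fit at a fixed breakpoint with F-tests.

    The analysis-of-deviance holds (i) the RH × temperature interaction test
    (additive intercepts vs free cell intercepts, 2 df, dispersion from the
    full model) and (ii) the 1-df collapse of the two highest-RH cells at
    25 °C, with dispersion taken from the collapsed model so the denominator
    df reflects that model's residual df.
    """
    times = [r.duration_h for r in records]
    if not min(times) <= psi <= max(times):
        raise ValueError(f"psi={psi} outside observed time range")
    y = _response(records, response)
    full = fit(y, _maximal_design(records, psi), POISSON)
    additive = fit(y, _additive_design(records, psi), POISSON)
    collapsed = fit(y, _collapsed_design(records, psi), POISSON)
    anova = [
        f_test(additive, full, label="RH x temperature interaction"),
        f_test(collapsed, full, label="collapse top-two RH cells at 25C",
               dispersion_from="reduced"),
    ]
    return SegmentedFit(
        psi_hat=float(psi),
        glm=full,
        anova=anova,
        design_times=np.array(sorted(set(times))),
    )


def discharge_window(segfit: SegmentedFit) -> tuple[float, float]:
    """Descriptive (onset, plateau) hours of the discharge curve.

    Onset is the largest design time before ψ̂ whose largest fitted mean is
    still below one conidium (the smallest design time when every mean is
    ≥ 1); the plateau is the breakpoint itself.
    """
    times = segfit.design_times
    rec_t = np.array(
        segfit.glm.design.X[:, -2] + segfit.glm.design.X[:, -1]
    )  # s1 + s2 = t
    onset = None
    for dt in sorted(times):
        if dt >= segfit.psi_hat:
            break
        max_mean = segfit.glm.fitted[np.isclose(rec_t, dt)].max()
        if max_mean < 1.0:
            onset = dt
    if onset is None:
        onset = float(min(times))
    return float(onset), float(segfit.psi_hat)
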