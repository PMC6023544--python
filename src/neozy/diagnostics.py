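"""Half-normal residual plots with simulation envelopes.

Goodness of fit for every GLM in the pipeline is assessed by ordering the
absolute deviance residuals against half-normal quantiles and surrounding
them with an envelope built by simulating from the fitted model (plain
Poisson/binomial at the fitted means — not inflated by the dispersion
estimate — so overdispersion shows up as points escaping the envelope).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .quasi_glm import ConvergenceError, FamilySpec, GLMFit, fit

__all__ = [
    "EnvelopeResult",
    "halfnormal_envelope",
    "envelope_summary",
    "half_normal_positions",
]


@dataclass
class EnvelopeResult:
    """Ordered absolute residuals with simulated envelope bands."""

    observed: np.ndarray      # sorted |deviance residuals|, length n
    positions: np.ndarray     # half-normal plotting quantiles
    lower: np.ndarray
    median: np.ndarray
    upper: np.ndarray
    outside: np.ndarray       # indices (into the sorted vector) outside bands
    n_sim: int
    level: float

    @property
    def n_outside(self) -> int:
        return len(self.outside)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.observed)
        flags = np.zeros(n, dtype=bool)
        flags[self.outside] = True
        return pd.DataFrame(
            {
                "position": np.arange(1, n + 1),
                "quantile": self.positions,
                "observed": self.observed,
                "lower": self.lower,
                "median": self.median,
                "upper": self.upper,
                "outside": flags,
            }
        )


def half_normal_positions(n: int) -> np.ndarray:
    """Half-normal plotting quantiles Φ⁻¹((i + n − 1/8)/(2n + 1/2)), i=1..n."""
    i = np.arange(1, n + 1)
    return scipy.stats.norm.ppf((i + n - 0.125) / (2 * n + 0.5))


def _deviance_residuals(y, fitted, family: FamilySpec, trials) -> np.ndarray:
    if family.family == "poisson":
        mu = fitted
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        d2 = 2.0 * (term - (y - mu))
    else:
        n = trials
        mu = fitted * n  # expected successes
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            t2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n - mu)), 0.0)
        d2 = 2.0 * (t1 + t2)
    return np.sign(y - mu) * np.sqrt(np.maximum(d2, 0.0))


def _simulate_response(rng, family: FamilySpec, fitted, trials):
    if family.family == "poisson":
        return rng.poisson(fitted).astype(float)
    return rng.binomial(trials.astype(int), fitted).astype(float)


def halfnormal_envelope(
    glm_fit: GLMFit,
    n_sim: int = 99,
    level: float = 0.95,
    seed: int | None = None,
) -> EnvelopeResult:
    """Half-normal plot data with a simulated envelope for a fitted GLM.

    ``n_sim`` response vectors are drawn from the fitted means under the
    fit's family, each refitted to the same design; per-position empirical
    quantiles at (1−level)/2, 1/2 and (1+level)/2 of the sorted absolute
    deviance residuals form the bands.  Replicates whose refit fails are
    dropped (error if more than 20% fail).
    """
    if not glm_fit.converged:
        raise ValueError("cannot build an envelope around a non-converged fit")
    if n_sim < 19:
        raise ValueError("n_sim must be at least 19")

    family = glm_fit.family
    trials = glm_fit.design.trials
    if family.family == "binomial" and trials is None:
        trials = np.ones(glm_fit.n_obs)
    observed = np.sort(
        np.abs(_deviance_residuals(glm_fit.response, glm_fit.fitted, family, trials))
    )
    n = len(observed)

    rng = np.random.default_rng(seed)
    sims = []
    for _ in range(n_sim):
        y_star = _simulate_response(rng, family, glm_fit.fitted, trials)
        try:
            refit = fit(y_star, glm_fit.design, family)
        except (ConvergenceError, ValueError):
            continue
        sims.append(
            np.sort(np.abs(_deviance_residuals(y_star, refit.fitted, family, trials)))
        )
    if len(sims) < 0.8 * n_sim:
        raise RuntimeError(
            f"only {len(sims)} of {n_sim} envelope refits succeeded (> 20% failed)"
        )
    if len(sims) < n_sim:
        warnings.warn(
            f"{n_sim - len(sims)} envelope replicates dropped (refit failure)",
            RuntimeWarning,
        )

    sims = np.vstack(sims)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(sims, alpha, axis=0)
    median = np.quantile(sims, 0.5, axis=0)
    upper = np.quantile(sims, 1.0 - alpha, axis=0)
    outside = np.nonzero((observed < lower) | (observed > upper))[0]

    return EnvelopeResult(
        observed=observed,
        positions=half_normal_positions(n),
        lower=lower,
        median=median,
        upper=upper,
        outside=outside,
        n_sim=len(sims),
        level=level,
    )


def envelope_summary(result: EnvelopeResult) -> float:
    """Fraction of observed points falling outside the envelope."""
    return result.n_outside / len(result.observed)
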