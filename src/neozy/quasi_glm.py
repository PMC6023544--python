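"""Quasi-likelihood GLM engine: estimation, dispersion, prediction, F-tests.

Two family/link pairs are supported — Poisson counts with a log link and
binomial proportions with a logit link — estimated by IRLS (via statsmodels)
and turned into quasi-likelihood inference through the Pearson dispersion
estimate phi = X² / (n − p).  Every analysis stage of the pipeline fits its
models through :func:`fit` and compares nested models through :func:`f_test`.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.special
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "DesignMatrix",
    "FamilySpec",
    "GLMFit",
    "FTestResult",
    "fit",
    "f_test",
    "predict",
]

#: linear predictors beyond this magnitude at convergence flag quasi-separation
SEPARATION_ETA = 30.0
MAX_ITER = 100
DEVIANCE_RTOL = 1e-8


@dataclass(frozen=True)
class DesignMatrix:
    """Observation-by-term design with names, optional trials and offset."""

    X: np.ndarray
    names: tuple[str, ...]
    trials: np.ndarray | None = None
    offset: np.ndarray | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        if X.ndim != 2:
            raise ValueError("design matrix must be 2-dimensional")
        if len(self.names) != X.shape[1]:
            raise ValueError(
                f"{len(self.names)} term names for {X.shape[1]} columns"
            )
        for attr in ("trials", "offset"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                object.__setattr__(self, attr, v)
                if v.shape != (X.shape[0],):
                    raise ValueError(f"{attr} length does not match design rows")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_terms(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class FamilySpec:
    """Variance/link family: 'poisson' (log) or 'binomial' (logit)."""

    family: Literal["poisson", "binomial"]

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "binomial"):
            raise ValueError(f"unsupported family {self.family!r}")

    def to_statsmodels(self):
        if self.family == "poisson":
            return sm.families.Poisson()
        return sm.families.Binomial()


POISSON = FamilySpec("poisson")
BINOMIAL = FamilySpec("binomial")


@dataclass
class GLMFit:
    """A fitted quasi-likelihood GLM.

    ``loglik`` is the exponential-family log-likelihood at the estimate with
    dispersion fixed at 1 (the quantity profiled over breakpoints); standard
    errors and F-tests use the Pearson dispersion ``dispersion``.
    """

    names: tuple[str, ...]
    coef: np.ndarray
    cov: np.ndarray
    fitted: np.ndarray          # means (Poisson) or probabilities (binomial)
    linear_predictor: np.ndarray
    deviance: float
    df_resid: int
    pearson_x2: float
    dispersion: float
    loglik: float
    converged: bool
    n_iter: int
    family: FamilySpec
    design: DesignMatrix
    response: np.ndarray
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.design.n_obs

    @property
    def n_params(self) -> int:
        return self.design.n_terms

    def coef_table(self) -> dict[str, float]:
        return dict(zip(self.names, self.coef.tolist()))

    def std_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def to_json_dict(self) -> dict:
        return {
            "family": self.family.family,
            "terms": list(self.names),
            "coefficients": self.coef.tolist(),
            "covariance": self.cov.tolist(),
            "deviance": self.deviance,
            "df_resid": self.df_resid,
            "pearson_x2": self.pearson_x2,
            "dispersion": self.dispersion,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "warnings": self.warnings_,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_json_dict(), **kwargs)


@dataclass(frozen=True)
class FTestResult:
    """Analysis-of-deviance quasi-F test between two nested fits."""

    label: str
    f_stat: float
    df_num: int
    df_den: int
    p_value: float

    def __post_init__(self) -> None:
        if self.df_num < 1:
            raise ValueError("numerator df must be >= 1")

    def as_row(self) -> dict:
        return {
            "test": self.label,
            "F": self.f_stat,
            "df1": self.df_num,
            "df2": self.df_den,
            "p": self.p_value,
        }


class RankDeficientError(ValueError):
    """Raised when the design matrix has linearly dependent (aliased) terms."""


class ConvergenceError(RuntimeError):
    """Raised when IRLS fails to converge within the iteration budget."""


def _aliased_terms(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name the columns made redundant by earlier ones (QR with pivoting)."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[j] for j in sorted(piv[rank:])]


def _deviance(y, mu, family: FamilySpec, trials) -> float:
    if family.family == "poisson":
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(term - (y - mu)))
    m = trials * mu  # mu is a probability here
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / m), 0.0)
        t2 = np.where(trials - y > 0, (trials - y) * np.log((trials - y) / (trials - m)), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def _loglik(y, mu, family: FamilySpec, trials) -> float:
    if family.family == "poisson":
        return float(scipy.stats.poisson.logpmf(y, mu).sum())
    return float(scipy.stats.binom.logpmf(y, trials, mu).sum())


def _damped_irls(y, design: DesignMatrix, family: FamilySpec, trials):
    """Step-halving IRLS used when the statsmodels path diverges.

    Returns (beta, mu, deviance, n_iter) or raises ConvergenceError.  mu is
    the mean for Poisson and the probability for binomial.
    """
    X = design.X
    offset = design.offset if design.offset is not None else 0.0
    if family.family == "poisson":
        z0 = np.log(y + 0.5)
    else:
        z0 = scipy.special.logit((y + 0.5) / (trials + 1.0))
    beta, *_ = np.linalg.lstsq(X, z0 - offset, rcond=None)

    def mean_of(b):
        eta = np.clip(X @ b + offset, -700, 700)
        return np.exp(eta) if family.family == "poisson" else scipy.special.expit(eta)

    mu = mean_of(beta)
    dev = _deviance(y, mu, family, trials)
    for it in range(1, MAX_ITER + 1):
        if family.family == "poisson":
            w = mu
            resp = y - mu
        else:
            w = trials * mu * (1.0 - mu)
            resp = y - trials * mu
        w = np.maximum(w, 1e-300)
        eta = np.clip(X @ beta + offset, -700, 700)
        z = eta - offset + resp / w
        WX = X * w[:, None]
        try:
            step = np.linalg.solve(X.T @ WX, WX.T @ z) - beta
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"IRLS normal equations singular: {exc}") from exc
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            mu_c = mean_of(cand)
            dev_c = _deviance(y, mu_c, family, trials)
            if np.isfinite(dev_c) and dev_c <= dev + 1e-12:
                break
            lam *= 0.5
        else:
            raise ConvergenceError("IRLS step halving failed to reduce deviance")
        beta, mu, dev_old, dev = cand, mu_c, dev, dev_c
        if abs(dev_old - dev) <= DEVIANCE_RTOL * (abs(dev) + 0.1):
            return beta, mu, dev, it
    raise ConvergenceError(f"damped IRLS did not converge in {MAX_ITER} iterations")


def _validate_response(y: np.ndarray, design: DesignMatrix, family: FamilySpec) -> None:
    if len(y) != design.n_obs:
        raise ValueError(f"response length {len(y)} != design rows {design.n_obs}")
    if family.family == "poisson":
        if np.any(y < 0):
            raise ValueError("Poisson response must be non-negative")
    else:
        trials = design.trials
        if trials is None:
            trials = np.ones_like(y, dtype=float)
        if np.any(y < 0) or np.any(y > trials):
            raise ValueError("binomial response must satisfy 0 <= y <= trials")


def fit(y: Sequence[float], design: DesignMatrix, family: FamilySpec) -> GLMFit:
    """Fit a quasi-Poisson or quasi-binomial GLM by IRLS.

    Parameters
    ----------
    y
        Counts (Poisson) or success counts (binomial; per-row trial sizes
        taken from ``design.trials``, default 1).
    design
        Full-column-rank design matrix; aliased terms raise
        :class:`RankDeficientError` naming the offending columns.
    family
        ``POISSON`` or ``BINOMIAL``.

    Returns
    -------
    GLMFit with Pearson dispersion X²/(n−p) and covariance phi·(XᵀWX)⁻¹.
    """
    y = np.asarray(y, dtype=float)
    _validate_response(y, design, family)

    aliased = _aliased_terms(design.X, design.names)
    if aliased:
        raise RankDeficientError(
            "design matrix is rank deficient; aliased terms: " + ", ".join(aliased)
        )

    if family.family == "binomial":
        trials = design.trials if design.trials is not None else np.ones_like(y)
        endog = np.column_stack([y, trials - y])
    else:
        trials = None
        endog = y

    # IRLS start: mu0 = y + 0.5 (Poisson) or (y + 0.5)/(n + 1) (binomial),
    # projected onto the design on the link scale; keeps the first working
    # weights finite where the default start can overflow
    if family.family == "poisson":
        z0 = np.log(y + 0.5)
    else:
        z0 = scipy.special.logit((y + 0.5) / (trials + 1.0))
    if design.offset is not None:
        z0 = z0 - design.offset
    start, *_ = np.linalg.lstsq(design.X, z0, rcond=None)

    model = sm.GLM(
        endog, design.X, family=family.to_statsmodels(), offset=design.offset
    )
    res = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(
                start_params=start, maxiter=MAX_ITER, tol=DEVIANCE_RTOL, scale=1.0
            )
        except (ValueError, np.linalg.LinAlgError):
            res = None
    notes = [str(w.message) for w in caught]

    trials_vec = trials if trials is not None else np.ones_like(y)
    if res is not None and res.converged:
        coef = np.asarray(res.params)
        fitted = np.asarray(res.mu)  # probabilities for binomial, means for Poisson
        deviance = float(res.deviance)
        loglik = float(res.llf)
        n_iter = int(res.fit_history.get("iteration", 0))
    else:
        # statsmodels IRLS diverged or stalled; retry with damped step-halving
        coef, mu, deviance, n_iter = _damped_irls(y, design, family, trials_vec)
        fitted = mu
        loglik = _loglik(y, mu, family, trials_vec)
        notes.append("statsmodels IRLS diverged; damped step-halving IRLS used")

    eta = design.X @ coef + (design.offset if design.offset is not None else 0.0)
    if np.any(np.abs(eta) > SEPARATION_ETA):
        notes.append(
            "possible separation: |linear predictor| exceeds "
            f"{SEPARATION_ETA:g} at convergence"
        )

    n, p = design.n_obs, design.n_terms
    df_resid = n - p
    if family.family == "poisson":
        var = np.maximum(fitted, 1e-300)
        resid2 = (y - fitted) ** 2
        w = np.maximum(fitted, 1e-300)
    else:
        var = np.maximum(trials_vec * fitted * (1 - fitted), 1e-300)
        resid2 = (y - trials_vec * fitted) ** 2
        w = var
    pearson_x2 = float(np.sum(resid2 / var))
    if res is not None and res.converged:
        pearson_x2 = float(res.pearson_chi2)
        cov_unit = np.asarray(res.cov_params())
    else:
        WX = design.X * w[:, None]
        cov_unit = np.linalg.inv(design.X.T @ WX)
    dispersion = pearson_x2 / df_resid if df_resid > 0 else float("nan")

    return GLMFit(
        names=design.names,
        coef=coef,
        cov=dispersion * cov_unit if df_resid > 0 else cov_unit * np.nan,
        fitted=fitted,
        linear_predictor=np.asarray(eta),
        deviance=deviance,
        df_resid=df_resid,
        pearson_x2=pearson_x2,
        dispersion=float(dispersion),
        loglik=loglik,
        converged=True,
        n_iter=n_iter,
        family=family,
        design=design,
        response=y,
        warnings_=notes,
    )


def _is_nested(reduced: DesignMatrix, full: DesignMatrix, tol: float = 1e-8) -> bool:
    """True when every reduced column lies in the full column space."""
    beta, *_ = np.linalg.lstsq(full.X, reduced.X, rcond=None)
    resid = reduced.X - full.X @ beta
    scale = max(1.0, float(np.abs(reduced.X).max()))
    return bool(np.abs(resid).max() <= tol * scale)


def f_test(
    reduced: GLMFit,
    full: GLMFit,
    label: str = "",
    dispersion_from: Literal["full", "reduced"] = "full",
) -> FTestResult:
    """Analysis-of-deviance quasi-F test of a reduced against a full model.

    F = [(D_red − D_full)/(df_red − df_full)] / phi, with phi the Pearson
    dispersion of the model named by ``dispersion_from`` (the larger model by
    default) and denominator df equal to that model's residual df.
    """
    if reduced.n_obs != full.n_obs or not np.array_equal(
        reduced.response, full.response
    ):
        raise ValueError("fits compare different response data")
    if full.n_params <= reduced.n_params:
        raise ValueError("full model must have strictly more terms than reduced")
    if not _is_nested(reduced.design, full.design):
        raise ValueError("designs are not nested (reduced not in full column space)")

    ref = full if dispersion_from == "full" else reduced
    if not ref.dispersion > 1e-12:
        raise ValueError(
            "reference model is saturated (dispersion 0); F-test undefined"
        )

    df_num = reduced.df_resid - full.df_resid
    df_den = ref.df_resid
    f_stat = ((reduced.deviance - full.deviance) / df_num) / ref.dispersion
    f_stat = max(f_stat, 0.0)
    p = float(scipy.stats.f.sf(f_stat, df_num, df_den))
    return FTestResult(label=label, f_stat=float(f_stat), df_num=df_num,
                       df_den=df_den, p_value=p)


def predict(fit_: GLMFit, X_new: DesignMatrix) -> np.ndarray:
    """Inverse-link predictions (means or probabilities) on new rows."""
    if tuple(X_new.names) != tuple(fit_.names):
        missing = set(fit_.names) - set(X_new.names)
        extra = set(X_new.names) - set(fit_.names)
        raise ValueError(
            f"design terms do not match fit: missing={sorted(missing)}, "
            f"extra={sorted(extra)}"
        )
    eta = X_new.X @ fit_.coef
    if X_new.offset is not None:
        eta = eta + X_new.offset
    if fit_.family.family == "poisson":
        return np.exp(eta)
    return scipy.special.expit(eta)
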