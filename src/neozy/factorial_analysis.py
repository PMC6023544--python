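"""Stage 1: temperature × RH factorial analysis of conidia production.

Counts (total, primary, or capilliconidia per cadaver) are modelled with
quasi-Poisson GLMs having a separate intercept and centered-temperature
slope per RH group, and the capilliconidia share of the total with a
quasi-binomial GLM weighted by per-cadaver totals.  Nested RH groupings
({90},{95},{100} → {90},{95,100} → one common line → intercept only) supply
the analysis-of-deviance F-tests: a 2-df test of collapsing the two highest
humidities and a 1-df test of the common temperature slope.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .quasi_glm import (
    BINOMIAL,
    POISSON,
    DesignMatrix,
    FTestResult,
    GLMFit,
    f_test,
    fit,
)
from .synthetic_data import TEMP_CENTER_C
from .types import ConidiaRecord

__all__ = [
    "RhGrouping",
    "FactorialResult",
    "FULL_GROUPING",
    "COLLAPSED_GROUPING",
    "filter_sporulating_levels",
    "build_design",
    "analyze_counts",
    "analyze_proportion",
]

# an RhGrouping is a partition of the RH levels present, e.g.
# ((90,), (95, 100)): groups share an intercept and a temperature slope
RhGrouping = tuple[tuple[float, ...], ...]

FULL_GROUPING: RhGrouping = ((90.0,), (95.0,), (100.0,))
COLLAPSED_GROUPING: RhGrouping = ((90.0,), (95.0, 100.0))

CountResponse = Literal["total", "primary", "capilli"]


def filter_sporulating_levels(
    records: Sequence[ConidiaRecord],
) -> tuple[list[ConidiaRecord], set[float]]:
    """Drop RH levels with zero total conidia across all records.

    Returns the kept records and the set of dropped RH levels.  Raises when
    every level is all-zero (no sporulation anywhere).
    """
    if not records:
        raise ValueError("no records supplied")
    levels = sorted({r.rh for r in records})
    totals = {lv: 0 for lv in levels}
    for r in records:
        totals[r.rh] += r.total_count
    dropped = {lv for lv in levels if totals[lv] == 0}
    if dropped == set(levels):
        raise ValueError("no sporulation at any RH level; nothing to analyze")
    kept = [r for r in records if r.rh not in dropped]
    return kept, dropped


def _grouping_for(levels: Sequence[float], grouping: RhGrouping) -> RhGrouping:
    present = set(levels)
    covered = {lv for g in grouping for lv in g}
    if covered != present:
        raise ValueError(
            f"grouping {grouping} does not cover the RH levels present "
            f"{sorted(present)}"
        )
    groups = tuple(tuple(sorted(g)) for g in grouping)
    if sum(len(g) for g in groups) != len(covered):
        raise ValueError(f"grouping {grouping} has overlapping groups")
    return groups


def build_design(
    records: Sequence[ConidiaRecord],
    grouping: RhGrouping,
    temperature_centering: float = TEMP_CENTER_C,
) -> DesignMatrix:
    """Per-group intercept and centered-temperature-slope design.

    Column count is 2 × number of groups; full column rank is enforced at
    fit time.
    """
    levels = sorted({r.rh for r in records})
    groups = _grouping_for(levels, grouping)
    rh = np.array([r.rh for r in records], float)
    tc = np.array([r.temperature for r in records], float) - temperature_centering
    cols, names = [], []
    for g in groups:
        ind = np.isin(rh, g).astype(float)
        label = "+".join(f"{lv:g}" for lv in g)
        cols.extend([ind, ind * tc])
        names.extend([f"rh{label}", f"rh{label}:temp_c"])
    return DesignMatrix(np.column_stack(cols), tuple(names))


@dataclass
class FactorialResult:
    """Fits over the grouping ladder plus the analysis-of-deviance table."""

    response: str
    fits: dict[str, GLMFit]
    anova: list[FTestResult]
    n_included: int
    n_excluded: int = 0

    def anova_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.as_row() for t in self.anova])


def _response_vector(records: Sequence[ConidiaRecord], response: CountResponse) -> np.ndarray:
    if response == "total":
        return np.array([r.total_count for r in records], float)
    if response == "primary":
        return np.array([r.primary_count for r in records], float)
    if response == "capilli":
        return np.array([r.capilli_count for r in records], float)
    raise ValueError(f"unknown count response {response!r}")


def _common_line_designs(records: Sequence[ConidiaRecord], trials=None):
    n = len(records)
    tc = np.array([r.temperature for r in records], float) - TEMP_CENTER_C
    ones = np.ones(n)
    common = DesignMatrix(
        np.column_stack([ones, tc]), ("intercept", "temp_c"), trials=trials
    )
    intercept_only = DesignMatrix(ones[:, None], ("intercept",), trials=trials)
    return common, intercept_only


def _analyze(records, y, family, trials=None, response_name="total") -> FactorialResult:
    levels = sorted({r.rh for r in records})
    full_grouping = tuple((lv,) for lv in levels)
    collapsed = _collapse_top_two(levels)

    def dm(grouping):
        d = build_design(records, grouping)
        if trials is None:
            return d
        return DesignMatrix(d.X, d.names, trials=trials)

    fits = {
        "full": fit(y, dm(full_grouping), family),
        "collapsed": fit(y, dm(collapsed), family),
    }
    common, intercept_only = _common_line_designs(records, trials)
    fits["common_line"] = fit(y, common, family)
    fits["intercept_only"] = fit(y, intercept_only, family)

    anova = [
        f_test(fits["collapsed"], fits["full"],
               label="collapse top-two RH levels vs full"),
        f_test(fits["intercept_only"], fits["common_line"],
               label="common temperature slope"),
    ]
    return FactorialResult(
        response=response_name,
        fits=fits,
        anova=anova,
        n_included=len(records),
    )


def _collapse_top_two(levels: Sequence[float]) -> RhGrouping:
    if len(levels) < 2:
        raise ValueError("need at least two RH levels to form the collapsed grouping")
    top_two = tuple(sorted(levels)[-2:])
    rest = tuple((lv,) for lv in sorted(levels)[:-2])
    return rest + (top_two,)


def analyze_counts(
    records: Sequence[ConidiaRecord], response: CountResponse = "total"
) -> FactorialResult:
    """Quasi-Poisson factorial analysis of a conidia count response.

    Produces (a) the 2-df test collapsing the two highest RH levels against
    the full per-level model, and (b) the 1-df common-temperature-slope test
    against an intercept-only model; each test takes its dispersion from the
    larger model of the pair.
    """
    records = list(records)
    y = _response_vector(records, response)
    return _analyze(records, y, POISSON, response_name=response)


def analyze_proportion(records: Sequence[ConidiaRecord]) -> FactorialResult:
    """Quasi-binomial analysis of the capilliconidia proportion.

    The response is capilli_count out of the per-cadaver total; cadavers
    with zero total conidia have no defined proportion and are excluded
    (their number is reported on the result).
    """
    records = list(records)
    kept = [r for r in records if r.total_count > 0]
    n_excluded = len(records) - len(kept)
    if not kept:
        raise ValueError("all cadavers have zero total conidia; no proportions to model")
    y = np.array([r.capilli_count for r in kept], float)
    trials = np.array([r.total_count for r in kept], float)
    result = _analyze(kept, y, BINOMIAL, trials=trials, response_name="proportion")
    result.n_excluded = n_excluded
    return result
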