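"""File I/O, configuration, and the end-to-end pipeline driver.

Plain-text formats throughout: CSV tables with explicit headers for data,
JSON for fitted objects, YAML or JSON for configuration.  Timestamps are
ISO-8601, local-time naive.  ``run_pipeline`` chains
simulate → factorial fit → time-course fit → surface fit → contours →
diagnostics, writing every artifact plus a manifest (seeds, versions,
SHA-256 hashes) under the configured output directory; identical
configuration reproduces identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, factorial_analysis, segmented_time, sporulation_dss
from .segmented_time import SegmentedSpec
from .synthetic_data import (
    FactorialGenConfig,
    SemiFieldGenConfig,
    TimeCourseGenConfig,
    default_surface,
    simulate_factorial,
    simulate_semifield,
    simulate_timecourse,
)
from .types import (
    ConidiaRecord,
    Thresholds,
    TimedConidiaRecord,
    WeatherSeries,
    WeeklyTrial,
    records_to_frame,
)

__all__ = [
    "PipelineConfig",
    "read_counts",
    "write_counts",
    "read_weather",
    "write_weather",
    "read_trials",
    "write_trials",
    "run_pipeline",
]

log = logging.getLogger("neozy")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(_h)

COUNT_COLUMNS = [
    "unit_id",
    "temperature_c",
    "rh_pct",
    "duration_h",
    "primary_conidia",
    "capilliconidia",
]
WEATHER_COLUMNS = ["timestamp", "temperature_c", "rh_pct"]
TRIAL_COLUMNS = ["week_id", "h_rh", "h_temp", "n_cadavers", "n_sporulated"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_counts(path) -> list[ConidiaRecord | TimedConidiaRecord]:
    """Read a conidia-count table; timed records where duration_h is set.

    Malformed rows (negative or non-integer counts, RH outside [0, 100])
    are reported together with their 1-based data row numbers.
    """
    df = pd.read_csv(path)
    _require_columns(df, COUNT_COLUMNS, path)
    problems: list[str] = []
    records: list[ConidiaRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        errs = []
        for col in ("primary_conidia", "capilliconidia"):
            v = getattr(row, col)
            if pd.isna(v) or float(v) != int(v) or int(v) < 0:
                errs.append(f"{col}={v!r} not a non-negative integer")
        if not 0 <= float(row.rh_pct) <= 100:
            errs.append(f"rh_pct={row.rh_pct!r} outside [0, 100]")
        if errs:
            problems.append(f"row {i}: " + "; ".join(errs))
            continue
        common = dict(
            unit_id=str(row.unit_id),
            temperature=float(row.temperature_c),
            rh=float(row.rh_pct),
            primary_count=int(row.primary_conidia),
            capilli_count=int(row.capilliconidia),
        )
        if pd.isna(row.duration_h):
            records.append(ConidiaRecord(**common))
        else:
            records.append(TimedConidiaRecord(**common, duration_h=float(row.duration_h)))
    if problems:
        raise ValueError(f"{path}: malformed rows:\n" + "\n".join(problems))
    return records


def write_counts(records, path) -> None:
    df = records_to_frame(records)
    df.to_csv(path, index=False)


def read_weather(path, window: int = 24) -> list[WeatherSeries]:
    """Read an hourly weather log and split it into consecutive windows.

    The log must be contiguous at 1 h spacing with no duplicates, and its
    length a multiple of ``window``.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    _require_columns(df, WEATHER_COLUMNS, path)
    ts = pd.DatetimeIndex(df["timestamp"])
    diffs = np.diff(ts.asi8) / 3.6e12
    bad = np.nonzero(diffs != 1.0)[0]
    if bad.size:
        offending = ", ".join(str(ts[i + 1]) for i in bad[:10])
        raise ValueError(f"{path}: gaps or duplicate timestamps at {offending}")
    if len(df) % window:
        raise ValueError(
            f"{path}: {len(df)} rows is not a whole number of {window} h windows"
        )
    out = []
    for w in range(len(df) // window):
        part = df.iloc[w * window : (w + 1) * window]
        out.append(
            WeatherSeries(
                window_id=f"W{w + 1:02d}",
                timestamps=pd.DatetimeIndex(part["timestamp"]),
                temperature=part["temperature_c"].to_numpy(float),
                rh=part["rh_pct"].to_numpy(float),
            )
        )
    return out


def write_weather(windows, path) -> None:
    frames = [w.to_frame() for w in windows]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials(path) -> list[WeeklyTrial]:
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS, path)
    return [
        WeeklyTrial(
            week_id=str(r.week_id),
            h_rh=float(r.h_rh),
            h_temp=float(r.h_temp),
            n_cadavers=int(r.n_cadavers),
            n_sporulated=int(r.n_sporulated),
        )
        for r in df.itertuples(index=False)
    ]


def write_trials(trials, path) -> None:
    pd.DataFrame(
        [
            {
                "week_id": t.week_id,
                "h_rh": t.h_rh,
                "h_temp": t.h_temp,
                "n_cadavers": t.n_cadavers,
                "n_sporulated": t.n_sporulated,
            }
            for t in trials
        ]
    ).to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Everything one reproducible end-to-end run needs."""

    seed: int
    out_dir: str = "results"
    factorial: FactorialGenConfig | None = None
    timecourse: TimeCourseGenConfig | None = None
    semifield: SemiFieldGenConfig | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    grid: SegmentedSpec = field(default_factory=SegmentedSpec)
    p_star: float = 0.9
    n_sim_envelope: int = 99

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required for a reproducible run")
        seed = int(self.seed)
        if self.factorial is None:
            self.factorial = FactorialGenConfig(seed=seed)
        if self.timecourse is None:
            self.timecourse = TimeCourseGenConfig(seed=seed + 1)
        if self.semifield is None:
            self.semifield = SemiFieldGenConfig(seed=seed + 2)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if "seed" not in raw:
            raise ValueError(f"{path}: config must set a seed")
        kwargs = dict(raw)
        for key, klass in (
            ("factorial", FactorialGenConfig),
            ("timecourse", TimeCourseGenConfig),
            ("semifield", SemiFieldGenConfig),
            ("thresholds", Thresholds),
            ("grid", SegmentedSpec),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate, fit all three stages, extract contours, and diagnose.

    Returns the manifest dict; all artifacts land under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage simulate: generating factorial, time-course, semi-field data")
    fact_records = simulate_factorial(config.factorial)
    time_records = simulate_timecourse(config.timecourse)
    weather, trials = simulate_semifield(config.semifield)
    write_counts(fact_records, out / "factorial_counts.csv")
    write_counts(time_records, out / "timecourse_counts.csv")
    write_weather(weather, out / "weather.csv")
    write_trials(trials, out / "trials.csv")

    log.info("stage factorial: quasi-Poisson counts and quasi-binomial proportion")
    kept, dropped = factorial_analysis.filter_sporulating_levels(fact_records)
    count_res = factorial_analysis.analyze_counts(kept, "total")
    prop_res = factorial_analysis.analyze_proportion(kept)
    fact_json = {
        "dropped_rh_levels": sorted(dropped),
        "counts": {
            "anova": [t.as_row() for t in count_res.anova],
            "full_fit": count_res.fits["full"].to_json_dict(),
        },
        "proportion": {
            "anova": [t.as_row() for t in prop_res.anova],
            "n_excluded_zero_total": prop_res.n_excluded,
            "full_fit": prop_res.fits["full"].to_json_dict(),
        },
    }
    _json_dump(fact_json, out / "factorial_fit.json")
    pd.DataFrame(
        [t.as_row() for t in count_res.anova + prop_res.anova]
    ).to_csv(out / "factorial_ftests.csv", index=False)

    log.info("stage timecourse: profile-likelihood breakpoint search")
    trace = segmented_time.profile_breakpoint(time_records, config.grid)
    segfit = segmented_time.fit_segmented(time_records, trace.psi_hat)
    onset, plateau = segmented_time.discharge_window(segfit)
    trace.to_frame().to_csv(out / "profile_trace.csv", index=False)
    _json_dump(
        {
            "psi_hat": trace.psi_hat,
            "onset_h": onset,
            "plateau_h": plateau,
            "anova": [t.as_row() for t in segfit.anova],
            "fit": segfit.glm.to_json_dict(),
        },
        out / "segmented_fit.json",
    )

    log.info("stage surface: quasi-binomial response surface and contours")
    sfit = sporulation_dss.fit_surface(trials)
    params = sfit.params
    contour_rows = []
    for p in (0.1, 0.25, 0.5, 0.75, 0.9):
        for fixed_axis, fixed_value in (("h_temp", 10.0), ("h_temp", 6.0),
                                        ("h_rh", 6.0), ("h_rh", 15.0)):
            sol = sporulation_dss.iso_contour(params, p, fixed_axis, fixed_value)
            contour_rows.append(
                {
                    "p": p,
                    "fixed_axis": fixed_axis,
                    "fixed_value": fixed_value,
                    "solution": sol.value,
                    "feasible": sol.feasible,
                    "unconstrained_root": sol.root,
                    "reason": sol.reason,
                }
            )
    pd.DataFrame(contour_rows).to_csv(out / "contours.csv", index=False)
    _json_dump(
        {
            "anova": [t.as_row() for t in sfit.anova],
            "fit": sfit.glm.to_json_dict(),
            "surface": dataclasses.asdict(params),
        },
        out / "surface_fit.json",
    )
    advice = sporulation_dss.sporulation_advice(
        weather, params, config.p_star, config.thresholds
    )
    pd.DataFrame([dataclasses.asdict(a) for a in advice]).to_csv(
        out / "advice.csv", index=False
    )

    log.info("stage diagnose: half-normal envelope of the surface fit")
    env = diagnostics.halfnormal_envelope(
        sfit.glm, n_sim=config.n_sim_envelope, seed=config.seed + 10
    )
    env.to_frame().to_csv(out / "surface_envelope.csv", index=False)

    inputs = [
        "factorial_counts.csv",
        "timecourse_counts.csv",
        "weather.csv",
        "trials.csv",
    ]
    import neozy

    manifest = {
        "package_version": getattr(neozy, "__version__", "unknown"),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "inputs": {name: _sha256(out / name) for name in inputs},
        "psi_hat": trace.psi_hat,
        "envelope_fraction_outside": diagnostics.envelope_summary(env),
    }
    _json_dump(manifest, out / "manifest.json")
    log.info("pipeline complete; artifacts in %s", out)
    return manifest
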