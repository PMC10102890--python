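"""Curve assembly across t, the time-until-prognosis-level report, and the
file-based run entry points behind the command-line interface.

The crossing report answers "how long until the desired prognosis delta is
achieved?": for each level it reads off the first time the estimated curve
reaches the level, and, as a pessimistic companion, the first time the
lower 95% confidence curve reaches it (on a rising curve the lower band
crosses later, so this plays the role of an upper percentile of the
crossing time).  Rendering conventions: an empty cell means the level is
achieved at t = 0, "est (pess)" gives the two crossing times, and an
em-dash means the level is never achieved within follow-up.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import read_cohort
from .params import (
    PrognosisCurve,
    cause_specific_curves,
    conditional_survival,
    crmtl,
    rmrl,
    write_curve,
)
from .population import contrast, ederer1, population_curves, read_ratetable

__all__ = [
    "LevelCrossing",
    "CrossingReport",
    "time_to_level",
    "render_report",
    "write_report",
    "RunConfig",
    "run_estimate",
    "run_contrast",
]

ACHIEVED_AT_ZERO = "achieved_at_zero"
ACHIEVED = "achieved"
NEVER = "never_achieved"

NEVER_MARK = "—"  # em-dash

PARAM_BUILDERS = {
    "cs": "conditional survival",
    "rmrl": "restricted mean residual lifetime",
    "crmtl": "restricted mean time lost",
    "risk": "cause-specific risk",
    "ratio": "cause-specific risk ratio",
    "difference": "cause-specific risk difference",
    "proportion": "proportion of deaths from cancer",
}


@dataclass(frozen=True)
class LevelCrossing:
    level: float
    status: str
    time_estimate: float | None
    time_pessimistic: float | None

    def cell(self) -> str:
        """Render as a report-table cell: "" (achieved at 0), an em-dash
        (never), or "est (pessimistic)"."""
        if self.status == ACHIEVED_AT_ZERO:
            return ""
        if self.status == NEVER:
            return NEVER_MARK
        pess = NEVER_MARK if self.time_pessimistic is None else f"{self.time_pessimistic:.1f}"
        return f"{self.time_estimate:.1f} ({pess})"


@dataclass
class CrossingReport:
    label: str
    delta: float
    levels: list

    def cells(self) -> list:
        return [lc.cell() for lc in self.levels]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": [lc.level for lc in self.levels],
                "status": [lc.status for lc in self.levels],
                "t_estimate": [np.nan if lc.time_estimate is None else lc.time_estimate for lc in self.levels],
                "t_pessimistic": [
                    np.nan if lc.time_pessimistic is None else lc.time_pessimistic for lc in self.levels
                ],
                "cell": self.cells(),
            }
        )


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """First time y reaches `level`, linearly interpolating between grid
    points; None if the curve never reaches it."""
    if t.size == 0:
        return None
    if y[0] >= level:
        return float(t[0])
    hit = np.flatnonzero(y >= level)
    if hit.size == 0:
        return None
    i = int(hit[0])
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    return float(t[i - 1] + (level - y0) * (t[i] - t[i - 1]) / (y1 - y0))


def time_to_level(curve: PrognosisCurve, levels) -> CrossingReport:
    """Crossing-time report for a prognosis curve.

    For each level: the first grid time at which the point estimate
    reaches the level (linear interpolation between adjacent grid points)
    and, analogously, for the lower confidence curve.  A level already met
    at the first defined time point reports ``achieved_at_zero``; a level
    never met within follow-up reports ``never_achieved``.  Undefined
    curve segments are skipped with a warning; a non-monotone estimate
    triggers a monotonicity warning (the report assumes the true curve is
    monotonically improving) but the first crossing is still reported.
    """
    levels = [float(l) for l in np.atleast_1d(levels)]
    if any(not (0 < l) for l in levels):
        raise ValueError("levels must be positive")
    ok = curve.defined & np.isfinite(curve.estimate)
    if not np.all(curve.defined):
        warnings.warn(
            f"{int((~curve.defined).sum())} undefined curve point(s) skipped in crossing report",
            stacklevel=2,
        )
    t = curve.t_grid[ok]
    est = curve.estimate[ok]
    lower = curve.ci_lower[ok]
    if est.size > 1 and np.any(np.diff(est) < -1e-12):
        warnings.warn("estimated curve is not monotone; reporting first crossings", stacklevel=2)
    out = []
    for level in levels:
        t_est = _first_crossing(t, est, level)
        t_pess = _first_crossing(t, lower, level)
        if t_est is None:
            out.append(LevelCrossing(level, NEVER, None, None))
        elif est.size and est[0] >= level and (t.size == 0 or t[0] <= 1e-12):
            out.append(LevelCrossing(level, ACHIEVED_AT_ZERO, 0.0, t_pess))
        else:
            out.append(LevelCrossing(level, ACHIEVED, t_est, t_pess))
    return CrossingReport(label=curve.label, delta=curve.delta, levels=out)


def write_report(report: CrossingReport, path, delimiter: str = "\t") -> None:
    df = report.to_frame()
    df.insert(0, "label", report.label)
    df.insert(1, "delta", report.delta)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def render_report(report: CrossingReport) -> str:
    """Human-readable one-row table mirroring the report conventions."""
    header = "\t".join(f"delta={lc.level:g}" for lc in report.levels)
    return f"{report.label}\t{header}\n{report.label}\t" + "\t".join(report.cells())


# ---------------------------------------------------------------------------
# file-based runs


@dataclass(frozen=True)
class RunConfig:
    """Configuration for the file-based entry points.

    ``delta`` defaults to the conventional 5-year horizon.  ``t_step``
    evaluates curves on a regular t grid (right-continuous step
    interpolation of the solved path, so evaluation between jumps is
    exact); None uses the event-time grid.
    """

    delta: float = 5.0
    horizon: float | None = None
    params: tuple = ("cs", "rmrl")
    mesh_step: float = 0.01
    t_step: float | None = None
    ci_scale: str = "plain"
    levels: tuple = (0.6, 0.7, 0.8, 0.9, 0.95, 1.0)
    out_dir: str = "."
    delimiter: str = "\t"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_log(out_dir: Path, config: RunConfig, cohort, curves: dict) -> Path:
    log = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in config.to_dict().items()},
        "n": int(cohort.n),
        "events": {
            "censored": int((cohort.event == 0).sum()),
            "cancer": int((cohort.event == 1).sum()),
            "other": int((cohort.event == 2).sum()),
        },
        "undefined": {name: int(c.undefined_mask.sum()) for name, c in curves.items()},
    }
    path = out_dir / "run_log.json"
    path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return path


def _cohort_curves(cohort, config: RunConfig, params) -> dict:
    kwargs = dict(
        delta=config.delta,
        horizon=config.horizon,
        t_step=config.t_step,
        ci_scale=config.ci_scale,
    )
    curves = {}
    for name in params:
        if name == "cs":
            curves[name] = conditional_survival(cohort, **kwargs)
        elif name == "rmrl":
            curves[name] = rmrl(cohort, mesh_step=config.mesh_step, **kwargs)
        elif name == "crmtl":
            base = curves.get("rmrl") or rmrl(cohort, mesh_step=config.mesh_step, **kwargs)
            curves[name] = crmtl(base)
        elif name in ("risk", "ratio", "difference", "proportion"):
            curves[name] = cause_specific_curves(cohort, which=name, **kwargs)
        else:
            raise ValueError(f"unknown parameter {name!r}; choose from {sorted(PARAM_BUILDERS)}")
    return curves


def run_estimate(cohort_file, config: RunConfig) -> list:
    """Estimate the requested cohort prognosis parameters and write one
    curve file per parameter plus a run log; returns the written paths."""
    if not config.params:
        raise ValueError("no parameters requested; nothing to estimate")
    cohort = read_cohort(cohort_file, delimiter=config.delimiter)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    curves = _cohort_curves(cohort, config, config.params)
    written = []
    for name, curve in curves.items():
        path = out_dir / f"param_{name}.tsv"
        write_curve(curve, path, delimiter=config.delimiter)
        written.append(path)
    written.append(_write_log(out_dir, config, cohort, curves))
    return written


def run_contrast(cohort_file, ratetable_file, config: RunConfig) -> list:
    """Cohort-vs-population contrasts (conditional survival and RMRL, on
    both scales) plus the crossing-time report on the conditional-survival
    ratio; writes curve files, the report, and a run log."""
    cohort = read_cohort(cohort_file, delimiter=config.delimiter)
    table = read_ratetable(ratetable_file, delimiter=config.delimiter)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort_curves = _cohort_curves(cohort, config, ("cs", "rmrl"))
    t_grid = cohort_curves["cs"].t_grid
    rm_grid = cohort_curves["rmrl"].t_grid
    pop_grid = np.unique(
        np.concatenate([t_grid, t_grid + config.delta, rm_grid, rm_grid + config.delta])
    )
    pop_grid = pop_grid[pop_grid >= 0]
    exp_surv = ederer1(cohort, table, pop_grid)
    cs_g, _ = population_curves(exp_surv, config.delta, t_grid=t_grid)
    _, rmrl_g = population_curves(exp_surv, config.delta, t_grid=rm_grid)

    curves = {
        "cs_ratio": contrast(cohort_curves["cs"], cs_g, "ratio"),
        "cs_difference": contrast(cohort_curves["cs"], cs_g, "difference"),
        "rmrl_ratio": contrast(cohort_curves["rmrl"], rmrl_g, "ratio"),
        "rmrl_difference": contrast(cohort_curves["rmrl"], rmrl_g, "difference"),
    }
    written = []
    for name, curve in curves.items():
        path = out_dir / f"contrast_{name}.tsv"
        write_curve(curve, path, delimiter=config.delimiter)
        written.append(path)
    report = time_to_level(curves["cs_ratio"], config.levels)
    report_path = out_dir / "crossing_report.tsv"
    write_report(report, report_path, delimiter=config.delimiter)
    written.append(report_path)
    written.append(_write_log(out_dir, config, cohort, curves))
    return written
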