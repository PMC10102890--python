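"""Expected (general-population) survival and cohort-vs-population contrasts.

The expected survival of a cancer cohort's demographic twin in the general
population is computed with the Ederer I estimator: each subject is
matched, by age at diagnosis, sex, and calendar year of diagnosis, to a
fictitious population individual whose all-cause mortality follows a
demographic rate table (yearly hazards by attained age x calendar year x
sex), and the matched survival curves are averaged,

    S_g(t) = (1/n) * sum_i exp(-int_0^t lambda_pop(a_i + u, y_i + u, sex_i) du).

Rates are treated as hazards, piecewise constant on unit attained-age /
calendar-year cells, so all integrals are closed-form per cell and S_g and
its running integral are evaluated exactly at the requested grid times.

The population analogues CS_g(t+Delta | t) and RMRL_g(t+Delta | t) are
formed from S_g, and :func:`contrast` combines them with the cohort curves
on the relative or absolute scale.  Population curves carry zero sampling
variance (they derive from national rate tables), so contrast confidence
intervals reflect cohort uncertainty only.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .params import PrognosisCurve

__all__ = [
    "RateTable",
    "ExpectedSurvival",
    "read_ratetable",
    "write_ratetable",
    "ederer1",
    "population_curves",
    "contrast",
]


@dataclass
class RateTable:
    """Yearly all-cause mortality hazards on contiguous integer
    age x calendar-year ranges, one matrix per sex.

    ``rates[sex][i, j]`` is the hazard (deaths per person-year) at
    attained age ``age_min + i`` during calendar year ``year_min + j``.

    Rate tables published as yearly death *probabilities* q must be
    converted to hazards first, with -log(1 - q) (see
    :func:`read_ratetable`).
    """

    age_min: int
    year_min: int
    rates: dict

    def __post_init__(self) -> None:
        shapes = {s: np.asarray(m, dtype=float) for s, m in self.rates.items()}
        if not shapes:
            raise ValueError("rate table must cover at least one sex")
        shape = next(iter(shapes.values())).shape
        for s, m in shapes.items():
            if m.shape != shape:
                raise ValueError("all sexes must cover the same age/year ranges")
            if np.any(m < 0) or not np.all(np.isfinite(m)):
                raise ValueError(f"rates for sex {s!r} must be finite and >= 0")
        self.rates = shapes

    @property
    def n_ages(self) -> int:
        return next(iter(self.rates.values())).shape[0]

    @property
    def n_years(self) -> int:
        return next(iter(self.rates.values())).shape[1]

    @property
    def age_max(self) -> int:
        return self.age_min + self.n_ages - 1

    @property
    def year_max(self) -> int:
        return self.year_min + self.n_years - 1

    def rate(self, age: int, year: int, sex: str, out_of_range: str = "clamp") -> float:
        """Hazard for the (age, year, sex) cell.

        Out-of-range ages/years either carry the boundary cell forward
        (``"clamp"``, the registry convention for tables that end at a
        maximum age) or raise (``"error"``)."""
        if sex not in self.rates:
            raise KeyError(f"sex {sex!r} not in rate table")
        i = age - self.age_min
        j = year - self.year_min
        if not (0 <= i < self.n_ages and 0 <= j < self.n_years):
            if out_of_range == "error":
                raise KeyError(
                    f"cell (age={age}, year={year}, sex={sex}) outside rate table "
                    f"[{self.age_min}-{self.age_max}] x [{self.year_min}-{self.year_max}]"
                )
            i = min(max(i, 0), self.n_ages - 1)
            j = min(max(j, 0), self.n_years - 1)
        return float(self.rates[sex][i, j])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex in sorted(self.rates):
            m = self.rates[sex]
            for i in range(self.n_ages):
                for j in range(self.n_years):
                    rows.append((self.age_min + i, self.year_min + j, sex, m[i, j]))
        return pd.DataFrame(rows, columns=["age", "year", "sex", "rate"])


def read_ratetable(path, delimiter: str = "\t", probabilities: bool = False) -> RateTable:
    """Read a rate table from delimited text with header columns
    age, year, sex, rate.

    ``rate`` is a hazard in deaths per person-year.  Standard
    relative-survival rate-table layouts (one age x year matrix per sex,
    holding yearly or daily death probabilities) map onto this schema by
    melting the matrices to long format and converting probabilities to
    hazards; pass ``probabilities=True`` for yearly probabilities q and
    the reader applies -log(1 - q).  Daily probabilities should be
    annualized (q_year = 1 - (1 - q_day)**365.24) before conversion.
    """
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    required = {"age", "year", "sex", "rate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rate table file {path} is missing columns: {sorted(missing)}")
    age_min, age_max = int(df["age"].min()), int(df["age"].max())
    year_min, year_max = int(df["year"].min()), int(df["year"].max())
    rates = {}
    for sex, grp in df.groupby("sex"):
        m = np.full((age_max - age_min + 1, year_max - year_min + 1), np.nan)
        m[grp["age"].to_numpy(int) - age_min, grp["year"].to_numpy(int) - year_min] = grp[
            "rate"
        ].to_numpy(float)
        if np.any(np.isnan(m)):
            raise ValueError(f"rate table for sex {sex!r} has gaps; ranges must be contiguous")
        if probabilities:
            if np.any(m >= 1):
                raise ValueError("yearly death probabilities must be < 1")
            m = -np.log1p(-m)
        rates[str(sex)] = m
    return RateTable(age_min=age_min, year_min=year_min, rates=rates)


def write_ratetable(table: RateTable, path, delimiter: str = "\t") -> None:
    table.to_frame().to_csv(path, sep=delimiter, index=False, float_format="%.17g")


@dataclass
class ExpectedSurvival:
    """Ederer I expected survival S_g and its running integral on a grid."""

    grid: np.ndarray
    s_exp: np.ndarray
    r_exp: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(np.diff(self.s_exp) > 1e-12):
            raise ValueError("expected survival must be nonincreasing")
        if np.any(np.diff(self.r_exp) < -1e-12):
            raise ValueError("integrated survival must be nondecreasing")

    def survival_at(self, t) -> np.ndarray:
        """S_g(t), log-linearly interpolated between grid points (exact
        at grid points; exact everywhere for a constant-rate table)."""
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            logs = np.log(np.maximum(self.s_exp, 1e-300))
        return np.exp(np.interp(t, self.grid, logs))

    def integral_at(self, t) -> np.ndarray:
        """int_0^t S_g, using the log-linear survival model within each
        grid interval (consistent with :meth:`survival_at`)."""
        scalar = np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty(t.size)
        for k, tt in enumerate(t):
            i = int(np.searchsorted(self.grid, tt, side="right") - 1)
            i = min(max(i, 0), self.grid.size - 2) if self.grid.size > 1 else 0
            g0, g1 = self.grid[i], self.grid[min(i + 1, self.grid.size - 1)]
            s0, s1 = self.s_exp[i], self.s_exp[min(i + 1, self.grid.size - 1)]
            if tt <= self.grid[0]:
                out[k] = self.r_exp[0] - (self.grid[0] - tt) * s0
                continue
            h = g1 - g0
            rho = 0.0 if (h <= 0 or s0 <= 0 or s1 <= 0) else np.log(s0 / s1) / h
            u = min(tt, self.grid[-1]) - g0
            if rho > 1e-14:
                seg = s0 * (1.0 - np.exp(-rho * u)) / rho
            else:
                seg = s0 * u
            out[k] = self.r_exp[i] + seg
            if tt > self.grid[-1]:
                out[k] += (tt - self.grid[-1]) * self.s_exp[-1]
        return out[0] if scalar else out


def _subject_expected(
    age: float, year: int, sex: str, table: RateTable, grid: np.ndarray, out_of_range: str
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Exact matched-individual survival and its integral at grid times."""
    gmax = float(grid[-1])
    frac = age - np.floor(age)
    first_age_break = 1.0 - frac if frac > 1e-12 else 1.0
    age_breaks = np.arange(first_age_break, gmax, 1.0)
    year_breaks = np.arange(1.0, gmax, 1.0)  # year_of_dx is integral
    bounds = np.unique(np.concatenate(([0.0], age_breaks, year_breaks, [gmax])))
    mids = 0.5 * (bounds[:-1] + bounds[1:])
    clamped = False
    lam = np.empty(mids.size)
    for j, u in enumerate(bounds[:-1]):
        a = int(np.floor(age + u + 1e-9))
        y = int(np.floor(year + u + 1e-9))
        if out_of_range == "error":
            lam[j] = table.rate(a, y, sex, out_of_range="error")
        else:
            in_range = table.age_min <= a <= table.age_max and table.year_min <= y <= table.year_max
            clamped |= not in_range
            lam[j] = table.rate(a, y, sex, out_of_range="clamp")
    widths = np.diff(bounds)
    cum_haz = np.concatenate(([0.0], np.cumsum(lam * widths)))
    s_bounds = np.exp(-cum_haz)
    with np.errstate(divide="ignore", invalid="ignore"):
        seg_int = np.where(
            lam > 1e-300,
            s_bounds[:-1] * (1.0 - np.exp(-lam * widths)) / np.where(lam > 0, lam, 1.0),
            s_bounds[:-1] * widths,
        )
    cum_int = np.concatenate(([0.0], np.cumsum(seg_int)))

    idx = np.clip(np.searchsorted(bounds, grid, side="right") - 1, 0, lam.size - 1)
    u = grid - bounds[idx]
    s = s_bounds[idx] * np.exp(-lam[idx] * u)
    with np.errstate(divide="ignore", invalid="ignore"):
        partial = np.where(
            lam[idx] > 1e-300,
            s_bounds[idx] * (1.0 - np.exp(-lam[idx] * u)) / np.where(lam[idx] > 0, lam[idx], 1.0),
            s_bounds[idx] * u,
        )
    r = cum_int[idx] + partial
    return s, r, clamped


def ederer1(
    cohort: Cohort, table: RateTable, grid, out_of_range: str = "clamp"
) -> ExpectedSurvival:
    """Ederer I expected survival of the cohort's matched population twins.

    Parameters
    ----------
    grid:
        Times since diagnosis (years) at which S_g and its integral are
        evaluated; the evaluation is exact at every grid time.
    out_of_range:
        ``"clamp"`` carries the boundary cell's rate forward with a
        warning when a subject's attained age or calendar year leaves the
        table; ``"error"`` raises naming the missing cell.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a nonempty 1-d array of times")
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be nonnegative and strictly increasing")
    if grid[0] > 0:
        grid = np.concatenate(([0.0], grid))
    s_sum = np.zeros(grid.size)
    r_sum = np.zeros(grid.size)
    any_clamped = False
    for i in range(cohort.n):
        s, r, clamped = _subject_expected(
            float(cohort.age_at_dx[i]),
            int(cohort.year_of_dx[i]),
            str(cohort.sex[i]),
            table,
            grid,
            out_of_range,
        )
        s_sum += s
        r_sum += r
        any_clamped |= clamped
    if any_clamped:
        warnings.warn(
            "some subjects left the rate table's age/year range; boundary rates were carried forward",
            stacklevel=2,
        )
    return ExpectedSurvival(grid=grid, s_exp=s_sum / cohort.n, r_exp=r_sum / cohort.n)


def population_curves(
    exp_surv: ExpectedSurvival, delta: float, t_grid=None
) -> tuple[PrognosisCurve, PrognosisCurve]:
    """Population analogues (CS_g, RMRL_g) of the conditional survival
    and restricted mean residual lifetime, treated as deterministic
    (zero variance)."""
    if t_grid is None:
        g = exp_surv.grid
        t_grid = g[g <= g[-1] - delta + 1e-9]
    t_grid = np.asarray(t_grid, dtype=float)
    s_t = exp_surv.survival_at(t_grid)
    s_td = exp_surv.survival_at(t_grid + delta)
    r_t = np.atleast_1d(exp_surv.integral_at(t_grid))
    r_td = np.atleast_1d(exp_surv.integral_at(t_grid + delta))
    mask = s_t <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        cs = np.where(mask, np.nan, s_td / s_t)
        rm = np.where(mask, np.nan, (r_td - r_t) / s_t)
    zeros = np.zeros(t_grid.size)

    def curve(label, est, clip):
        e = np.clip(est, clip[0], clip[1])
        e = np.where(mask, np.nan, e)
        return PrognosisCurve(
            label=label,
            delta=delta,
            t_grid=t_grid.copy(),
            estimate=e,
            variance=np.where(mask, np.nan, zeros),
            ci_lower=e.copy(),
            ci_upper=e.copy(),
            undefined_mask=mask.copy(),
        )

    return curve("CS_g", cs, (0.0, 1.0)), curve("RMRL_g", rm, (0.0, delta))


def contrast(
    cohort_curve: PrognosisCurve, pop_curve: PrognosisCurve, scale: str
) -> PrognosisCurve:
    """Cohort-vs-population contrast on the relative ("ratio") or
    absolute ("difference") scale.

    The population curve is treated as a known constant, so
    var(ratio) = var_c / pop^2 and var(difference) = var_c.
    """
    if scale not in ("ratio", "difference"):
        raise ValueError(f"scale must be 'ratio' or 'difference', got {scale!r}")
    if cohort_curve.t_grid.shape != pop_curve.t_grid.shape or not np.allclose(
        cohort_curve.t_grid, pop_curve.t_grid
    ):
        raise ValueError("cohort and population curves must share the t grid")
    if abs(cohort_curve.delta - pop_curve.delta) > 1e-12:
        raise ValueError("cohort and population curves must share delta")
    mask = cohort_curve.undefined_mask | pop_curve.undefined_mask
    pop = pop_curve.estimate
    with np.errstate(divide="ignore", invalid="ignore"):
        if scale == "ratio":
            mask = mask | ~(np.abs(pop) > 1e-300)
            est = cohort_curve.estimate / pop
            var = cohort_curve.variance / pop**2
            lo = cohort_curve.ci_lower / pop
            hi = cohort_curve.ci_upper / pop
        else:
            est = cohort_curve.estimate - pop
            var = cohort_curve.variance.copy()
            lo = cohort_curve.ci_lower - pop
            hi = cohort_curve.ci_upper - pop
    est = np.where(mask, np.nan, est)
    var = np.where(mask, np.nan, var)
    lo = np.where(mask, np.nan, lo)
    hi = np.where(mask, np.nan, hi)
    return PrognosisCurve(
        label=f"{cohort_curve.label}_{scale}",
        delta=cohort_curve.delta,
        t_grid=cohort_curve.t_grid.copy(),
        estimate=est,
        variance=var,
        ci_lower=lo,
        ci_upper=hi,
        undefined_mask=mask,
    )
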