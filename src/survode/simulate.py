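"""Seeded synthetic cohorts and rate tables with known closed-form truths.

The generator emulates the structure of a cancer-registry cohort: latent
cause-specific death times (target cancer vs. other causes) with constant
or piecewise-constant hazards, independent exponential censoring, an
administrative censoring horizon, and demographics (age at diagnosis,
sex, calendar year of diagnosis) drawn independently of survival by
default.  Because the hazards are (piecewise-)exponential, every
prognosis parameter has an exact closed form under the generating law;
:func:`truth` evaluates it, so estimators and variances can be validated
without any external data.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np
import yaml

from .cohort import Cohort
from .population import RateTable

__all__ = [
    "PiecewiseHazard",
    "ScenarioSpec",
    "generate_cohort",
    "truth",
    "generate_ratetable",
    "load_scenario",
]

HazardLike = Union[float, "PiecewiseHazard", tuple, list, dict]


@dataclass(frozen=True)
class PiecewiseHazard:
    """A piecewise-constant hazard: ``rates[k]`` applies on
    [breaks[k-1], breaks[k]) with breaks[-1] = inf."""

    rates: tuple
    breaks: tuple = ()

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in np.atleast_1d(self.rates))
        breaks = tuple(float(b) for b in np.atleast_1d(self.breaks)) if self.breaks else ()
        if any(r < 0 for r in rates):
            raise ValueError("hazard rates must be >= 0")
        if len(breaks) != len(rates) - 1:
            raise ValueError("need exactly one change-point fewer than rates")
        if any(b <= 0 for b in breaks) or any(np.diff(breaks) <= 0):
            raise ValueError("change-points must be positive and increasing")
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "breaks", breaks)

    @classmethod
    def coerce(cls, value: HazardLike) -> "PiecewiseHazard":
        if isinstance(value, cls):
            return value
        if isinstance(value, dict):
            return cls(rates=tuple(value["rates"]), breaks=tuple(value.get("breaks", ())))
        if np.isscalar(value):
            return cls(rates=(float(value),))
        value = list(value)
        if len(value) == 2 and not np.isscalar(value[0]):
            return cls(rates=tuple(value[0]), breaks=tuple(value[1]))
        return cls(rates=tuple(value))

    def rate_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(np.asarray(self.breaks), t, side="right")
        return np.asarray(self.rates)[idx]

    def cumulative(self, t) -> np.ndarray:
        """Lambda(t) = int_0^t rate."""
        t = np.asarray(t, dtype=float)
        edges = np.concatenate(([0.0], self.breaks))
        rates = np.asarray(self.rates)
        cum_at_edges = np.concatenate(([0.0], np.cumsum(rates[:-1] * np.diff(edges)))) if rates.size > 1 else np.array([0.0])
        idx = np.searchsorted(np.asarray(self.breaks), t, side="right")
        return cum_at_edges[idx] + rates[idx] * (t - edges[idx])

    def inverse_cumulative(self, h) -> np.ndarray:
        """Lambda^{-1}(h); inf where the total hazard never reaches h."""
        h = np.asarray(h, dtype=float)
        edges = np.concatenate(([0.0], self.breaks))
        rates = np.asarray(self.rates)
        cum = np.concatenate(([0.0], np.cumsum(rates[:-1] * np.diff(edges)))) if rates.size > 1 else np.array([0.0])
        idx = np.searchsorted(cum, h, side="right") - 1
        idx = np.clip(idx, 0, rates.size - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = edges[idx] + (h - cum[idx]) / rates[idx]
        out = np.where(rates[idx] <= 0, np.inf, out)
        return out

    @property
    def is_constant(self) -> bool:
        return len(self.rates) == 1


@dataclass(frozen=True)
class ScenarioSpec:
    """Study conditions for a synthetic registry cohort.

    Defaults emulate a registry cohort of working-age patients: diagnosis
    in 2001-2015, age at diagnosis uniform on [30, 60) (registry analyses
    of this kind restrict to under-60 patients), administrative censoring
    18 years after the earliest diagnosis year, and mild independent
    drop-out.
    """

    n: int = 1000
    lambda_cancer: HazardLike = 0.3
    lambda_other: HazardLike = 0.1
    censoring_rate: float = 0.1
    admin_censor_time: float = 18.0
    age_range: tuple = (30.0, 60.0)
    p_male: float = 0.5
    year_range: tuple = (2001, 2015)
    age_hazard_loghr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be > 0")
        object.__setattr__(self, "lambda_cancer", PiecewiseHazard.coerce(self.lambda_cancer))
        object.__setattr__(self, "lambda_other", PiecewiseHazard.coerce(self.lambda_other))


def generate_cohort(spec: ScenarioSpec) -> Cohort:
    """Draw a cohort under the scenario's competing-risks law.

    Latent cause-specific times come from the (piecewise-)exponential
    hazards via inverse-transform sampling; the observed time is the
    minimum of the two death times, the censoring time, and the
    administrative horizon.  Exact latent ties (probability zero) are
    broken toward the smaller event code, deterministically.  The same
    seed always yields an identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    age = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    sex = np.where(rng.random(n) < spec.p_male, "M", "F").astype("<U1")
    year = rng.integers(spec.year_range[0], spec.year_range[1] + 1, size=n)
    mult = (
        np.exp(spec.age_hazard_loghr * (age - 50.0) / 10.0)
        if spec.age_hazard_loghr
        else np.ones(n)
    )
    t_cancer = spec.lambda_cancer.inverse_cumulative(rng.exponential(size=n) / mult)
    t_other = spec.lambda_other.inverse_cumulative(rng.exponential(size=n) / mult)
    if spec.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum.reduce([t_cancer, t_other, t_cens, np.full(n, spec.admin_censor_time)])
    event = np.zeros(n, dtype=int)
    event[t_other <= time] = 2
    event[t_cancer <= time] = 1  # ties break toward the smaller event code
    return Cohort(time=time, event=event, age_at_dx=age, sex=sex, year_of_dx=year)


# ---------------------------------------------------------------------------
# closed-form truths

_PARAMETERS = (
    "cs",
    "rmrl",
    "crmtl",
    "risk",
    "risk_other",
    "ratio",
    "difference",
    "proportion",
    "cs_ratio",
    "cs_difference",
    "rmrl_ratio",
    "rmrl_difference",
)


def _segment_integrals(
    h1: PiecewiseHazard, h2: PiecewiseHazard, t0: float, t1: float
) -> tuple[float, float, float]:
    """Exact (int S, int S*l1, int S*l2) over [t0, t1] for the competing
    (piecewise-)exponential law, by composition over the change-points."""
    cuts = sorted({t0, t1} | {b for b in h1.breaks + h2.breaks if t0 < b < t1})
    i_s = i_1 = i_2 = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        l1 = float(h1.rate_at(a))
        l2 = float(h2.rate_at(a))
        lam = l1 + l2
        s_a = float(np.exp(-(h1.cumulative(a) + h2.cumulative(a))))
        w = b - a
        if lam > 0:
            block = s_a * (1.0 - np.exp(-lam * w)) / lam
        else:
            block = s_a * w
        i_s += block
        if lam > 0:
            i_1 += l1 * block
            i_2 += l2 * block
    return i_s, i_1, i_2


def truth(
    spec: ScenarioSpec,
    parameter: str,
    t: float,
    delta: float,
    pop_rate: float | None = None,
) -> float:
    """Analytic value of a prognosis parameter under the generating law.

    Censoring is ignored (it is independent by construction, so the
    parameters are functionals of the latent death-time law alone).
    Population contrasts (``"cs_ratio"``, ``"rmrl_difference"``, ...)
    need ``pop_rate``, a constant population hazard.
    """
    if parameter not in _PARAMETERS:
        raise ValueError(f"parameter must be one of {_PARAMETERS}, got {parameter!r}")
    h1, h2 = spec.lambda_cancer, spec.lambda_other
    s_t = float(np.exp(-(h1.cumulative(t) + h2.cumulative(t))))
    s_td = float(np.exp(-(h1.cumulative(t + delta) + h2.cumulative(t + delta))))
    i_s, i_1, i_2 = _segment_integrals(h1, h2, t, t + delta)
    cs = s_td / s_t
    rmrl_v = i_s / s_t
    risk_c = i_1 / s_t
    risk_o = i_2 / s_t

    if parameter == "cs":
        return cs
    if parameter == "rmrl":
        return rmrl_v
    if parameter == "crmtl":
        return delta - rmrl_v
    if parameter == "risk":
        return risk_c
    if parameter == "risk_other":
        return risk_o
    if parameter == "ratio":
        return risk_c / risk_o
    if parameter == "difference":
        return risk_c - risk_o
    if parameter == "proportion":
        return i_1 / (i_1 + i_2)

    if pop_rate is None:
        raise ValueError(f"parameter {parameter!r} needs pop_rate")
    cs_g = float(np.exp(-pop_rate * delta))
    rmrl_g = (1.0 - np.exp(-pop_rate * delta)) / pop_rate if pop_rate > 0 else delta
    if parameter == "cs_ratio":
        return cs / cs_g
    if parameter == "cs_difference":
        return cs - cs_g
    if parameter == "rmrl_ratio":
        return rmrl_v / rmrl_g
    return rmrl_v - rmrl_g  # rmrl_difference


def generate_ratetable(
    kind: str,
    params: dict,
    ages: tuple = (0, 109),
    years: tuple = (1990, 2030),
    sex_multiplier: float = 1.0,
) -> RateTable:
    """Deterministic synthetic rate tables.

    ``kind="constant"`` fills every cell with ``params["rate"]``;
    ``kind="gompertz"`` uses a * exp(b * age) (age-dependent, year-free).
    Male cells are ``sex_multiplier`` times the female cells.
    """
    n_age = ages[1] - ages[0] + 1
    n_year = years[1] - years[0] + 1
    age_axis = np.arange(ages[0], ages[1] + 1, dtype=float)
    if kind == "constant":
        col = np.full(n_age, float(params["rate"]))
    elif kind == "gompertz":
        col = float(params["a"]) * np.exp(float(params["b"]) * age_axis)
    else:
        raise ValueError(f"kind must be 'constant' or 'gompertz', got {kind!r}")
    female = np.tile(col[:, None], (1, n_year))
    return RateTable(
        age_min=ages[0],
        year_min=years[0],
        rates={"F": female, "M": female * sex_multiplier},
    )


def load_scenario(path) -> tuple[ScenarioSpec, dict | None]:
    """Read a scenario file (YAML / key-value mapping).

    Top-level keys are :class:`ScenarioSpec` fields; an optional
    ``ratetable`` mapping (kind, params, ages, years, sex_multiplier)
    describes a companion rate table and is returned as-is.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"scenario file {path} must contain a mapping")
    ratetable = raw.pop("ratetable", None)
    for key in ("age_range", "year_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ScenarioSpec(**raw), ratetable
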