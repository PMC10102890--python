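"""Prognosis parameters for cancer survivors, as plug-in ODE systems.

Built-in systems
----------------
* :func:`survival_system` -- all-cause survival S, dS = -S dA.  The
  plug-in solution is the Kaplan--Meier estimator written as a difference
  equation.
* :func:`rmrl_system` -- (S, R) with R(t) = int_0^t S(s) ds, driven by the
  all-cause hazard and the reserved time component.
* :func:`cif_system` -- (S, C^c, C^o): survival plus the cause-specific
  cumulative incidence functions, driven by the two cause-specific
  hazards.

Parameter curves
----------------
Each public curve function returns a :class:`PrognosisCurve`
t |-> Q-hat(t+Delta | t) with a pointwise variance from the generic
delta-method machinery.  For every parameter the variance is *also*
computed through the independently printed closed form (the scalar
survival-variance recursion, the Kaplan--Meier ratio formula, the RMRL
block form, and the a(t)/b(t) quadratic forms for the cause-specific
contrasts) and the two routes are asserted to agree to ``CHECK_TOL``;
this dual computation is always on, because the equivalence of the
generic recursions with the closed forms is the strongest available
internal correctness check.

Confidence intervals are Wald on the natural scale by default (clipped to
the parameter's logical range); ``ci_scale`` in {"plain", "log",
"loglog"} selects the transformation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import Cohort, StepHazard, TIME_COMPONENT, augment_time_component, nelson_aalen
from .engine import (
    CrossCov,
    ODESystem,
    PluginPath,
    Transform,
    cross_covariance,
    solve,
    transform_covariance,
)

__all__ = [
    "SystemBundle",
    "PrognosisCurve",
    "survival_system",
    "cif_system",
    "rmrl_system",
    "conditional_survival",
    "rmrl",
    "crmtl",
    "cause_specific_curves",
    "CAUSE_SPECIFIC_KINDS",
    "write_curve",
    "read_curve",
]

#: Tolerance of the always-on generic-vs-closed-form variance agreement.
CHECK_TOL = 1e-10

#: Denominators smaller than this (in absolute value) flag the transform
#: as undefined at that base time instead of raising.
DENOM_TOL = 1e-12

CAUSE_SPECIFIC_KINDS = ("risk", "ratio", "difference", "proportion")


@dataclass(frozen=True)
class SystemBundle:
    """An ODE system together with the bookkeeping needed to drive it:
    which state entry plays which role, which cause components the hazard
    must carry, and whether a time component is required."""

    system: ODESystem
    component_roles: tuple[str, ...]
    causes: object  # "all" or a tuple of event codes
    needs_time: bool

    def __post_init__(self) -> None:
        if len(self.component_roles) != self.system.p:
            raise ValueError("component_roles must name every state entry exactly once")


def survival_system() -> SystemBundle:
    """All-cause survival: p = 1, X(0) = 1, F(x) = -x."""
    return SystemBundle(
        system=ODESystem(
            p=1,
            q=1,
            x0=[1.0],
            F=lambda x: np.array([[-x[0]]]),
            gradF=lambda x: np.array([[[-1.0]]]),
        ),
        component_roles=("S",),
        causes="all",
        needs_time=False,
    )


def rmrl_system() -> SystemBundle:
    """Survival with its running integral: state (S, R), R(t) = int_0^t S.

    dS = -S dA (all-cause), dR = S dt; requires a time component."""
    def F(x):
        return np.array([[-x[0], 0.0], [0.0, x[0]]])

    def gradF(x):
        return np.array(
            [
                [[-1.0, 0.0], [0.0, 0.0]],  # all-cause hazard column
                [[0.0, 0.0], [1.0, 0.0]],  # time column
            ]
        )

    return SystemBundle(
        system=ODESystem(p=2, q=2, x0=[1.0, 0.0], F=F, gradF=gradF),
        component_roles=("S", "R"),
        causes="all",
        needs_time=True,
    )


def cif_system() -> SystemBundle:
    """Competing risks: state (S, C^c, C^o) driven by the cause-specific
    hazards (A^c, A^o).

    dS = -S dA^c - S dA^o, dC^c = S dA^c, dC^o = S dA^o; the rows sum so
    that S + C^c + C^o = 1 is conserved exactly."""
    def F(x):
        s = x[0]
        return np.array([[-s, -s], [s, 0.0], [0.0, s]])

    def gradF(x):
        return np.array(
            [
                [[-1.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]],  # A^c
                [[-1.0, 0.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]],  # A^o
            ]
        )

    return SystemBundle(
        system=ODESystem(p=3, q=2, x0=[1.0, 0.0, 0.0], F=F, gradF=gradF),
        component_roles=("S", "Cc", "Co"),
        causes=(1, 2),
        needs_time=False,
    )


# ---------------------------------------------------------------------------
# PrognosisCurve


@dataclass
class PrognosisCurve:
    """A prognosis parameter curve t |-> Q-hat(t+Delta | t).

    ``undefined_mask[i]`` is True where the transform was undefined (for
    example S-hat(t) = 0 late in follow-up); estimates, variances, and
    confidence bounds are NaN there.
    """

    label: str
    delta: float
    t_grid: np.ndarray
    estimate: np.ndarray
    variance: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    undefined_mask: np.ndarray

    def __post_init__(self) -> None:
        ok = ~self.undefined_mask
        if np.any(self.variance[ok] < 0):
            raise ValueError("variance must be nonnegative wherever defined")
        if np.any(self.ci_lower[ok] > self.estimate[ok] + 1e-12) or np.any(
            self.estimate[ok] > self.ci_upper[ok] + 1e-12
        ):
            raise ValueError("confidence bounds must bracket the estimate wherever defined")

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.variance)

    @property
    def defined(self) -> np.ndarray:
        return ~self.undefined_mask

    def at(self, t: float) -> float:
        i = int(np.argmin(np.abs(self.t_grid - t)))
        if abs(self.t_grid[i] - t) > 1e-9:
            raise ValueError(f"t = {t} is not on the curve grid")
        return float(self.estimate[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t_grid,
                "delta": self.delta,
                "estimate": self.estimate,
                "se": self.se,
                "lo95": self.ci_lower,
                "hi95": self.ci_upper,
                "defined": (~self.undefined_mask).astype(int),
            }
        )


def write_curve(curve: PrognosisCurve, path, delimiter: str = "\t") -> None:
    """Write a curve as delimited text (t, delta, estimate, se, lo95,
    hi95, defined); the header's first line carries the label."""
    df = curve.to_frame()
    df.insert(0, "label", curve.label)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def read_curve(path, delimiter: str = "\t") -> PrognosisCurve:
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    se = df["se"].to_numpy(float)
    return PrognosisCurve(
        label=str(df["label"].iloc[0]),
        delta=float(df["delta"].iloc[0]),
        t_grid=df["t"].to_numpy(float),
        estimate=df["estimate"].to_numpy(float),
        variance=se**2,
        ci_lower=df["lo95"].to_numpy(float),
        ci_upper=df["hi95"].to_numpy(float),
        undefined_mask=df["defined"].to_numpy(int) == 0,
    )


def _wald_ci(
    est: np.ndarray,
    var: np.ndarray,
    scale: str,
    clip: tuple[float, float],
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    z = norm.ppf(0.5 + level / 2)
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        if scale == "plain":
            lo, hi = est - z * se, est + z * se
        elif scale == "log":
            rel = np.where(est > 0, se / np.where(est > 0, est, 1.0), np.nan)
            lo, hi = est * np.exp(-z * rel), est * np.exp(z * rel)
            bad = ~(est > 0)
            lo = np.where(bad, est - z * se, lo)
            hi = np.where(bad, est + z * se, hi)
        elif scale == "loglog":
            inner = (0 < est) & (est < 1)
            theta = np.where(inner, z * se / np.abs(est * np.log(np.where(inner, est, 0.5))), np.nan)
            lo = np.where(inner, est ** np.exp(theta), est - z * se)
            hi = np.where(inner, est ** np.exp(-theta), est + z * se)
        else:
            raise ValueError(f"unknown ci scale {scale!r}")
    lo = np.clip(lo, clip[0], clip[1])
    hi = np.clip(hi, clip[0], clip[1])
    return lo, hi


# ---------------------------------------------------------------------------
# transforms


def _cs_transform() -> Transform:
    return Transform(
        m=1,
        H=lambda x, y: np.array([y[0] / x[0]]),
        gradH=lambda x, y: np.array([[-y[0] / x[0] ** 2, 1.0 / x[0]]]),
    )


def _rmrl_transform() -> Transform:
    # state (S, R); H = (R(t+D) - R(t)) / S(t)
    def H(x, y):
        return np.array([(y[1] - x[1]) / x[0]])

    def grad(x, y):
        s = x[0]
        dr = y[1] - x[1]
        return np.array([[-dr / s**2, -1.0 / s, 0.0, 1.0 / s]])

    return Transform(m=1, H=H, gradH=grad)


def _cause_transform(which: str) -> Transform:
    # state (S, Cc, Co)
    if which == "risk":
        def H(x, y):
            return np.array([(y[1] - x[1]) / x[0]])

        def grad(x, y):
            s = x[0]
            dc = y[1] - x[1]
            return np.array([[-dc / s**2, -1.0 / s, 0.0, 0.0, 1.0 / s, 0.0]])

    elif which == "ratio":
        def H(x, y):
            return np.array([(y[1] - x[1]) / (y[2] - x[2])])

        def grad(x, y):
            j1 = 1.0 / (y[2] - x[2])
            r = (y[1] - x[1]) * j1
            return np.array([[0.0, -j1, r * j1, 0.0, j1, -r * j1]])

    elif which == "difference":
        def H(x, y):
            return np.array([((y[1] - x[1]) - (y[2] - x[2])) / x[0]])

        def grad(x, y):
            s = x[0]
            d = (y[1] - x[1]) - (y[2] - x[2])
            return np.array([[-d / s**2, -1.0 / s, 1.0 / s, 0.0, 1.0 / s, -1.0 / s]])

    elif which == "proportion":
        def H(x, y):
            return np.array([(y[1] - x[1]) / (x[0] - y[0])])

        def grad(x, y):
            j2 = 1.0 / (x[0] - y[0])
            pr = (y[1] - x[1]) * j2
            return np.array([[-pr * j2, -j2, 0.0, pr * j2, j2, 0.0]])

    else:
        raise ValueError(f"which must be one of {CAUSE_SPECIFIC_KINDS}, got {which!r}")
    return Transform(m=1, H=H, gradH=grad)


# ---------------------------------------------------------------------------
# closed-form cross-checks


def _survival_closed_form(hazard: StepHazard) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan--Meier product and the scalar survival-variance recursion
    (the printed closed form, with the quadratic-covariation increment
    (dA)^2, which coincides with (1/Y) dA in the absence of ties).

    Computed independently of the generic engine, on the path grid
    (t = 0 prepended).
    """
    da = hazard.increments[:, 0]
    g = da.size
    s = np.empty(g + 1)
    v = np.empty(g + 1)
    s[0], v[0] = 1.0, 0.0
    for k in range(1, g + 1):
        d = da[k - 1]
        v[k] = v[k - 1] * (1.0 - 2.0 * d) + hazard.n * s[k - 1] ** 2 * d**2
        s[k] = s[k - 1] * (1.0 - d)
    return s, v


def _quadform(a: np.ndarray, b: np.ndarray, v_t, v_td, c, n: int, signs=(1, 1, 1, 1)) -> float:
    """(1/n) { s0 a'V(t)a + s1 a'V(t,t+D)'b + s2 b'V(t,t+D)a + s3 b'V(t+D)b }."""
    s0, s1, s2, s3 = signs
    return (
        s0 * a @ v_t @ a + s1 * a @ c.T @ b + s2 * b @ c @ a + s3 * b @ v_td @ b
    ) / n


def _assert_close(generic: float, closed: float, what: str, t: float) -> None:
    if not np.isfinite(closed) or not np.isfinite(generic):
        return
    if abs(generic - closed) > CHECK_TOL * max(1.0, abs(closed)):
        raise RuntimeError(
            f"internal consistency failure: generic variance {generic!r} != "
            f"closed-form {closed!r} for {what} at t = {t}"
        )


# ---------------------------------------------------------------------------
# curve assembly


def _default_t_grid(hazard: StepHazard, horizon: float, delta: float) -> np.ndarray:
    grid = np.concatenate(([0.0], hazard.times))
    return grid[grid <= horizon - delta + 1e-9]


def _regular_t_grid(horizon: float, delta: float, step: float) -> np.ndarray:
    return np.arange(0.0, horizon - delta + 1e-9, step)


def _assemble(
    bundle: SystemBundle,
    hazard: StepHazard,
    path: PluginPath,
    transform: Transform,
    t_grid: np.ndarray,
    delta: float,
    label: str,
    clip: tuple[float, float],
    ci_scale: str,
    guard: Callable[[np.ndarray, np.ndarray], bool],
    closed_check: Callable[[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray], float] | None,
    horizon: float | None = None,
) -> PrognosisCurve:
    m = t_grid.size
    est = np.full(m, np.nan)
    var = np.full(m, np.nan)
    mask = np.zeros(m, dtype=bool)
    for i, t in enumerate(t_grid):
        x_t = path.state_at(t)
        x_td = path.state_at(t + delta)
        if guard(x_t, x_td):
            mask[i] = True
            continue
        cc = cross_covariance(bundle.system, hazard, path, float(t), delta, horizon=horizon)
        e, cov = transform_covariance(transform, path, cc, float(t), delta)
        if not (np.isfinite(e[0]) and np.isfinite(cov[0, 0])):
            mask[i] = True
            continue
        est[i] = e[0]
        var[i] = max(cov[0, 0], 0.0)
        if closed_check is not None:
            v_t = path.cov_at(t)
            v_td = path.cov_at(t + delta)
            cf = closed_check(float(t), x_t, x_td, v_t, v_td, cc.final)
            _assert_close(float(cov[0, 0]), cf, label, float(t))
    lo, hi = _wald_ci(est, var, ci_scale, clip)
    lo[mask] = np.nan
    hi[mask] = np.nan
    return PrognosisCurve(
        label=label,
        delta=delta,
        t_grid=np.asarray(t_grid, float),
        estimate=est,
        variance=var,
        ci_lower=lo,
        ci_upper=hi,
        undefined_mask=mask,
    )


def _prepare(
    cohort: Cohort,
    bundle: SystemBundle,
    delta: float,
    horizon: float | None,
    mesh_step: float,
    t_grid: np.ndarray | None,
    t_step: float | None,
) -> tuple[StepHazard, PluginPath, np.ndarray, float]:
    hazard = nelson_aalen(cohort, bundle.causes)
    if horizon is None:
        horizon = float(cohort.time.max())
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if bundle.needs_time:
        hazard = augment_time_component(hazard, mesh_step, horizon=horizon)
    path = solve(bundle.system, hazard)
    if t_grid is None:
        t_grid = (
            _regular_t_grid(horizon, delta, t_step)
            if t_step is not None
            else _default_t_grid(hazard, horizon, delta)
        )
    else:
        t_grid = np.asarray(t_grid, dtype=float)
        if t_grid.size and t_grid.max() + delta > horizon + 1e-9:
            raise ValueError("t_grid extends beyond horizon - delta")
    return hazard, path, t_grid, horizon


def conditional_survival(
    cohort: Cohort,
    delta: float,
    t_grid: np.ndarray | None = None,
    horizon: float | None = None,
    t_step: float | None = None,
    ci_scale: str = "plain",
) -> PrognosisCurve:
    """Conditional Delta-year survival CS_c(t+Delta | t) = S(t+Delta)/S(t).

    The point estimate is a ratio of Kaplan--Meier values; the variance
    comes from the generic delta-method machinery and is cross-checked
    against the printed Kaplan--Meier-ratio closed form at every t.
    """
    bundle = survival_system()
    hazard, path, t_grid, horizon = _prepare(cohort, bundle, delta, horizon, 0.01, t_grid, t_step)
    s_cf, v_cf = _survival_closed_form(hazard)
    grid = path.grid

    def closed_check(t, x_t, x_td, v_t, v_td, c):
        i = int(np.searchsorted(grid, t, side="right") - 1)
        j = int(np.searchsorted(grid, t + delta, side="right") - 1)
        s_t, s_td = s_cf[i], s_cf[j]
        if s_t <= 0:
            return np.nan
        # the cross-covariance recursion collapses to V(t) S(t+D)/S(t)
        _assert_close(float(c[0, 0]), v_cf[i] * s_td / s_t, "CS cross-covariance", t)
        return (v_cf[j] - v_cf[i] * (s_td / s_t) ** 2) / (hazard.n * s_t**2)

    return _assemble(
        bundle,
        hazard,
        path,
        _cs_transform(),
        t_grid,
        delta,
        label="CS",
        clip=(0.0, 1.0),
        ci_scale=ci_scale,
        guard=lambda x_t, x_td: x_t[0] <= DENOM_TOL,
        closed_check=closed_check,
        horizon=horizon,
    )


def rmrl(
    cohort: Cohort,
    delta: float,
    t_grid: np.ndarray | None = None,
    horizon: float | None = None,
    mesh_step: float = 0.01,
    t_step: float | None = None,
    ci_scale: str = "plain",
) -> PrognosisCurve:
    """Restricted mean residual lifetime
    RMRL_c(t+Delta | t) = (R(t+Delta) - R(t)) / S(t), R(t) = int_0^t S.

    The generic variance is cross-checked against the printed block
    quadratic form in (V(t), V(t, t+Delta), V(t+Delta)) at every t.
    """
    bundle = rmrl_system()
    hazard, path, t_grid, horizon = _prepare(cohort, bundle, delta, horizon, mesh_step, t_grid, t_step)

    def closed_check(t, x_t, x_td, v_t, v_td, c):
        s_t = x_t[0]
        if s_t <= 0:
            return np.nan
        dr = x_td[1] - x_t[1]
        a = np.array([dr / s_t**2, 1.0 / s_t])
        b = np.array([0.0, 1.0 / s_t])
        return _quadform(a, b, v_t, v_td, c, hazard.n, signs=(1, -1, -1, 1))

    return _assemble(
        bundle,
        hazard,
        path,
        _rmrl_transform(),
        t_grid,
        delta,
        label="RMRL",
        clip=(0.0, delta),
        ci_scale=ci_scale,
        guard=lambda x_t, x_td: x_t[0] <= DENOM_TOL,
        closed_check=closed_check,
        horizon=horizon,
    )


def crmtl(curve: PrognosisCurve) -> PrognosisCurve:
    """Conditional restricted mean time lost: Delta - RMRL.

    An affine transform, so the variance is identical and the confidence
    bounds swap roles."""
    if curve.label not in ("RMRL", "CRMTL"):
        raise ValueError("crmtl expects an RMRL curve")
    d = curve.delta
    return PrognosisCurve(
        label="CRMTL",
        delta=d,
        t_grid=curve.t_grid.copy(),
        estimate=d - curve.estimate,
        variance=curve.variance.copy(),
        ci_lower=np.clip(d - curve.ci_upper, 0.0, d),
        ci_upper=np.clip(d - curve.ci_lower, 0.0, d),
        undefined_mask=curve.undefined_mask.copy(),
    )


def cause_specific_curves(
    cohort: Cohort,
    delta: float,
    which: str = "risk",
    t_grid: np.ndarray | None = None,
    horizon: float | None = None,
    t_step: float | None = None,
    ci_scale: str = "plain",
) -> PrognosisCurve:
    """Cause-specific prognosis parameters among survivors at t.

    ``which`` selects the transform of (S, C^c, C^o):

    * ``"risk"``        (C^c(t+D) - C^c(t)) / S(t)
    * ``"ratio"``       (C^c(t+D) - C^c(t)) / (C^o(t+D) - C^o(t))
    * ``"difference"``  risk of cancer death minus risk of other death
    * ``"proportion"``  (C^c(t+D) - C^c(t)) / (S(t) - S(t+D))

    Ratio/proportion are flagged undefined where their denominator
    vanishes.  The generic variance is cross-checked against the printed
    a(t)/b(t) quadratic forms at every t.
    """
    if which not in CAUSE_SPECIFIC_KINDS:
        raise ValueError(f"which must be one of {CAUSE_SPECIFIC_KINDS}, got {which!r}")
    bundle = cif_system()
    hazard, path, t_grid, horizon = _prepare(cohort, bundle, delta, horizon, 0.01, t_grid, t_step)
    n = hazard.n

    def guard(x_t, x_td):
        if x_t[0] <= DENOM_TOL:
            return True
        if which == "ratio" and abs(x_td[2] - x_t[2]) <= DENOM_TOL:
            return True
        if which == "proportion" and abs(x_t[0] - x_td[0]) <= DENOM_TOL:
            return True
        return False

    def closed_check(t, x_t, x_td, v_t, v_td, c):
        s_t = x_t[0]
        dcc = x_td[1] - x_t[1]
        dco = x_td[2] - x_t[2]
        if which == "risk":
            a = np.array([-dcc / s_t, -1.0, 0.0]) / s_t
            b = np.array([0.0, 1.0, 0.0]) / s_t
        elif which == "ratio":
            j1 = 1.0 / dco
            r = dcc / dco
            a = j1 * np.array([0.0, -1.0, r])
            b = j1 * np.array([0.0, 1.0, -r])
        elif which == "difference":
            a = np.array([-(dcc - dco) / s_t, -1.0, 1.0]) / s_t
            b = np.array([0.0, 1.0, -1.0]) / s_t
        else:  # proportion
            j2 = 1.0 / (x_t[0] - x_td[0])
            pr = dcc * j2
            a = j2 * np.array([-pr, -1.0, 0.0])
            b = j2 * np.array([pr, 1.0, 0.0])
        return _quadform(a, b, v_t, v_td, c, n)

    clip = {
        "risk": (0.0, 1.0),
        "ratio": (0.0, np.inf),
        "difference": (-1.0, 1.0),
        "proportion": (0.0, 1.0),
    }[which]
    return _assemble(
        bundle,
        hazard,
        path,
        _cause_transform(which),
        t_grid,
        delta,
        label=which.upper(),
        clip=clip,
        ci_scale=ci_scale,
        guard=guard,
        closed_check=closed_check,
        horizon=horizon,
    )
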