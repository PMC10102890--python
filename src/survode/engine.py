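"""Generic plug-in solver for ODE-representable survival parameters.

Many survival summaries X solve an integral equation driven by a vector A
of cumulative hazard coefficients,

    X(t) = X(0) + int_0^t F(X(s)) dA(s),

and replacing A by its Nelson--Aalen estimate turns the equation into a
pathwise difference equation for the plug-in estimator X-hat.  This module
solves that difference equation and propagates its sampling covariance:

* :func:`solve` / :func:`solve_plugin` -- the state path X-hat(t),
* :func:`solve_variance` -- the covariance path V-hat(t) of the
  root-n-scaled residual, via a forward recursion whose correction term is
  driven by the quadratic covariation [B] of the hazard increments,
* :func:`cross_covariance` -- V-hat(t, t+Delta) between two time points,
* :func:`transform_covariance` -- the delta-method covariance of a smooth
  functional H(X(t), X(t+Delta)).

All coefficient evaluations use the state at the previous grid point
(the "s-" convention of the defining equations).  Components of the
driving :class:`~survode.cohort.StepHazard` labelled ``"time"`` are
Lebesgue integrators: they never enter [B], and their contribution to the
covariance recursions is applied as the exact one-step transport
(I + grad-F_time * h) V (I + grad-F_time * h)^T, which solves the
continuous part of the recursion exactly whenever grad-F_time is
state-independent and nilpotent -- true for every system shipped in
:mod:`survode.params` -- and makes the solution independent of the mesh.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .cohort import StepHazard

__all__ = [
    "ODESystem",
    "PluginPath",
    "CrossCov",
    "Transform",
    "solve",
    "solve_plugin",
    "solve_variance",
    "quadratic_covariation",
    "cross_covariance",
    "transform_covariance",
]


@dataclass(frozen=True)
class ODESystem:
    """An ODE system X(t) = X(0) + int F(X) dA.

    Attributes
    ----------
    p, q:
        State dimension and number of integrator components.
    x0:
        Initial value X(0), length p.
    F:
        Map from a state vector to the p x q coefficient matrix.
    gradF:
        Map from a state vector to a (q, p, p) array whose j-th slice is
        the Jacobian of column j of F: ``gradF(x)[j][r, c] = d F[r, j] / d x[c]``.
    v0:
        Initial covariance V(0) (p x p); zero when X(0) is a known
        constant, which is the case for every built-in system.
    """

    p: int
    q: int
    x0: np.ndarray
    F: Callable[[np.ndarray], np.ndarray]
    gradF: Callable[[np.ndarray], np.ndarray]
    v0: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x0", np.asarray(self.x0, dtype=float).reshape(self.p))
        v0 = np.zeros((self.p, self.p)) if self.v0 is None else np.asarray(self.v0, dtype=float)
        if v0.shape != (self.p, self.p):
            raise ValueError(f"v0 must be {self.p}x{self.p}")
        if not np.allclose(v0, v0.T):
            raise ValueError("v0 must be symmetric")
        if np.any(np.linalg.eigvalsh(0.5 * (v0 + v0.T)) < -1e-10):
            raise ValueError("v0 must be positive semidefinite")
        object.__setattr__(self, "v0", v0)

    def check_gradients(
        self,
        states: Sequence[np.ndarray] | None = None,
        rng: np.random.Generator | None = None,
        h: float = 1e-6,
        tol: float = 1e-4,
    ) -> None:
        """Verify gradF against central finite differences of F.

        Raises ``ValueError`` on disagreement; used by tests and available
        to users defining their own systems.
        """
        if states is None:
            rng = rng or np.random.default_rng(0)
            states = [self.x0 + rng.normal(scale=0.3, size=self.p) for _ in range(5)]
        for x in states:
            x = np.asarray(x, dtype=float)
            g = np.asarray(self.gradF(x), dtype=float)
            if g.shape != (self.q, self.p, self.p):
                raise ValueError(f"gradF(x) must have shape ({self.q}, {self.p}, {self.p})")
            for c in range(self.p):
                e = np.zeros(self.p)
                e[c] = h
                fd = (np.asarray(self.F(x + e)) - np.asarray(self.F(x - e))) / (2 * h)
                for j in range(self.q):
                    if not np.allclose(fd[:, j], g[j][:, c], atol=tol, rtol=tol):
                        raise ValueError(
                            f"gradF component {j}, column {c} disagrees with finite differences at {x}"
                        )


@dataclass
class PluginPath:
    """The solved plug-in path on the hazard grid (prepended with t = 0).

    ``x[k]`` is X-hat at ``grid[k]`` (a right-continuous step function:
    X-hat(s-) is the value at the previous grid point); ``v[k]`` is the
    covariance V-hat at ``grid[k]`` when solved with variance, else None.
    """

    grid: np.ndarray
    x: np.ndarray
    v: np.ndarray | None
    n: int

    def index_of(self, t: float) -> int:
        """Index of the last grid point <= t (right-continuous evaluation,
        with a 1e-9 tolerance absorbing float noise in mesh multiples)."""
        if t < self.grid[0] - 1e-12:
            raise ValueError(f"t = {t} precedes the grid start {self.grid[0]}")
        return int(np.searchsorted(self.grid, t + 1e-9, side="right") - 1)

    def state_at(self, t: float) -> np.ndarray:
        return self.x[self.index_of(t)]

    def cov_at(self, t: float) -> np.ndarray:
        if self.v is None:
            raise ValueError("path was solved without a covariance; use solve()")
        return self.v[self.index_of(t)]


@dataclass
class CrossCov:
    """Cross-covariances V-hat(t, s) for s in (t, t+Delta], anchored at
    V-hat(t, t) = V-hat(t).

    ``mats[i]`` is V-hat(t, times[i]); ``times[0] == base_time`` holds the
    anchor.  ``final`` is V-hat(t, t+Delta).
    """

    base_time: float
    times: np.ndarray
    mats: np.ndarray

    @property
    def final(self) -> np.ndarray:
        return self.mats[-1]


@dataclass(frozen=True)
class Transform:
    """A smooth functional H(X(t), X(t+Delta)) with Jacobian.

    ``H(x, y)`` returns a length-m vector; ``gradH(x, y)`` the (m, 2p)
    Jacobian with the derivative in x in the first p columns.
    """

    m: int
    H: Callable[[np.ndarray, np.ndarray], np.ndarray]
    gradH: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def check_gradient(
        self,
        pairs: Sequence[tuple[np.ndarray, np.ndarray]],
        h: float = 1e-6,
        tol: float = 1e-4,
    ) -> None:
        for x, y in pairs:
            x = np.asarray(x, float)
            y = np.asarray(y, float)
            p = x.size
            g = np.asarray(self.gradH(x, y), float)
            if g.shape != (self.m, 2 * p):
                raise ValueError(f"gradH must have shape ({self.m}, {2 * p})")
            for c in range(2 * p):
                dx = np.zeros(p)
                dy = np.zeros(p)
                (dx if c < p else dy)[c % p] = h
                fd = (
                    np.asarray(self.H(x + dx, y + dy)) - np.asarray(self.H(x - dx, y - dy))
                ) / (2 * h)
                if not np.allclose(fd, g[:, c], atol=tol, rtol=tol):
                    raise ValueError(f"gradH column {c} disagrees with finite differences")


def _check_dims(system: ODESystem, hazard: StepHazard) -> None:
    if hazard.q != system.q:
        raise ValueError(
            f"hazard has {hazard.q} components but the system expects q = {system.q}"
        )


def quadratic_covariation(hazard: StepHazard) -> np.ndarray:
    """Per-jump quadratic covariation increments Delta[B] (G, q, q).

    Delta[B]_{ij}(s) = Delta A-hat^i(s) * Delta A-hat^j(s) for hazard
    components; any entry involving a "time" component is zero.
    """
    inc = hazard.increments
    db = inc[:, :, None] * inc[:, None, :]
    ti = hazard.time_index
    if ti is not None:
        db[:, ti, :] = 0.0
        db[:, :, ti] = 0.0
    return db


def solve(system: ODESystem, hazard: StepHazard, with_variance: bool = True) -> PluginPath:
    """Solve the plug-in difference equation, optionally with its
    covariance recursion, in a single forward pass over the grid.

    The state update is X(s_k) = X(s_{k-1}) + F(X(s_{k-1})) dA(s_k); the
    path is exact for pure-jump integrators.  The covariance update adds
    the drift terms V gradF^T + gradF V for each jump component, the
    correction n F d[B] F^T, and the exact transport for time components.
    """
    _check_dims(system, hazard)
    g = hazard.times.size
    grid = np.concatenate(([0.0], hazard.times))
    x = np.empty((g + 1, system.p))
    x[0] = system.x0
    v = None
    if with_variance:
        v = np.empty((g + 1, system.p, system.p))
        v[0] = system.v0
    ti = hazard.time_index
    haz = hazard.hazard_indices
    eye = np.eye(system.p)
    n = hazard.n

    for k in range(1, g + 1):
        xk = x[k - 1]
        inc = hazard.increments[k - 1]
        Fx = np.asarray(system.F(xk), dtype=float).reshape(system.p, system.q)
        xn = xk + Fx @ inc
        if not np.all(np.isfinite(xn)):
            raise FloatingPointError(
                f"non-finite state at grid time {grid[k]:.6g} (overflowing system?)"
            )
        x[k] = xn
        if not with_variance:
            continue
        grads = np.asarray(system.gradF(xk), dtype=float)
        V = v[k - 1]
        if ti is not None and inc[ti] != 0.0:
            T = eye + grads[ti] * inc[ti]
            V = T @ V @ T.T
        drift = np.zeros((system.p, system.p))
        for j in haz:
            if inc[j] != 0.0:
                drift += grads[j] * inc[j]
        if np.any(drift):
            V = V + drift @ V + V @ drift.T
        hinc = inc.copy()
        if ti is not None:
            hinc[ti] = 0.0
        if np.any(hinc):
            db = np.outer(hinc, hinc)
            V = V + n * (Fx @ db @ Fx.T)
        v[k] = 0.5 * (V + V.T)

    return PluginPath(grid=grid, x=x, v=v, n=n)


def solve_plugin(system: ODESystem, hazard: StepHazard) -> PluginPath:
    """State path only (no covariance)."""
    return solve(system, hazard, with_variance=False)


def solve_variance(system: ODESystem, hazard: StepHazard, path: PluginPath) -> np.ndarray:
    """Covariance path V-hat for an already-solved state path.

    Re-runs the fused recursion (the state pass is cheap) and attaches the
    covariance to ``path``; returns the (G+1, p, p) array.
    """
    full = solve(system, hazard, with_variance=True)
    if full.x.shape != path.x.shape or not np.allclose(full.x, path.x):
        raise ValueError("path was not solved on this hazard")
    path.v = full.v
    return full.v


def cross_covariance(
    system: ODESystem,
    hazard: StepHazard,
    path: PluginPath,
    t: float,
    delta: float,
    horizon: float | None = None,
) -> CrossCov:
    """Cross-covariance recursion V-hat(t, s) over s in (t, t+Delta].

    Anchored at V-hat(t, t) = V-hat(t); each jump applies
    V <- (I + sum_j gradF_j dA^j) V, and time components apply the exact
    transport (I + gradF_time h) V.

    ``horizon`` is the end of follow-up; the path is constant between the
    last jump and the horizon (the product-limit convention), so t may
    exceed the last grid time as long as it stays within the horizon.
    """
    _check_dims(system, hazard)
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if t > (path.grid[-1] if horizon is None else horizon) + 1e-9:
        raise ValueError(f"t = {t} lies beyond the solved horizon")
    if path.v is None:
        raise ValueError("path must carry a covariance; use solve()")
    i_t = path.index_of(t)
    V = path.v[i_t].copy()
    times = [t]
    mats = [V.copy()]
    eye = np.eye(system.p)
    ti = hazard.time_index
    s_end = t + delta + 1e-12
    for k in range(i_t + 1, path.grid.size):
        s = path.grid[k]
        if s > s_end:
            break
        inc = hazard.increments[k - 1]
        grads = np.asarray(system.gradF(path.x[k - 1]), dtype=float)
        if ti is not None and inc[ti] != 0.0:
            V = (eye + grads[ti] * inc[ti]) @ V
        drift = np.zeros((system.p, system.p))
        for j in hazard.hazard_indices:
            if inc[j] != 0.0:
                drift += grads[j] * inc[j]
        if np.any(drift):
            V = V + drift @ V
        times.append(s)
        mats.append(V.copy())
    return CrossCov(base_time=t, times=np.asarray(times), mats=np.asarray(mats))


def transform_covariance(
    transform: Transform,
    path: PluginPath,
    crosscov: CrossCov,
    t: float,
    delta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Delta-method estimate and covariance of H(X-hat(t), X-hat(t+Delta)).

    Returns ``(estimate, covariance)`` with covariance
    (1/n) gradH [[V(t), V(t,t+D)^T], [V(t,t+D), V(t+D)]] gradH^T,
    symmetrized.  A non-finite gradient (e.g. a vanishing denominator)
    yields NaN entries rather than an exception, so that callers can flag
    single undefined time points without aborting a whole curve.
    """
    if abs(crosscov.base_time - t) > 1e-9:
        raise ValueError("crosscov was computed for a different base time")
    x_t = path.state_at(t)
    x_td = path.state_at(t + delta)
    v_t = path.cov_at(t)
    v_td = path.cov_at(t + delta)
    c = crosscov.final
    est = np.atleast_1d(np.asarray(transform.H(x_t, x_td), dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        grad = np.asarray(transform.gradH(x_t, x_td), dtype=float)
    p = path.x.shape[1]
    big = np.empty((2 * p, 2 * p))
    big[:p, :p] = v_t
    big[:p, p:] = c.T
    big[p:, :p] = c
    big[p:, p:] = v_td
    if not np.all(np.isfinite(grad)):
        cov = np.full((transform.m, transform.m), np.nan)
    else:
        cov = grad @ big @ grad.T / path.n
        cov = 0.5 * (cov + cov.T)
    return est, cov
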