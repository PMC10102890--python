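"""Cohort data model and nonparametric cumulative-hazard estimation.

Right-censored competing-risks event data (time since diagnosis, cause of
death, demographics) and the Nelson--Aalen estimator of (cause-specific)
cumulative hazards with at-risk accounting.  The resulting
:class:`StepHazard` is the multivariate integrator that drives the plug-in
ODE solver in :mod:`survode.engine`; :func:`augment_time_component` adds a
reserved "time" component so that Lebesgue (dt) integrals, such as the
running integral of the survival curve, can be accumulated on the same
grid as the hazard jumps.

Conventions
-----------
* The time origin is diagnosis (t = 0); all times are in years.
* Event codes: 0 = censored, 1 = death from the target cancer,
  2 = death from other causes.
* Simultaneous deaths at a time s are pooled: the hazard jump is
  dN(s)/Y(s) with dN possibly > 1.
* Subjects censored exactly at an event time remain in the risk set at
  that time (censoring is processed after events).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence, Union

import numpy as np
import pandas as pd

CENSORED = 0
DEATH_CANCER = 1
DEATH_OTHER = 2
EVENT_CODES = (CENSORED, DEATH_CANCER, DEATH_OTHER)

#: Reserved component label for the Lebesgue (dt) integrator.
TIME_COMPONENT = "time"

_CAUSE_LABELS = {DEATH_CANCER: "cancer", DEATH_OTHER: "other"}

_MERGE_TOL = 1e-9


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: follow-up time (years since diagnosis), event code,
    and the demographics used for population matching."""

    follow_up_time: float
    event_code: int
    age_at_dx: float = 50.0
    sex: str = "F"
    year_of_dx: int = 2005

    def __post_init__(self) -> None:
        if not self.follow_up_time >= 0:
            raise ValueError(f"follow_up_time must be >= 0, got {self.follow_up_time}")
        if self.event_code not in EVENT_CODES:
            raise ValueError(f"event_code must be one of {EVENT_CODES}, got {self.event_code}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")


class Cohort:
    """An ordered collection of subject records, stored columnwise.

    Parameters
    ----------
    time, event:
        Follow-up times (years, nonnegative) and event codes (0/1/2).
    age_at_dx, sex, year_of_dx:
        Demographics; defaulted when not relevant (purely cohort-internal
        parameters never look at them, only Ederer I matching does).
    """

    def __init__(
        self,
        time: Iterable[float],
        event: Iterable[int],
        age_at_dx: Iterable[float] | None = None,
        sex: Iterable[str] | None = None,
        year_of_dx: Iterable[int] | None = None,
    ) -> None:
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        n = self.time.size
        if n < 1:
            raise ValueError("a cohort must contain at least one record")
        if self.event.size != n:
            raise ValueError("time and event must have equal length")
        if np.any(self.time < 0):
            raise ValueError("follow-up times must be nonnegative")
        if not np.all(np.isin(self.event, EVENT_CODES)):
            raise ValueError(f"event codes must be in {EVENT_CODES}")
        self.age_at_dx = (
            np.full(n, 50.0) if age_at_dx is None else np.asarray(age_at_dx, dtype=float)
        )
        self.sex = (
            np.full(n, "F", dtype="<U1") if sex is None else np.asarray(sex, dtype="<U1")
        )
        self.year_of_dx = (
            np.full(n, 2005) if year_of_dx is None else np.asarray(year_of_dx, dtype=int)
        )
        for arr, name in ((self.age_at_dx, "age_at_dx"), (self.sex, "sex"), (self.year_of_dx, "year_of_dx")):
            if arr.size != n:
                raise ValueError(f"{name} must have length {n}")
        if not np.all(np.isin(self.sex, ("F", "M"))):
            raise ValueError("sex must be coded 'F'/'M'")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def records(self) -> list[SubjectRecord]:
        return list(iter(self))

    def __iter__(self) -> Iterator[SubjectRecord]:
        for i in range(self.n):
            yield SubjectRecord(
                follow_up_time=float(self.time[i]),
                event_code=int(self.event[i]),
                age_at_dx=float(self.age_at_dx[i]),
                sex=str(self.sex[i]),
                year_of_dx=int(self.year_of_dx[i]),
            )

    def __len__(self) -> int:
        return self.n

    @classmethod
    def from_records(cls, records: Sequence[SubjectRecord]) -> "Cohort":
        return cls(
            time=[r.follow_up_time for r in records],
            event=[r.event_code for r in records],
            age_at_dx=[r.age_at_dx for r in records],
            sex=[r.sex for r in records],
            year_of_dx=[r.year_of_dx for r in records],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(1, self.n + 1),
                "time": self.time,
                "event": self.event,
                "age_dx": self.age_at_dx,
                "sex": self.sex,
                "year_dx": self.year_of_dx,
            }
        )


def read_cohort(path, delimiter: str = "\t") -> Cohort:
    """Read a cohort from delimited text with header columns
    id, time, event, age_dx, sex, year_dx."""
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    required = {"id", "time", "event", "age_dx", "sex", "year_dx"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file {path} is missing columns: {sorted(missing)}")
    return Cohort(
        time=df["time"].to_numpy(float),
        event=df["event"].to_numpy(int),
        age_at_dx=df["age_dx"].to_numpy(float),
        sex=df["sex"].astype(str).to_numpy(),
        year_of_dx=df["year_dx"].to_numpy(int),
    )


def write_cohort(cohort: Cohort, path, delimiter: str = "\t") -> None:
    cohort.to_frame().to_csv(path, sep=delimiter, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# StepHazard


@dataclass
class StepHazard:
    """A multivariate cumulative-hazard step function with at-risk counts.

    ``increments[k, j]`` is the jump of component ``labels[j]`` at
    ``times[k]``; ``at_risk[k]`` is Y(times[k]), the number of subjects
    still under observation just before the jump.  A component labelled
    ``"time"`` is reserved for the Lebesgue integrator: its increment at
    each grid point is the spacing since the previous grid point.
    """

    times: np.ndarray
    increments: np.ndarray
    at_risk: np.ndarray
    n: int
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.increments = np.atleast_2d(np.asarray(self.increments, dtype=float))
        self.at_risk = np.asarray(self.at_risk, dtype=float)
        g = self.times.size
        if self.increments.shape != (g, len(self.labels)):
            raise ValueError(
                f"increments must have shape ({g}, {len(self.labels)}), got {self.increments.shape}"
            )
        if g and np.any(np.diff(self.times) <= 0):
            raise ValueError("jump times must be strictly increasing")
        if g and self.times[0] <= 0:
            raise ValueError("jump times must be strictly positive")
        if g and np.any(np.diff(self.at_risk) > 1e-9):
            raise ValueError("at-risk counts must be nonincreasing in time")
        for j, lab in enumerate(self.labels):
            if lab == TIME_COMPONENT:
                continue
            col = self.increments[:, j]
            if np.any(col < 0) or np.any(col > 1 + 1e-12):
                raise ValueError(f"hazard increments of component {lab!r} must lie in [0, 1]")

    @property
    def q(self) -> int:
        return len(self.labels)

    @property
    def time_index(self) -> int | None:
        """Index of the reserved "time" component, or None."""
        return self.labels.index(TIME_COMPONENT) if TIME_COMPONENT in self.labels else None

    @property
    def hazard_indices(self) -> tuple[int, ...]:
        return tuple(j for j, lab in enumerate(self.labels) if lab != TIME_COMPONENT)

    def cumulative(self) -> np.ndarray:
        """Cumulative hazard values A^j(times[k]) (right-continuous)."""
        return np.cumsum(self.increments, axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, t in enumerate(self.times):
            for j, lab in enumerate(self.labels):
                rows.append((t, lab, self.increments[k, j], self.at_risk[k]))
        return pd.DataFrame(rows, columns=["time", "component", "increment", "at_risk"])


def write_stephazard(hazard: StepHazard, path, delimiter: str = "\t") -> None:
    """Write a StepHazard in long format (time, component, increment, at_risk)."""
    df = hazard.to_frame()
    df.insert(0, "n", hazard.n)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Nelson--Aalen


CauseSpec = Union[str, int, Sequence[int]]


def nelson_aalen(cohort: Cohort, causes: CauseSpec = "all") -> StepHazard:
    """Nelson--Aalen estimator of (cause-specific) cumulative hazards.

    Parameters
    ----------
    cohort:
        The event data.  Censored records contribute only to the at-risk
        counts Y(s).
    causes:
        ``"all"`` pools the two death causes into a single all-cause
        component; a sequence of event codes (subset of {1, 2}) yields one
        component per cause, on the pooled grid of their event times.

    Returns
    -------
    StepHazard
        A^j(t) = sum_{s <= t} dN^j(s) / Y(s).  A cohort whose records are
        all censored yields a StepHazard with zero jumps.
    """
    if causes == "all":
        groups = [("all", cohort.event > CENSORED)]
    else:
        if isinstance(causes, (int, np.integer)):
            causes = [int(causes)]
        causes = [int(c) for c in causes]
        if not causes or not set(causes) <= {DEATH_CANCER, DEATH_OTHER}:
            raise ValueError(f"causes must be 'all' or a nonempty subset of {{1, 2}}, got {causes}")
        if len(set(causes)) != len(causes):
            raise ValueError("duplicate cause codes")
        groups = [(_CAUSE_LABELS[c], cohort.event == c) for c in causes]

    any_event = np.zeros(cohort.n, dtype=bool)
    for _, mask in groups:
        any_event |= mask
    jump_times = np.unique(cohort.time[any_event])
    if jump_times.size and jump_times[0] <= 0:
        raise ValueError("death at exactly t = 0 is not supported (the time origin is diagnosis)")

    sorted_times = np.sort(cohort.time)
    # Y(s) = #{T_i >= s}; censoring ties at s stay in the risk set.
    at_risk = cohort.n - np.searchsorted(sorted_times, jump_times, side="left")

    increments = np.zeros((jump_times.size, len(groups)))
    for j, (_, mask) in enumerate(groups):
        dn = np.zeros(jump_times.size)
        idx = np.searchsorted(jump_times, cohort.time[mask])
        np.add.at(dn, idx, 1.0)
        increments[:, j] = dn / at_risk

    return StepHazard(
        times=jump_times,
        increments=increments,
        at_risk=at_risk.astype(float),
        n=cohort.n,
        labels=tuple(lab for lab, _ in groups),
    )


def augment_time_component(
    hazard: StepHazard, mesh_step: float, horizon: float | None = None
) -> StepHazard:
    """Add a reserved "time" component on the union of the event grid and a
    regular mesh.

    The time component's increment at each grid point equals the elapsed
    time since the previous grid point (so its cumulative sum telescopes to
    t exactly for any mesh); hazard components keep their original jumps
    and are zero at inserted mesh points.

    Parameters
    ----------
    mesh_step:
        Mesh spacing in years (> 0).
    horizon:
        End of the grid; defaults to the last jump time.  Event times
        beyond the horizon are dropped.

    Notes
    -----
    At inserted mesh points the at-risk count is carried from the next
    event time (it is exact only at the original jump times; nothing in
    the estimation machinery reads it between events).
    """
    if mesh_step <= 0:
        raise ValueError(f"mesh_step must be > 0, got {mesh_step}")
    if TIME_COMPONENT in hazard.labels:
        raise ValueError("hazard already has a time component")
    last = float(hazard.times[-1]) if hazard.times.size else 0.0
    if horizon is None:
        horizon = last
    if horizon <= 0:
        raise ValueError("horizon must be positive (pass horizon= explicitly for an event-free hazard)")

    k = int(np.floor(horizon / mesh_step + 1e-9))
    mesh = np.arange(1, k + 1) * mesh_step
    if mesh.size == 0 or mesh[-1] < horizon - _MERGE_TOL:
        mesh = np.append(mesh, horizon)
    keep = hazard.times <= horizon + _MERGE_TOL
    grid = np.union1d(hazard.times[keep], mesh)
    # merge float-coincident points (an event time vs. a mesh multiple)
    if grid.size > 1:
        distinct = np.concatenate(([True], np.diff(grid) > _MERGE_TOL))
        grid = grid[distinct]

    increments = np.zeros((grid.size, hazard.q + 1))
    increments[:, -1] = np.diff(grid, prepend=0.0)
    src = np.flatnonzero(keep)
    pos = np.searchsorted(grid, hazard.times[keep])
    pos = np.clip(pos, 0, grid.size - 1)
    # snap to the nearest grid point within the merge tolerance
    left = np.clip(pos - 1, 0, grid.size - 1)
    use_left = np.abs(grid[left] - hazard.times[keep]) < np.abs(grid[pos] - hazard.times[keep])
    pos = np.where(use_left, left, pos)
    increments[pos, : hazard.q] = hazard.increments[src]

    if hazard.times.size:
        nxt = np.searchsorted(hazard.times, grid, side="left")
        at_risk = np.where(
            nxt < hazard.times.size,
            hazard.at_risk[np.clip(nxt, 0, hazard.times.size - 1)],
            hazard.at_risk[-1],
        )
    else:
        at_risk = np.full(grid.size, float(hazard.n))

    return StepHazard(
        times=grid,
        increments=increments,
        at_risk=at_risk.astype(float),
        n=hazard.n,
        labels=hazard.labels + (TIME_COMPONENT,),
    )
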