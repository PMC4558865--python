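"""Bounded random-walk model of a one-dimensional environmental condition.

The environment is summarised by a single dimensionless condition
``x(t) ∈ [-1, +1]`` (think pH, temperature, irradiance — any bounded abiotic
axis).  From one time step to the next the condition performs a bounded
random walk::

    x(0) = 0,    x(t+1) = x(t) + RND[-T, T],    |x(t+1)| <= 1

where ``RND[-T, T]`` is a uniform draw and ``T`` (the *turbulence*) is the
half-width of the per-step increment, ``0 <= T <= 0.5``.  ``T = 0`` is a
perfectly constant environment; larger ``T`` means a less predictable one.

The boundary constraint ``|x| <= 1`` can be enforced in three ways
(``boundary_mode``): ``"resample"`` (default) redraws the increment until the
constraint holds, which keeps the walk a proper bounded walk without
probability atoms at the boundaries; ``"clip"`` projects onto the interval;
``"reflect"`` folds the overshoot back inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EnvironmentState",
    "TurbulenceSchedule",
    "step_environment",
    "turbulence_at",
    "simulate_trajectory",
    "BOUNDARY_MODES",
]

T_MAX = 0.5
BOUNDARY_MODES = ("resample", "clip", "reflect")


@dataclass(frozen=True)
class EnvironmentState:
    """Current environmental condition ``x`` at integer time ``t``."""

    x: float = 0.0
    t: int = 0

    def __post_init__(self) -> None:
        if abs(self.x) > 1.0:
            raise ValueError(f"environmental condition out of range: x={self.x}")
        if self.t < 0:
            raise ValueError(f"negative time step: t={self.t}")


@dataclass(frozen=True)
class TurbulenceSchedule:
    """Piecewise-constant turbulence: ordered ``(start_step, T)`` segments.

    The first segment must start at step 0, start steps must be strictly
    increasing and every ``T`` must lie in ``[0, 0.5]``.  A plain number is
    accepted wherever a schedule is expected and means a single constant
    segment.
    """

    segments: tuple[tuple[int, float], ...] = field(default=((0, 0.0),))

    def __post_init__(self) -> None:
        segs = tuple((int(s), float(T)) for s, T in self.segments)
        if not segs:
            raise ValueError("schedule needs at least one segment")
        if segs[0][0] != 0:
            raise ValueError("first segment must start at step 0")
        starts = [s for s, _ in segs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start steps must be strictly increasing")
        for _, T in segs:
            _check_turbulence(T)
        object.__setattr__(self, "segments", segs)

    @classmethod
    def constant(cls, T: float) -> "TurbulenceSchedule":
        return cls(((0, float(T)),))

    @classmethod
    def from_value(
        cls, value: "float | TurbulenceSchedule | Iterable"
    ) -> "TurbulenceSchedule":
        """Coerce a scalar, a schedule, or an iterable of pairs/dicts."""
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, float)):
            return cls.constant(float(value))
        segs = []
        for item in value:
            if isinstance(item, dict):
                segs.append((int(item["start_step"]), float(item["T"])))
            else:
                s, T = item
                segs.append((int(s), float(T)))
        return cls(tuple(segs))

    def at(self, t: int) -> float:
        return turbulence_at(self, t)

    def to_jsonable(self) -> list[dict]:
        return [{"start_step": s, "T": T} for s, T in self.segments]


def _check_turbulence(T: float) -> None:
    if not (0.0 <= T <= T_MAX):
        raise ValueError(f"turbulence T must lie in [0, {T_MAX}], got {T}")


def turbulence_at(schedule: TurbulenceSchedule, t: int) -> float:
    """Turbulence in force at step ``t``: the T of the last segment with
    ``start_step <= t`` (segment starts are inclusive)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    T = schedule.segments[0][1]
    for start, seg_T in schedule.segments:
        if start <= t:
            T = seg_T
        else:
            break
    return T


def _draw_increment(
    x: float, T: float, rng: np.random.Generator, boundary_mode: str
) -> float:
    d = rng.uniform(-T, T)
    new = x + d
    if abs(new) <= 1.0:
        return new
    if boundary_mode == "resample":
        # Redraw until the walk stays inside [-1, 1]; T <= 0.5 guarantees a
        # positive acceptance probability from any admissible x.
        while abs(new) > 1.0:
            new = x + rng.uniform(-T, T)
        return new
    if boundary_mode == "clip":
        return float(np.clip(new, -1.0, 1.0))
    if boundary_mode == "reflect":
        if new > 1.0:
            new = 2.0 - new
        elif new < -1.0:
            new = -2.0 - new
        return float(np.clip(new, -1.0, 1.0))
    raise ValueError(f"unknown boundary_mode {boundary_mode!r}")


def step_environment(
    state: EnvironmentState,
    T: float,
    rng: np.random.Generator,
    boundary_mode: str = "resample",
) -> EnvironmentState:
    """Advance the bounded random walk by one step.

    Parameters
    ----------
    state : current ``EnvironmentState`` with ``|x| <= 1``.
    T : turbulence level in ``[0, 0.5]``; half-width of the uniform increment.
    rng : numpy random generator (the environment stream).
    boundary_mode : one of ``"resample"``, ``"clip"``, ``"reflect"``.

    Returns the new state with ``t`` incremented and ``|x| <= 1``.
    """
    _check_turbulence(T)
    if boundary_mode not in BOUNDARY_MODES:
        raise ValueError(f"unknown boundary_mode {boundary_mode!r}")
    if T == 0.0:
        return replace(state, t=state.t + 1)
    new_x = _draw_increment(state.x, T, rng, boundary_mode)
    return EnvironmentState(x=new_x, t=state.t + 1)


def simulate_trajectory(
    schedule: "float | TurbulenceSchedule",
    steps: int,
    rng: np.random.Generator,
    boundary_mode: str = "resample",
) -> np.ndarray:
    """Trajectory ``x(0..steps)`` (length ``steps + 1``, ``x(0) = 0``)."""
    sched = TurbulenceSchedule.from_value(schedule)
    xs = np.empty(steps + 1)
    state = EnvironmentState()
    xs[0] = state.x
    for t in range(steps):
        state = step_environment(state, sched.at(t), rng, boundary_mode)
        xs[t + 1] = state.x
    return xs
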