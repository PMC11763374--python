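"""Closed-form target-approximation dynamics for a single interval.

A channel variable approaches a linear target ``b + m*t`` under a
critically damped third-order linear system with rate constant ``lam``
(triple pole at ``-lam``).  The solution with full state matching at the
interval onset is

    x(t) = (c1 + c2*t + c3*t**2) * exp(-lam*t) + b + m*t

with coefficients fixed by the onset state ``(x0, v0, a0)``:

    c1 = x0 - b
    c2 = v0 + lam*c1 - m
    c3 = (a0 + 2*lam*c2 - lam**2*c1) / 2

The target line is the exact asymptote: as ``t`` grows, position tends to
``b + m*t``, velocity to ``m``, and acceleration to ``0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, InvalidInputError, OracleFailureError

__all__ = [
    "TargetSpec",
    "DynamicState",
    "CoefficientSet",
    "TrajectorySegment",
    "solve_coefficients",
    "evaluate_state",
    "evaluate_positions",
    "synthesize_interval",
    "reference_integrator",
    "remaining_fraction",
]

#: Order of the linear system (triple pole).  A single constant so that a
#: higher-order variant could be explored, but nothing else in the package
#: depends on changing it.
SYSTEM_ORDER = 3


@dataclass(frozen=True)
class TargetSpec:
    """An underlying linear target: line (slope, height), strength, duration.

    Parameters
    ----------
    slope
        Target slope ``m`` in units/s.  ``0`` encodes a static target,
        nonzero a dynamic one.
    height
        Target height ``b`` in channel units at interval-local time 0.
    strength
        Rate constant ``lam`` in 1/s; must be positive.
    duration
        Interval length ``d`` in s; must be positive.
    """

    slope: float
    height: float
    strength: float
    duration: float

    def __post_init__(self):
        vals = (self.slope, self.height, self.strength, self.duration)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidInputError(f"non-finite target parameters: {vals}")
        if self.strength <= 0:
            raise DomainError(f"strength must be > 0, got {self.strength}")
        if self.duration <= 0:
            raise DomainError(f"duration must be > 0, got {self.duration}")

    @property
    def is_dynamic(self) -> bool:
        return self.slope != 0.0

    def line(self, t):
        """Value of the target line at interval-local time ``t``."""
        return self.height + self.slope * np.asarray(t, dtype=float)

    def with_duration(self, duration: float) -> "TargetSpec":
        return TargetSpec(self.slope, self.height, self.strength, duration)


@dataclass(frozen=True)
class DynamicState:
    """Instantaneous (position, velocity, acceleration) at a given time."""

    position: float
    velocity: float
    acceleration: float
    at_time: float = 0.0

    def __post_init__(self):
        vals = (self.position, self.velocity, self.acceleration, self.at_time)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidInputError(f"non-finite dynamic state: {vals}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.position, self.velocity, self.acceleration)


@dataclass(frozen=True)
class CoefficientSet:
    """Polynomial coefficients of the transient term, fixed by onset state."""

    c1: float
    c2: float
    c3: float


@dataclass(frozen=True)
class TrajectorySegment:
    """Sampled interval plus the analytic state at its end."""

    times: np.ndarray
    values: np.ndarray
    final_state: DynamicState
    target: TargetSpec = field(repr=False, default=None)

    def __post_init__(self):
        if len(self.times) != len(self.values):
            raise InvalidInputError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("times must be strictly increasing")


def solve_coefficients(target: TargetSpec, init: DynamicState) -> CoefficientSet:
    """Coefficients that make the closed form match ``init`` exactly at t=0."""
    lam = target.strength
    c1 = init.position - target.height
    c2 = init.velocity + lam * c1 - target.slope
    c3 = (init.acceleration + 2.0 * lam * c2 - lam**2 * c1) / 2.0
    return CoefficientSet(c1, c2, c3)


def evaluate_state(target: TargetSpec, coeffs: CoefficientSet, t: float) -> DynamicState:
    """Analytic (position, velocity, acceleration) at interval-local time ``t`` >= 0."""
    if t < 0:
        raise DomainError(f"local time must be >= 0, got {t}")
    lam = target.strength
    c1, c2, c3 = coeffs.c1, coeffs.c2, coeffs.c3
    e = math.exp(-lam * t)
    p = c1 + c2 * t + c3 * t * t
    dp = c2 + 2.0 * c3 * t
    ddp = 2.0 * c3
    x = p * e + target.height + target.slope * t
    v = (dp - lam * p) * e + target.slope
    a = (ddp - 2.0 * lam * dp + lam * lam * p) * e
    return DynamicState(x, v, a, at_time=t)


def evaluate_positions(target: TargetSpec, coeffs: CoefficientSet, t) -> np.ndarray:
    """Vectorized position-only evaluation at local times ``t`` (>= 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("local times must be >= 0")
    lam = target.strength
    p = coeffs.c1 + coeffs.c2 * t + coeffs.c3 * t * t
    return p * np.exp(-lam * t) + target.height + target.slope * t


def synthesize_interval(target: TargetSpec, init: DynamicState, rate: float) -> TrajectorySegment:
    """Sample one interval at ``t = 0, 1/rate, ...`` up to its duration.

    The final state is evaluated analytically at ``duration`` (not at the
    last grid point), so state transfer across intervals is independent of
    the sample rate.
    """
    if rate <= 0:
        raise DomainError(f"rate must be > 0, got {rate}")
    if target.duration < 1.0 / rate:
        raise DomainError(
            f"duration {target.duration} shorter than one sample period {1.0 / rate}"
        )
    coeffs = solve_coefficients(target, init)
    n = int(math.floor(target.duration * rate + 1e-9)) + 1
    times = np.arange(n) / rate
    # keep the grid inside the interval
    times = times[times <= target.duration + 1e-12]
    values = evaluate_positions(target, coeffs, times)
    final = evaluate_state(target, coeffs, target.duration)
    return TrajectorySegment(times=times, values=values, final_state=final, target=target)


def reference_integrator(target: TargetSpec, init: DynamicState, t_grid) -> np.ndarray:
    """Numerically integrate the third-order ODE; test oracle only.

    Integrates ``x''' = -3*lam*x'' - 3*lam^2*(x' - m) - lam^3*(x - (b + m*t))``
    from ``init`` with tight tolerances and returns positions on ``t_grid``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or (len(t_grid) > 1 and not np.all(np.diff(t_grid) > 0)):
        raise InvalidInputError("t_grid must be a 1-D increasing array")
    lam, m, b = target.strength, target.slope, target.height

    def rhs(t, y):
        x, v, a = y
        jerk = -3.0 * lam * a - 3.0 * lam**2 * (v - m) - lam**3 * (x - (b + m * t))
        return [v, a, jerk]

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]) if len(t_grid) > 1 else (t_grid[0], t_grid[0] + 1e-9),
        list(init.as_tuple()),
        t_eval=t_grid,
        method="DOP853",
        rtol=1e-11,
        atol=1e-12,
        max_step=0.01,
    )
    if not sol.success:
        raise OracleFailureError(f"reference integrator failed: {sol.message}")
    return sol.y[0]


def remaining_fraction(u) -> np.ndarray:
    """Fraction of an initial offset left after ``u = lam*t`` with zero
    initial velocity/acceleration relative to the target line:
    ``g(u) = (1 + u + u**2/2) * exp(-u)``.  Decreasing in ``u``."""
    u = np.asarray(u, dtype=float)
    return (1.0 + u + 0.5 * u * u) * np.exp(-u)
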