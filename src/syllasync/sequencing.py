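"""Arrange several targets on one channel: strict sequential synthesis with
state transfer, truncation of an interval, and blending via an inserted
averaged target."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, InvalidInputError
from .qta import (
    DynamicState,
    TargetSpec,
    evaluate_positions,
    evaluate_state,
    solve_coefficients,
)

__all__ = [
    "Channel",
    "TargetSequence",
    "Trajectory",
    "TrajectorySet",
    "synthesize_sequence",
    "apply_truncation",
    "apply_blending",
    "on_target_state",
]


@dataclass(frozen=True)
class Channel:
    """A named channel with a declared unit (units are metadata, never converted)."""

    name: str
    unit: str = ""


@dataclass(frozen=True)
class TargetSequence:
    """Ordered targets tiling ``[start_time, start_time + sum(durations)]``
    on one channel, contiguous without overlap."""

    targets: tuple[TargetSpec, ...]
    start_time: float = 0.0
    channel: Channel = Channel("x")

    def __post_init__(self):
        object.__setattr__(self, "targets", tuple(self.targets))
        if not self.targets:
            raise InvalidInputError("a target sequence needs at least one target")

    @property
    def durations(self) -> np.ndarray:
        return np.array([t.duration for t in self.targets])

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    @property
    def boundary_times(self) -> np.ndarray:
        """Global times of all interval edges, including both ends."""
        return self.start_time + np.concatenate(([0.0], np.cumsum(self.durations)))


@dataclass(frozen=True)
class Trajectory:
    """A sampled single-channel time series on a global clock."""

    times: np.ndarray
    values: np.ndarray
    channel: Channel = Channel("x")
    boundary_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape:
            raise InvalidInputError("times and values must have the same shape")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "boundary_times", np.asarray(self.boundary_times, dtype=float))

    @property
    def rate(self) -> float:
        if len(self.times) < 2:
            raise InvalidInputError("rate undefined for fewer than two samples")
        return 1.0 / float(np.median(np.diff(self.times)))


@dataclass(frozen=True)
class TrajectorySet:
    """Multi-channel trajectories sharing one clock."""

    trajectories: dict[str, Trajectory]
    rate: float

    def __post_init__(self):
        if not self.trajectories:
            raise InvalidInputError("empty trajectory set")

    def __getitem__(self, name: str) -> Trajectory:
        return self.trajectories[name]

    @property
    def channels(self) -> list[str]:
        return list(self.trajectories)


def on_target_state(target: TargetSpec, at_time: float = 0.0) -> DynamicState:
    """The already-attained state on a target's line at its local time 0."""
    return DynamicState(target.height, target.slope, 0.0, at_time=at_time)


def synthesize_sequence(
    seq: TargetSequence, init: DynamicState, rate: float
) -> Trajectory:
    """Synthesize a sequence of targets with analytic state transfer.

    Samples lie on a single uniform grid anchored at ``seq.start_time``.
    Each boundary sample belongs to the following interval (half-open
    convention), and each interval starts from the previous interval's
    analytic final state, so the output is C2-continuous at boundaries.
    """
    if rate <= 0:
        raise DomainError(f"rate must be > 0, got {rate}")
    edges = seq.boundary_times
    n_total = int(np.floor(seq.total_duration * rate + 1e-9))
    times = seq.start_time + np.arange(n_total + 1) / rate

    values = np.empty_like(times)
    state = init
    for k, target in enumerate(seq.targets):
        lo, hi = edges[k], edges[k + 1]
        if k < len(seq.targets) - 1:
            sel = (times >= lo - 1e-12) & (times < hi - 1e-12)
        else:  # last interval also owns the final edge sample
            sel = (times >= lo - 1e-12) & (times <= hi + 1e-12)
        coeffs = solve_coefficients(target, state)
        local = np.clip(times[sel] - lo, 0.0, None)
        values[sel] = evaluate_positions(target, coeffs, local)
        state = evaluate_state(target, coeffs, target.duration)
    return Trajectory(
        times=times, values=values, channel=seq.channel, boundary_times=edges[1:-1]
    )


def apply_truncation(seq: TargetSequence, index: int, delta: float) -> TargetSequence:
    """Shorten interval ``index`` by ``delta`` seconds; later targets shift left.

    With ``delta == 0`` the sequence is returned unchanged.  The synthesized
    trajectory on the surviving part of interval ``index`` is identical to
    the untruncated one restricted to that range (prefix property), because
    the closed form on the interval does not depend on its duration.
    """
    if not 0 <= index < len(seq.targets):
        raise InvalidInputError(f"index {index} out of range")
    d = seq.targets[index].duration
    if not 0 <= delta < d:
        raise InvalidInputError(f"delta must be in [0, {d}), got {delta}")
    if delta == 0:
        return seq
    targets = list(seq.targets)
    targets[index] = targets[index].with_duration(d - delta)
    return replace(seq, targets=tuple(targets))


def apply_blending(seq: TargetSequence, index: int, overlap: float) -> TargetSequence:
    """Insert an averaged target of duration ``overlap`` between intervals
    ``index`` and ``index + 1``.

    The blend window occupies the first ``overlap`` seconds of interval
    ``index + 1``, which is shortened accordingly (interval ``index`` is
    untouched and the total duration is unchanged).  Blended slope and
    strength are arithmetic means of the neighbours'; heights are averaged
    after re-anchoring both target lines to the blend window's local time
    origin, so the blend of two lines is their pointwise mean line.  The
    shortened second target keeps its global line (its height is re-anchored
    to the window end).
    """
    if not 0 <= index < len(seq.targets) - 1:
        raise InvalidInputError(f"index {index} has no following interval")
    first, second = seq.targets[index], seq.targets[index + 1]
    if not 0 <= overlap < second.duration:
        raise InvalidInputError(
            f"overlap must be in [0, {second.duration}), got {overlap}"
        )
    if overlap == 0:
        return seq
    b_first_at_window = first.height + first.slope * first.duration
    blended = TargetSpec(
        slope=0.5 * (first.slope + second.slope),
        height=0.5 * (b_first_at_window + second.height),
        strength=0.5 * (first.strength + second.strength),
        duration=overlap,
    )
    shortened = TargetSpec(
        slope=second.slope,
        height=second.height + second.slope * overlap,
        strength=second.strength,
        duration=second.duration - overlap,
    )
    targets = (
        seq.targets[: index + 1] + (blended, shortened) + seq.targets[index + 2 :]
    )
    return replace(seq, targets=targets)
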