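"""Compile syllable specifications into per-dimension target sequences under
edge synchronization, with dimension-specific sequential target approximation
(DSSTA) and sequential coda placement; synthesize multi-channel trajectories;
export the synchronization-based segmentation; derive locus-equation
regressions from synthesized CV families.

Edge synchronization means: every dimension's first target of a syllable
starts at the syllable onset.  On a dimension constrained by an onset
consonant, the consonant target occupies an initial sub-interval before the
vowel target; on dimensions it leaves unconstrained, the vowel target starts
at the syllable onset itself.  Coda targets follow the nucleus without
overlap.  Tone and phonation targets span the whole syllable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DimensionConflictError, InvalidInputError
from .qta import DynamicState, TargetSpec, remaining_fraction, solve_coefficients, evaluate_positions
from .sequencing import (
    Channel,
    TargetSequence,
    Trajectory,
    TrajectorySet,
    on_target_state,
    synthesize_sequence,
)

__all__ = [
    "Dimension",
    "DimensionInventory",
    "TargetParams",
    "GestureSpec",
    "SyllableSpec",
    "Interval",
    "CompiledScore",
    "compile_syllable",
    "compile_utterance",
    "synthesize_score",
    "export_segmentation",
    "compute_locus_equation",
    "locus_equation_slope",
]

#: Default duration weights per role class; normalized per dimension over the
#: gestures that actually constrain it.  The onset-hold share is a free
#: parameter of the model, not an empirical constant.
DEFAULT_FRACTIONS = {"onset": 0.3, "nucleus": 0.7, "coda": 0.3}

LARYNGEAL_ROLES = frozenset({"tone-T", "phonation-Ph"})
ORAL_ROLE_CLASS = {"onset-C": "onset", "nucleus-V": "nucleus", "coda-C": "coda"}


@dataclass(frozen=True)
class Dimension:
    """A controllable articulatory/acoustic dimension, e.g. f0, F2, lip-aperture."""

    name: str
    unit: str = ""
    tier: str = "V"  # one of C, V, T, Ph

    def __post_init__(self):
        if self.tier not in {"C", "V", "T", "Ph"}:
            raise InvalidInputError(f"unknown tier {self.tier!r} for {self.name!r}")


class DimensionInventory:
    """Unique-named set of dimensions."""

    def __init__(self, dims):
        self._dims: dict[str, Dimension] = {}
        for d in dims:
            if d.name in self._dims:
                raise InvalidInputError(f"duplicate dimension name {d.name!r}")
            self._dims[d.name] = d

    def __getitem__(self, name: str) -> Dimension:
        return self._dims[name]

    def __contains__(self, name: str) -> bool:
        return name in self._dims

    def __iter__(self):
        return iter(self._dims.values())

    @property
    def names(self) -> list[str]:
        return list(self._dims)


@dataclass(frozen=True)
class TargetParams:
    """(slope, height, strength) of a target; duration is set by the compiler."""

    slope: float
    height: float
    strength: float

    def with_duration(self, duration: float) -> TargetSpec:
        return TargetSpec(self.slope, self.height, self.strength, duration)


@dataclass(frozen=True)
class GestureSpec:
    """One gesture: its role, the targets it carries per dimension, and the
    subset of dimensions it actually demands (its coarticulation-resistance
    footprint)."""

    role: str  # onset-C | nucleus-V | coda-C | tone-T | phonation-Ph
    targets: dict[str, TargetParams]
    constrained: frozenset[str] = None
    label: str = ""

    def __post_init__(self):
        if self.role not in set(ORAL_ROLE_CLASS) | LARYNGEAL_ROLES:
            raise InvalidInputError(f"unknown gesture role {self.role!r}")
        constrained = self.constrained
        if constrained is None:
            constrained = frozenset(self.targets)
        else:
            constrained = frozenset(constrained)
        if not constrained <= set(self.targets):
            missing = constrained - set(self.targets)
            raise InvalidInputError(
                f"constrained dimensions without targets: {sorted(missing)}"
            )
        object.__setattr__(self, "constrained", constrained)


@dataclass(frozen=True)
class SyllableSpec:
    """A syllable: ordered onset consonants, nucleus elements (glides, vowel,
    diphthong elements), optional coda, tone, optional phonation, duration,
    and duration-fraction weights for the sequential split on shared
    dimensions."""

    onset: tuple[GestureSpec, ...] = ()
    nucleus: tuple[GestureSpec, ...] = ()
    coda: GestureSpec | None = None
    tone: GestureSpec | None = None
    phonation: GestureSpec | None = None
    duration: float = 0.2
    fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "onset", tuple(self.onset))
        object.__setattr__(self, "nucleus", tuple(self.nucleus))
        if self.duration <= 0:
            raise InvalidInputError(f"syllable duration must be > 0, got {self.duration}")
        if not self.nucleus and not self.onset:
            raise InvalidInputError("a syllable needs at least one gesture")
        for key, val in self.fractions.items():
            if key not in DEFAULT_FRACTIONS or val <= 0:
                raise InvalidInputError(f"bad duration fraction {key}={val}")

    @property
    def gestures(self) -> list[GestureSpec]:
        out = list(self.onset) + list(self.nucleus)
        if self.coda is not None:
            out.append(self.coda)
        if self.tone is not None:
            out.append(self.tone)
        if self.phonation is not None:
            out.append(self.phonation)
        return out


@dataclass(frozen=True)
class Interval:
    label: str
    start: float
    end: float

    def __post_init__(self):
        if self.end < self.start:
            raise InvalidInputError(f"interval end before start: {self}")


@dataclass
class CompiledScore:
    """Per-dimension tiled target sequences plus labelled intervals."""

    sequences: dict[str, TargetSequence]
    syllable_intervals: list[Interval]
    segment_intervals: dict[str, list[Interval]]
    inventory: DimensionInventory

    @property
    def total_duration(self) -> float:
        return self.syllable_intervals[-1].end if self.syllable_intervals else 0.0


def _dimension_plan(spec: SyllableSpec, dims: list[str]):
    """For each dimension, the ordered (gesture, duration) tiling of the
    syllable, honouring DSSTA.  Returns {dim: [(gesture, duration), ...]}."""
    plan: dict[str, list[tuple[GestureSpec, float]]] = {}
    for dim in dims:
        laryngeal = [
            g
            for g in [spec.tone, spec.phonation]
            if g is not None and dim in g.constrained
        ]
        if len(laryngeal) > 1:
            raise DimensionConflictError(dim)
        oral = [
            g
            for g in list(spec.onset) + list(spec.nucleus) + ([spec.coda] if spec.coda else [])
            if dim in g.constrained
        ]
        if laryngeal and oral:
            raise DimensionConflictError(
                dim, f"dimension {dim!r} demanded by both laryngeal and oral gestures"
            )
        if laryngeal:
            plan[dim] = [(laryngeal[0], spec.duration)]
            continue
        if not oral:
            raise InvalidInputError(
                f"syllable {spec.label!r} leaves dimension {dim!r} targetless"
            )
        # normalize role-class weights over the constraining gestures,
        # splitting each class weight equally within the class
        classes = [ORAL_ROLE_CLASS[g.role] for g in oral]
        counts = {c: classes.count(c) for c in set(classes)}
        weights = np.array(
            [spec.fractions.get(c, DEFAULT_FRACTIONS[c]) / counts[c] for c in classes]
        )
        durations = spec.duration * weights / weights.sum()
        plan[dim] = list(zip(oral, durations))
    return plan


def compile_syllable(
    spec: SyllableSpec, inventory: DimensionInventory, onset_time: float = 0.0
) -> CompiledScore:
    """Compile one syllable starting at ``onset_time``."""
    return compile_utterance([spec], inventory, start_time=onset_time)


def compile_utterance(
    specs, inventory: DimensionInventory, start_time: float = 0.0
) -> CompiledScore:
    """Compile a syllable sequence; syllable k+1's onset is syllable k's offset.

    Every dimension used anywhere must receive a target in every syllable
    (no targetless intervals), so per-dimension sequences tile the utterance.
    """
    specs = list(specs)
    if not specs:
        raise InvalidInputError("utterance needs at least one syllable")
    dims = []
    for spec in specs:
        for g in spec.gestures:
            for name in g.targets:
                if name not in inventory:
                    raise InvalidInputError(f"unknown dimension {name!r}")
                if name not in dims:
                    dims.append(name)

    per_dim_targets: dict[str, list[TargetSpec]] = {d: [] for d in dims}
    per_dim_segments: dict[str, list[Interval]] = {d: [] for d in dims}
    syllable_intervals: list[Interval] = []

    t = start_time
    for i, spec in enumerate(specs):
        plan = _dimension_plan(spec, dims)
        for dim in dims:
            pos = t
            for gesture, dur in plan[dim]:
                per_dim_targets[dim].append(gesture.targets[dim].with_duration(dur))
                per_dim_segments[dim].append(
                    Interval(gesture.label or gesture.role, pos, pos + dur)
                )
                pos += dur
        syllable_intervals.append(
            Interval(spec.label or f"syl{i + 1}", t, t + spec.duration)
        )
        t += spec.duration

    sequences = {
        d: TargetSequence(
            targets=tuple(per_dim_targets[d]),
            start_time=start_time,
            channel=Channel(d, inventory[d].unit),
        )
        for d in dims
    }
    return CompiledScore(
        sequences=sequences,
        syllable_intervals=syllable_intervals,
        segment_intervals=per_dim_segments,
        inventory=inventory,
    )


def synthesize_score(
    score: CompiledScore,
    init: dict[str, DynamicState] | None = None,
    rate: float = 200.0,
) -> TrajectorySet:
    """One trajectory per dimension, all on the same clock.

    Missing initial states default to the first target's line
    (already-attained: position = height, velocity = slope, acceleration 0).
    """
    init = dict(init or {})
    trajectories: dict[str, Trajectory] = {}
    for name, seq in score.sequences.items():
        state = init.pop(name, None) or on_target_state(seq.targets[0])
        trajectories[name] = synthesize_sequence(seq, state, rate)
    if init:
        raise InvalidInputError(f"initial states for unknown dimensions: {sorted(init)}")
    return TrajectorySet(trajectories=trajectories, rate=rate)


def export_segmentation(
    score: CompiledScore, conventional_fractions: dict[str, list[tuple[str, float]]] | None = None
) -> dict[str, list[Interval]]:
    """Annotation tiers of the synchronization-based segmentation.

    Returns a ``syllable`` tier, one tier per dimension (each segment's onset
    is its target-approximation onset, its offset the approximation end),
    and optionally a conventional-comparison tier computed from user-supplied
    per-syllable landmark fractions ``{syllable label: [(label, fraction)...]}``
    (fractions of syllable duration, summing to 1).
    """
    tiers: dict[str, list[Interval]] = {"syllable": list(score.syllable_intervals)}
    for dim, intervals in score.segment_intervals.items():
        tiers[dim] = list(intervals)
    if conventional_fractions is not None:
        conventional: list[Interval] = []
        for syl in score.syllable_intervals:
            marks = conventional_fractions.get(syl.label)
            if marks is None:
                continue
            total = sum(f for _, f in marks)
            if abs(total - 1.0) > 1e-9:
                raise InvalidInputError(
                    f"conventional fractions for {syl.label!r} sum to {total}, not 1"
                )
            pos = syl.start
            dur = syl.end - syl.start
            for lab, frac in marks:
                conventional.append(Interval(lab, pos, pos + frac * dur))
                pos += frac * dur
        tiers["conventional"] = conventional
    return tiers


def locus_equation_slope(strength: float, t_onset: float) -> float:
    """Model-predicted locus-equation slope ``1 - g(lam * t_onset)`` for a CV
    family approached from rest at the consonant state."""
    return float(1.0 - remaining_fraction(strength * t_onset))


def compute_locus_equation(
    consonant_position: float,
    vowel_heights,
    strength: float,
    t_onset: float,
    vowel_duration: float | None = None,
    rate: float = 1000.0,
):
    """Regress F2 at voice onset on F2 at vowel attainment across a CV family.

    The family shares one consonant (common onset state ``consonant_position``
    with zero velocity/acceleration and common ``strength``) while the vowel
    height varies.  Under the model the relation is exactly linear with slope
    ``1 - g(strength * t_onset)`` and intercept ``g(strength * t_onset) *
    consonant_position``.

    Returns ``(slope, intercept, r_squared)``.
    """
    vowel_heights = np.asarray(vowel_heights, dtype=float)
    if vowel_heights.size < 3:
        raise InvalidInputError("need at least 3 vowels for a locus regression")
    if t_onset <= 0:
        raise InvalidInputError("t_onset must be > 0")
    if vowel_duration is None:
        # long enough that attainment is numerically on the target
        vowel_duration = max(2.0 * t_onset, 30.0 / strength)
    f2_onset = np.empty_like(vowel_heights)
    f2_attained = np.empty_like(vowel_heights)
    init = DynamicState(consonant_position, 0.0, 0.0)
    for i, b_v in enumerate(vowel_heights):
        target = TargetSpec(0.0, float(b_v), strength, vowel_duration)
        coeffs = solve_coefficients(target, init)
        f2_onset[i], f2_attained[i] = evaluate_positions(
            target, coeffs, [t_onset, vowel_duration]
        )
    fit = stats.linregress(f2_attained, f2_onset)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
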