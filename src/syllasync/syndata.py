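"""Synthetic-data generators with known ground truth.

Everything the analysis modules consume can be generated here: noisy f0
contours of tone sequences, minimal triplets of formant-like trajectories
with a constructed divergence point at the second syllable's onset, and tone
corpora for alignment-learning experiments.  All generators are pure
functions of (configuration, seed); noise is additive i.i.d. Gaussian on
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidInputError
from .qta import DynamicState, TargetSpec
from .sequencing import (
    Channel,
    TargetSequence,
    Trajectory,
    on_target_state,
    synthesize_sequence,
)
from .divergence import RepetitionSet

__all__ = [
    "NoiseConfig",
    "DEFAULT_TONES",
    "generate_contour",
    "generate_repetitions",
    "generate_minimal_triplet",
    "generate_tone_corpus",
]

#: Illustrative static/dynamic tone targets (st rel. a declared reference):
#: High, Rising, Low, Falling, plus a weak-strength mid target N emulating a
#: neutral tone.  Chosen by the implementer; not empirical values.
DEFAULT_TONES: dict[str, tuple[float, float, float]] = {
    "H": (0.0, 4.0, 30.0),
    "R": (40.0, -2.0, 30.0),
    "L": (0.0, -4.0, 30.0),
    "F": (-60.0, 6.0, 35.0),
    "N": (0.0, 1.0, 8.0),
}


@dataclass(frozen=True)
class NoiseConfig:
    """Additive Gaussian sample noise plus per-repetition duration jitter."""

    sigma: float = 0.0
    duration_jitter_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise InvalidInputError("sigma must be >= 0")
        if self.duration_jitter_cv < 0:
            raise InvalidInputError("duration jitter cv must be >= 0")


def _jitter_sequence(seq: TargetSequence, cv: float, rng: np.random.Generator) -> TargetSequence:
    if cv == 0:
        return seq
    factors = np.clip(rng.normal(1.0, cv, size=len(seq.targets)), 0.2, None)
    targets = tuple(
        t.with_duration(t.duration * f) for t, f in zip(seq.targets, factors)
    )
    return replace(seq, targets=targets)


def generate_contour(
    seq: TargetSequence,
    noise: NoiseConfig = NoiseConfig(),
    rate: float = 200.0,
    init: DynamicState | None = None,
) -> tuple[Trajectory, dict]:
    """Synthesize a sequence, jitter durations, add noise; return the
    trajectory together with a ground-truth record."""
    rng = np.random.default_rng(noise.seed)
    jittered = _jitter_sequence(seq, noise.duration_jitter_cv, rng)
    state = init or on_target_state(jittered.targets[0])
    clean = synthesize_sequence(jittered, state, rate)
    values = clean.values + rng.normal(0.0, noise.sigma, size=len(clean.values)) \
        if noise.sigma > 0 else clean.values.copy()
    traj = Trajectory(
        times=clean.times, values=values, channel=clean.channel,
        boundary_times=clean.boundary_times,
    )
    truth = {
        "targets": list(jittered.targets),
        "boundaries": jittered.boundary_times[1:-1],  # internal edges only
        "init": state,
        "clean": clean,
    }
    return traj, truth


def generate_repetitions(
    seq: TargetSequence,
    n_reps: int,
    noise: NoiseConfig,
    rate: float = 200.0,
    label: str = "",
    init: DynamicState | None = None,
) -> RepetitionSet:
    """Independent noisy repetitions of one underlying sequence."""
    reps = []
    for i in range(n_reps):
        traj, _ = generate_contour(
            seq, replace(noise, seed=noise.seed + i), rate=rate, init=init
        )
        reps.append(traj)
    return RepetitionSet(repetitions=tuple(reps), label=label)


def generate_minimal_triplet(
    n_reps: int = 20,
    noise: NoiseConfig = NoiseConfig(sigma=0.1),
    rate: float = 200.0,
    first_syllable: tuple[float, float, float, float] = (0.0, 10.0, 40.0, 0.2),
    control_height: float = 16.0,
    c_contrast_height: float = 10.0,
    v_contrast_height: float = 22.0,
    second_duration: float = 0.25,
    strength: float = 80.0,
    v_onset_delay: float = 0.0,
) -> tuple[RepetitionSet, RepetitionSet, RepetitionSet, dict]:
    """Minimal triplet on an F2-like channel with constructed divergence truth.

    All three conditions share the first syllable; targets differ only from
    the second syllable's onset.  The consonant contrast diverges from the
    control at the second syllable's onset; the vowel contrast keeps the
    control target for ``v_onset_delay`` seconds before switching, which
    creates an asynchronous ground truth when the delay is nonzero.

    Returns ``(control, c_contrast, v_contrast, truth)`` with
    ``truth["t_div_c"]`` and ``truth["t_div_v"]`` the constructed divergence
    times on the global clock.
    """
    if n_reps < 2:
        raise InvalidInputError("need n_reps >= 2")
    m1, b1, lam1, d1 = first_syllable
    channel = Channel("F2", "arb")
    shared = TargetSpec(m1, b1, lam1, d1)

    def seq(second_targets) -> TargetSequence:
        return TargetSequence(targets=(shared, *second_targets), channel=channel)

    control_seq = seq([TargetSpec(0.0, control_height, strength, second_duration)])
    c_seq = seq([TargetSpec(0.0, c_contrast_height, strength, second_duration)])
    if v_onset_delay > 0:
        if v_onset_delay >= second_duration:
            raise InvalidInputError("v_onset_delay must be shorter than the second syllable")
        v_seq = seq(
            [
                TargetSpec(0.0, control_height, strength, v_onset_delay),
                TargetSpec(0.0, v_contrast_height, strength, second_duration - v_onset_delay),
            ]
        )
    else:
        v_seq = seq([TargetSpec(0.0, v_contrast_height, strength, second_duration)])

    sets = []
    for offset, label, s in (
        (0, "control", control_seq),
        (1, "c_contrast", c_seq),
        (2, "v_contrast", v_seq),
    ):
        sets.append(
            generate_repetitions(
                s, n_reps, replace(noise, seed=noise.seed + 10_000 * offset),
                rate=rate, label=label,
            )
        )
    truth = {
        "t_div_c": d1,
        "t_div_v": d1 + v_onset_delay,
        "sequences": {"control": control_seq, "c_contrast": c_seq, "v_contrast": v_seq},
    }
    return sets[0], sets[1], sets[2], truth


def generate_tone_corpus(
    n_sentences: int = 10,
    n_syllables: int = 5,
    syllable_duration: float = 0.2,
    noise: NoiseConfig = NoiseConfig(sigma=0.2),
    rate: float = 200.0,
    tones: dict[str, tuple[float, float, float]] | None = None,
    tone_pattern: list[str] | None = None,
    init: DynamicState | None = None,
    reference_hz: float = 100.0,
) -> list[tuple[Trajectory, dict]]:
    """Corpus of f0 contours (semitones) with tone targets synchronized to
    syllables.

    Each sentence carries one tone per syllable drawn from ``tones`` (the
    default inventory unless a fixed ``tone_pattern`` is given), one
    interval per syllable, all boundaries at syllable edges.
    """
    tones = dict(tones or DEFAULT_TONES)
    rng = np.random.default_rng(noise.seed + 777)
    names = sorted(tones)
    corpus = []
    for s in range(n_sentences):
        if tone_pattern is not None:
            labels = list(tone_pattern)
        else:
            labels = [names[i] for i in rng.integers(0, len(names), size=n_syllables)]
        targets = tuple(
            TargetSpec(*tones[lab], duration=syllable_duration) for lab in labels
        )
        seq = TargetSequence(targets=targets, channel=Channel("f0", f"st re {reference_hz:g}Hz"))
        traj, truth = generate_contour(
            seq, replace(noise, seed=noise.seed + s), rate=rate,
            init=init or DynamicState(0.0, 0.0, 0.0),
        )
        truth["tones"] = labels
        corpus.append((traj, truth))
    return corpus
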