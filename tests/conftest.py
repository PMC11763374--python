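import numpy as np
import pytest

from syllasync.qta import DynamicState, TargetSpec
from syllasync.score import (
    Dimension,
    DimensionInventory,
    GestureSpec,
    SyllableSpec,
    TargetParams,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def inventory():
    return DimensionInventory(
        [
            Dimension("f0", "st", "T"),
            Dimension("F2", "Hz", "V"),
            Dimension("lip-aperture", "arb", "C"),
            Dimension("tongue-tip", "arb", "C"),
            Dimension("phonation", "arb", "Ph"),
        ]
    )


def make_gesture(role, targets, constrained=None, label=""):
    return GestureSpec(
        role=role,
        targets={k: TargetParams(*v) for k, v in targets.items()},
        constrained=frozenset(constrained) if constrained is not None else None,
        label=label,
    )


VOWEL_A = {
    "F2": (0.0, 1100.0, 30.0),
    "lip-aperture": (0.0, 5.0, 30.0),
    "tongue-tip": (0.0, 0.0, 30.0),
}
VOWEL_I = {
    "F2": (0.0, 2200.0, 30.0),
    "lip-aperture": (0.0, 3.0, 30.0),
    "tongue-tip": (0.0, 1.0, 30.0),
}
HIGH_TONE = {"f0": (0.0, 4.0, 30.0)}


def make_ma(duration=0.2, tone=HIGH_TONE, label="ma"):
    """CV syllable: /m/ constrains lip-aperture only; /a/ takes the rest."""
    return SyllableSpec(
        onset=(
            make_gesture(
                "onset-C",
                {"lip-aperture": (0.0, -5.0, 50.0)},
                constrained=["lip-aperture"],
                label="m",
            ),
        ),
        nucleus=(make_gesture("nucleus-V", VOWEL_A, label="a"),),
        tone=make_gesture("tone-T", tone, label="T"),
        duration=duration,
        label=label,
    )


def make_li(duration=0.2, label="li"):
    return SyllableSpec(
        onset=(
            make_gesture(
                "onset-C",
                {"tongue-tip": (0.0, -4.0, 50.0)},
                constrained=["tongue-tip"],
                label="l",
            ),
        ),
        nucleus=(make_gesture("nucleus-V", VOWEL_I, label="i"),),
        tone=make_gesture("tone-T", HIGH_TONE, label="T"),
        duration=duration,
        label=label,
    )


def random_target(rng, lam_range=(5.0, 80.0), dur_range=(0.05, 0.5)) -> TargetSpec:
    return TargetSpec(
        slope=rng.uniform(-80, 80),
        height=rng.uniform(-10, 10),
        strength=rng.uniform(*lam_range),
        duration=rng.uniform(*dur_range),
    )


def random_state(rng) -> DynamicState:
    return DynamicState(rng.uniform(-10, 10), rng.uniform(-50, 50), rng.uniform(-500, 500))
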