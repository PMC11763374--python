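import numpy as np
import pytest

from syllasync.errors import DimensionConflictError, InvalidInputError
from syllasync.qta import DynamicState, remaining_fraction
from syllasync.score import (
    SyllableSpec,
    compile_syllable,
    compile_utterance,
    compute_locus_equation,
    export_segmentation,
    locus_equation_slope,
    synthesize_score,
)

from conftest import HIGH_TONE, VOWEL_A, VOWEL_I, make_gesture, make_li, make_ma

RATE = 200.0


def onset_spread(score):
    """Max spread of first-target onset times across dimensions, per syllable."""
    spreads = []
    for syl in score.syllable_intervals:
        firsts = []
        for dim, intervals in score.segment_intervals.items():
            starts = [iv.start for iv in intervals if iv.start >= syl.start - 1e-12
                      and iv.start < syl.end - 1e-12]
            firsts.append(min(starts))
        spreads.append(max(firsts) - min(firsts))
    return max(spreads)


class TestCompileSyllable:
    def test_ma_high_tone_layout(self, inventory):
        score = compile_syllable(make_ma(duration=0.2), inventory)
        lip = score.sequences["lip-aperture"]
        assert len(lip.targets) == 2  # C closure then V opening
        assert lip.targets[0].height == -5.0
        assert lip.targets[1].height == 5.0
        # dimensions not constrained by /m/ get /a/ targets from t=0
        f2 = score.sequences["F2"]
        assert len(f2.targets) == 1
        assert score.segment_intervals["F2"][0].start == 0.0
        # tone spans the whole syllable
        f0 = score.sequences["f0"]
        assert len(f0.targets) == 1
        assert f0.targets[0].duration == pytest.approx(0.2)

    def test_edge_synchronization_zero_onset_spread(self, inventory):
        score = compile_syllable(make_ma(), inventory)
        assert onset_spread(score) == 0.0

    def test_cv_offsets_coincide(self, inventory):
        score = compile_syllable(make_ma(duration=0.2), inventory)
        syl = score.syllable_intervals[0]
        v_end = score.segment_intervals["F2"][-1].end
        tone_end = score.segment_intervals["f0"][-1].end
        assert v_end == pytest.approx(syl.end, abs=1e-12)
        assert tone_end == pytest.approx(syl.end, abs=1e-12)

    def test_default_onset_fraction(self, inventory):
        score = compile_syllable(make_ma(duration=0.2), inventory)
        c_iv = score.segment_intervals["lip-aperture"][0]
        assert (c_iv.end - c_iv.start) == pytest.approx(0.2 * 0.3)

    def test_coda_follows_nucleus(self, inventory):
        coda = make_gesture(
            "coda-C", {"tongue-tip": (0.0, -4.0, 50.0)}, constrained=["tongue-tip"],
            label="n",
        )
        spec = SyllableSpec(
            onset=make_ma().onset,
            nucleus=make_ma().nucleus,
            coda=coda,
            tone=make_ma().tone,
            duration=0.25,
            label="man",
        )
        score = compile_syllable(spec, inventory)
        tt = score.segment_intervals["tongue-tip"]
        assert [iv.label for iv in tt] == ["a", "n"]
        assert tt[1].start >= tt[0].end - 1e-12  # coda after nucleus, no overlap
        # tone still ends at the syllable (== coda) offset
        assert score.segment_intervals["f0"][-1].end == pytest.approx(0.25)

    def test_ccv_vowel_starts_at_first_consonant_onset(self, inventory):
        c1 = make_gesture("onset-C", {"lip-aperture": (0.0, -5.0, 50.0)},
                          constrained=["lip-aperture"], label="p")
        c2 = make_gesture("onset-C", {"tongue-tip": (0.0, -4.0, 50.0)},
                          constrained=["tongue-tip"], label="l")
        spec = SyllableSpec(
            onset=(c1, c2),
            nucleus=(make_gesture("nucleus-V", VOWEL_A, label="a"),),
            tone=make_gesture("tone-T", HIGH_TONE, label="T"),
            duration=0.3,
            label="pla",
        )
        score = compile_syllable(spec, inventory)
        # F2 unconstrained by either consonant: vowel target from t=0
        assert score.segment_intervals["F2"][0].label == "a"
        assert score.segment_intervals["F2"][0].start == 0.0
        assert onset_spread(score) == 0.0

    def test_glide_forces_sequential_on_all_dims(self, inventory):
        glide = make_gesture(
            "nucleus-V",
            {"F2": (0.0, 700.0, 40.0), "lip-aperture": (0.0, -2.0, 40.0),
             "tongue-tip": (0.0, 0.5, 40.0)},
            label="w",
        )
        spec = SyllableSpec(
            nucleus=(glide, make_gesture("nucleus-V", VOWEL_I, label="ei")),
            tone=make_gesture("tone-T", HIGH_TONE, label="T"),
            duration=0.3,
            label="wei",
        )
        score = compile_syllable(spec, inventory)
        for dim in ("F2", "lip-aperture", "tongue-tip"):
            labels = [iv.label for iv in score.segment_intervals[dim]]
            assert labels == ["w", "ei"]

    def test_laryngeal_conflict_names_dimension(self, inventory):
        spec = SyllableSpec(
            nucleus=(make_gesture("nucleus-V", VOWEL_A, label="a"),),
            tone=make_gesture("tone-T", HIGH_TONE),
            phonation=make_gesture("phonation-Ph", {"f0": (0.0, 0.0, 10.0)}),
            duration=0.2,
        )
        with pytest.raises(DimensionConflictError) as err:
            compile_syllable(spec, inventory)
        assert err.value.dimension == "f0"

    def test_targetless_dimension_rejected(self, inventory):
        bare = SyllableSpec(
            nucleus=(make_gesture("nucleus-V", {"F2": (0.0, 1000.0, 30.0)}),),
            tone=make_gesture("tone-T", HIGH_TONE),
            duration=0.2,
        )
        full = make_ma()
        with pytest.raises(InvalidInputError):
            compile_utterance([full, bare], inventory)


class TestCompileUtterance:
    def test_two_syllables_chain(self, inventory):
        score = compile_utterance([make_ma(), make_ma(label="ma2")], inventory)
        syls = score.syllable_intervals
        assert syls[0].end == syls[1].start
        # per-dimension tiling with no gaps
        for dim, intervals in score.segment_intervals.items():
            for a, b in zip(intervals, intervals[1:]):
                assert a.end == pytest.approx(b.start, abs=1e-12)
            assert intervals[0].start == 0.0
            assert intervals[-1].end == pytest.approx(0.4)

    def test_tone_varied_second_syllable_reconverges(self, inventory):
        # five syllables, tone of syllable 2 varied; lam*d >= 6 forces
        # reconvergence during syllable 3
        variants = {}
        for name, tone in [("H", (0.0, 4.0, 30.0)), ("L", (0.0, -4.0, 30.0))]:
            syls = [make_ma(tone=HIGH_TONE, label=f"s{i}") for i in range(5)]
            syls[1] = make_ma(tone={"f0": tone}, label="s1v")
            score = compile_utterance(syls, inventory)
            trajset = synthesize_score(score, rate=RATE)
            variants[name] = trajset["f0"]
        a, b = variants["H"], variants["L"]
        # targets differ only in interval 2
        sel_syl2 = (a.times >= 0.2) & (a.times < 0.4)
        assert np.max(np.abs(a.values[sel_syl2] - b.values[sel_syl2])) > 4.0
        end_syl3 = int(np.argmin(np.abs(a.times - 0.6)))
        assert abs(a.values[end_syl3] - b.values[end_syl3]) < 0.5

    def test_neutral_tone_slow_approach(self, inventory):
        falling = {"f0": (-60.0, 6.0, 35.0)}
        weak_mid = {"f0": (0.0, 1.0, 8.0)}
        syls = [make_ma(tone=falling, label="F")] + [
            make_ma(tone=weak_mid, label=f"N{i}") for i in range(3)
        ]
        score = compile_utterance(syls, inventory)
        traj = synthesize_score(score, rate=RATE)["f0"]
        i_end_n1 = int(np.argmin(np.abs(traj.times - 0.4)))
        i_end_n3 = int(np.argmin(np.abs(traj.times - 0.8)))
        err1 = abs(traj.values[i_end_n1] - 1.0)
        err3 = abs(traj.values[i_end_n3] - 1.0)
        assert err1 > 0.5  # still far after one weak syllable
        assert err3 < err1  # but converging

    def test_empty_utterance_rejected(self, inventory):
        with pytest.raises(InvalidInputError):
            compile_utterance([], inventory)


class TestSynthesizeScore:
    def test_attained_static_targets_are_flat(self, inventory):
        spec = SyllableSpec(
            nucleus=(make_gesture("nucleus-V", VOWEL_A),),
            tone=make_gesture("tone-T", HIGH_TONE),
            duration=0.2,
        )
        score = compile_utterance([spec, spec], inventory)
        trajset = synthesize_score(score, rate=RATE)
        for name in trajset.channels:
            assert np.allclose(np.diff(trajset[name].values), 0.0)

    def test_early_vowel_onset_on_f2(self, inventory):
        score = compile_utterance([make_ma(), make_li()], inventory)
        trajset = synthesize_score(score, rate=RATE)
        f2 = trajset["F2"]
        before = (f2.times > 0.15) & (f2.times < 0.2)
        after = (f2.times >= 0.2) & (f2.times < 0.25)
        # still settled on /a/ just before the boundary, clearly moving after
        assert np.max(np.abs(np.diff(f2.values[before]))) < 1.0
        assert np.max(np.abs(np.diff(f2.values[after]))) > 10.0

    def test_unknown_init_dimension_rejected(self, inventory):
        score = compile_utterance([make_ma()], inventory)
        with pytest.raises(InvalidInputError):
            synthesize_score(score, init={"nope": DynamicState(0, 0, 0)}, rate=RATE)

    def test_channels_share_clock(self, inventory):
        score = compile_utterance([make_ma(), make_li()], inventory)
        trajset = synthesize_score(score, rate=RATE)
        ref = trajset[trajset.channels[0]].times
        for name in trajset.channels[1:]:
            assert np.array_equal(trajset[name].times, ref)


class TestExportSegmentation:
    def test_tiers_and_tone_equals_syllable(self, inventory):
        score = compile_utterance([make_ma(), make_li()], inventory)
        tiers = export_segmentation(score)
        assert set(tiers) >= {"syllable", "f0", "F2", "lip-aperture"}
        for tone_iv, syl_iv in zip(tiers["f0"], tiers["syllable"]):
            assert tone_iv.start == syl_iv.start
            assert tone_iv.end == syl_iv.end

    def test_conventional_tier(self, inventory):
        score = compile_utterance([make_ma()], inventory)
        tiers = export_segmentation(
            score, conventional_fractions={"ma": [("m", 0.4), ("a", 0.6)]}
        )
        conv = tiers["conventional"]
        assert [iv.label for iv in conv] == ["m", "a"]
        assert conv[0].end == pytest.approx(0.08)

    def test_bad_fractions_rejected(self, inventory):
        score = compile_utterance([make_ma()], inventory)
        with pytest.raises(InvalidInputError):
            export_segmentation(score, conventional_fractions={"ma": [("m", 0.5)]})


class TestLocusEquation:
    def test_closed_form_slopes(self):
        for u in (2.0, 4.0):
            lam, t_onset = 40.0, u / 40.0
            slope, intercept, r2 = compute_locus_equation(
                1500.0, [600, 900, 1400, 1900, 2300], lam, t_onset
            )
            assert slope == pytest.approx(1 - remaining_fraction(u), abs=1e-6)
            assert r2 == pytest.approx(1.0, abs=1e-9)
            assert intercept == pytest.approx(remaining_fraction(u) * 1500.0, rel=1e-6)

    def test_reference_values(self):
        assert locus_equation_slope(40.0, 0.05) == pytest.approx(0.3233, abs=1e-4)
        assert locus_equation_slope(40.0, 0.10) == pytest.approx(0.7619, abs=1e-4)

    def test_slope_increases_with_measurement_delay(self):
        slopes = [locus_equation_slope(40.0, t) for t in (0.02, 0.05, 0.1, 0.2)]
        assert all(a < b for a, b in zip(slopes, slopes[1:]))
        assert slopes[-1] < 1.0

    def test_strong_consonantless_limit(self):
        assert locus_equation_slope(1e4, 0.05) == pytest.approx(1.0, abs=1e-12)

    def test_too_few_vowels_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_locus_equation(1500.0, [600, 900], 40.0, 0.05)
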