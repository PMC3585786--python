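"""Rate / rhythm / pattern / AF classifiers and their invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cycleont import (
    AttributeLabel,
    ThresholdConfig,
    ValidationError,
    attribute_profile,
    build_sequence,
    classify_af_pattern,
    classify_rate,
    classify_rhythm,
    detect_bigeminy,
    detect_sudden_onset,
    is_ideal_accelerating,
    is_ideal_decelerating,
    is_ideal_even,
    pattern_distances,
    segment_runs,
    tolerant_pattern,
)
from cycleont.model import CycleType
from conftest import AF, SA, MIXED_TREND_DURATIONS, typed_sequence

CFG = ThresholdConfig()

positive_durations = st.lists(
    st.floats(min_value=0.01, max_value=10, allow_nan=False), min_size=2, max_size=40
)


class TestRateClassification:
    @pytest.mark.parametrize(
        "count, label",
        [
            (59, AttributeLabel.SLOW_RATE),
            (60, AttributeLabel.NORMAL_RATE),
            (100, AttributeLabel.NORMAL_RATE),
            (101, AttributeLabel.FAST_RATE),
        ],
    )
    def test_band_boundaries_at_sixty_seconds(self, count, label):
        assert classify_rate(count, 60.0, CFG).label is label

    def test_trichotomy_over_count_sweep(self):
        rate_labels = {
            AttributeLabel.SLOW_RATE,
            AttributeLabel.NORMAL_RATE,
            AttributeLabel.FAST_RATE,
        }
        normal = set()
        for k in range(201):
            attr = classify_rate(k, 60.0, CFG)
            assert attr.label in rate_labels  # exactly one label per count
            if attr.label is AttributeLabel.NORMAL_RATE:
                normal.add(k)
        assert normal == set(range(60, 101))

    def test_thresholds_rescale_with_window_duration(self):
        # 30 s window: normal band becomes [30, 50]
        assert classify_rate(29, 30.0, CFG).label is AttributeLabel.SLOW_RATE
        assert classify_rate(30, 30.0, CFG).label is AttributeLabel.NORMAL_RATE
        assert classify_rate(50, 30.0, CFG).label is AttributeLabel.NORMAL_RATE
        assert classify_rate(51, 30.0, CFG).label is AttributeLabel.FAST_RATE

    def test_parameters_echo_the_thresholds_used(self):
        attr = classify_rate(70, 60.0, CFG)
        assert attr.parameters["normal_low"] == 60
        assert attr.parameters["normal_high"] == 100

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            classify_rate(-1, 60.0, CFG)


class TestIdealPatterns:
    def test_even_examples(self):
        assert is_ideal_even([2, 2, 2])
        assert not is_ideal_even([2, 2, 3])
        assert is_ideal_even([1.00, 1.005], tol=0.01)  # |d|/max = 0.005

    def test_strictly_shortening_durations_are_accelerating(self):
        assert is_ideal_accelerating([5, 4, 3])
        assert is_ideal_decelerating([3, 4, 5])

    def test_ties_falsify_both_strict_ideals(self):
        assert not is_ideal_accelerating([5, 5, 4])
        assert not is_ideal_decelerating([4, 5, 5])

    def test_mixed_trend_sequence_is_not_ideal_accelerating(self):
        assert not is_ideal_accelerating(MIXED_TREND_DURATIONS)

    def test_fewer_than_two_cycles_is_an_error(self):
        for fn in (is_ideal_even, is_ideal_accelerating, is_ideal_decelerating):
            with pytest.raises(ValidationError):
                fn([1.0])


class TestTolerantPatterns:
    def test_one_violation_in_four_pairs_within_quarter_tolerance(self):
        cfg = ThresholdConfig(violation_fraction=0.25)
        assert tolerant_pattern([5, 4, 5, 3, 2], "accelerating", cfg)

    def test_ideal_sequence_passes_any_tolerance(self):
        cfg = ThresholdConfig(violation_fraction=0.0)
        assert tolerant_pattern([5, 4, 3, 2], "accelerating", cfg)

    def test_reversed_ideal_swaps_pattern_membership(self):
        cfg = ThresholdConfig(violation_fraction=0.0)
        assert tolerant_pattern([2, 3, 4, 5], "decelerating", cfg)
        assert not tolerant_pattern([2, 3, 4, 5], "accelerating", cfg)

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValidationError):
            tolerant_pattern([1, 2], "wobbling", CFG)


class TestPatternDistances:
    def test_mixed_trend_sequence_hand_tally(self):
        prof = pattern_distances(MIXED_TREND_DURATIONS)
        assert (prof.accel, prof.decel, prof.even) == (3, 7, 10)
        assert prof.accel < prof.even and prof.accel < prof.decel

    def test_constant_sequence_is_at_zero_distance_everywhere(self):
        prof = pattern_distances([2, 2, 2, 2])
        assert (prof.accel, prof.decel, prof.even) == (0, 0, 0)

    def test_strictly_shortening_has_zero_accel_distance(self):
        prof = pattern_distances([5, 4, 3])
        assert prof.accel == 0 and prof.decel > 0

    @given(positive_durations)
    def test_even_distance_is_accel_plus_decel(self, durs):
        prof = pattern_distances(durs)
        assert prof.even == pytest.approx(prof.accel + prof.decel)
        assert prof.accel >= 0 and prof.decel >= 0

    @given(positive_durations)
    def test_reversal_swaps_accel_and_decel(self, durs):
        fwd = pattern_distances(durs)
        rev = pattern_distances(durs[::-1])
        assert rev.accel == pytest.approx(fwd.decel)
        assert rev.decel == pytest.approx(fwd.accel)
        assert rev.even == pytest.approx(fwd.even)
        if is_ideal_accelerating(durs):
            assert is_ideal_decelerating(durs[::-1])

    @given(positive_durations, st.floats(min_value=0.1, max_value=10))
    def test_distances_scale_linearly_and_booleans_are_scale_free(self, durs, c):
        base, scaled = pattern_distances(durs), pattern_distances([c * d for d in durs])
        assert scaled.accel == pytest.approx(c * base.accel, rel=1e-9)
        assert scaled.even == pytest.approx(c * base.even, rel=1e-9)
        assert is_ideal_accelerating([c * d for d in durs]) == is_ideal_accelerating(durs)

    @given(st.integers(0, 2**31 - 1))
    def test_jitter_on_a_constant_sequence_never_shrinks_even_distance(self, seed):
        rng = np.random.default_rng(seed)
        base = np.full(20, 1.0)
        noise = np.abs(rng.normal(0, 0.1, size=20))
        jittered = base + noise
        assert pattern_distances(base.tolist()).even == 0.0
        even = pattern_distances(jittered.tolist()).even
        assert even >= 0.0
        if np.any(np.diff(noise) != 0):
            assert even > 0.0


class TestRhythm:
    def test_constant_durations_are_regular(self):
        assert classify_rhythm([1, 1, 1], CFG).label is AttributeLabel.REGULAR_RHYTHM

    def test_two_cycles_error_cites_three_cycle_minimum(self):
        with pytest.raises(ValidationError, match="3"):
            classify_rhythm([1, 1], CFG)

    def test_high_variability_is_irregular_with_cv_oracle(self):
        rng = np.random.default_rng(42)
        sigma = np.sqrt(np.log1p(0.3**2))
        durs = (60 / 90) * rng.lognormal(-sigma**2 / 2, sigma, size=100)
        cv = durs.std(ddof=1) / durs.mean()
        attr = classify_rhythm(durs.tolist(), CFG)
        assert attr.parameters["cv"] == pytest.approx(cv)
        assert cv > CFG.rhythm_cv_threshold
        assert attr.label is AttributeLabel.IRREGULAR_RHYTHM


class TestBigeminy:
    def test_alternating_short_long_pairs_detected(self):
        assert detect_bigeminy([0.5, 1.0] * 3, CFG)  # 0.5 < 0.8 * 1.0

    def test_constant_durations_are_not_bigeminal(self):
        assert not detect_bigeminy([1.0] * 10, CFG)

    def test_mixed_trend_sequence_is_not_bigeminal(self):
        assert not detect_bigeminy(MIXED_TREND_DURATIONS, CFG)

    def test_too_short_sequence_returns_false_not_error(self):
        assert detect_bigeminy([0.5, 1.0], CFG) is False

    def test_long_short_parity_also_detected(self):
        assert detect_bigeminy([1.0, 0.5] * 4, CFG)

    def test_insufficient_contrast_rejected(self):
        # 0.9 is not < 0.8 * 1.0: pairs lack the short/long contrast
        assert not detect_bigeminy([0.9, 1.0] * 5, CFG)


class TestAfPattern:
    def test_pure_af_is_chronic(self):
        runs = segment_runs(typed_sequence([AF] * 5))
        assert classify_af_pattern(runs, CFG).label is AttributeLabel.CHRONIC_AF

    def test_two_af_episodes_with_sinus_gap_is_paroxysmal(self):
        runs = segment_runs(typed_sequence([AF] * 3 + [SA] * 4 + [AF] * 3))
        assert classify_af_pattern(runs, CFG).label is AttributeLabel.PAROXYSMAL_AF

    def test_pure_sinus_has_no_af_attribute(self):
        runs = segment_runs(typed_sequence([SA] * 10))
        assert classify_af_pattern(runs, CFG) is None

    def test_single_af_cycle_is_isolated_ectopy_not_an_episode(self):
        runs = segment_runs(typed_sequence([AF] + [SA] * 9))
        assert classify_af_pattern(runs, CFG) is None

    def test_empty_run_list_is_an_error(self):
        with pytest.raises(ValidationError):
            classify_af_pattern([], CFG)


class TestSuddenOnset:
    @staticmethod
    def normal_then_accelerating():
        steady = [60.0 / 70.0] * 70  # one minute at 70 cycles/min
        ramp = np.linspace(0.85, 0.45, 25).tolist()
        return build_sequence(steady + ramp)

    def test_onset_reported_at_the_shared_boundary(self):
        events = detect_sudden_onset(self.normal_then_accelerating(), CFG)
        assert len(events) == 1
        t, preceding, following = events[0]
        assert t == pytest.approx(60.0)
        assert preceding is AttributeLabel.NORMAL_RATE
        assert following == "accelerating"

    def test_steady_beating_has_no_onset(self):
        seq = build_sequence([60.0 / 70.0] * 140)
        assert detect_sudden_onset(seq, CFG) == []

    def test_fast_rate_before_acceleration_does_not_qualify(self):
        fast = [60.0 / 140.0] * 140  # 140 cycles/min: FAST, not NORMAL
        ramp = np.linspace(0.40, 0.20, 67).tolist()  # ~20 s: two full segments
        seq = build_sequence(fast + ramp)
        assert detect_sudden_onset(seq, CFG) == []


class TestAttributeProfile:
    def test_empty_sequence_is_a_validation_error(self):
        with pytest.raises(ValidationError):
            attribute_profile(build_sequence([]), CFG)

    def test_steady_preset_yields_normal_rate_and_regular_rhythm_everywhere(self):
        seq = build_sequence([60.0 / 70.0] * 140)
        profile = attribute_profile(seq, CFG)
        rate = [a for a in profile.attributes if "RATE" in a.label.value]
        rhythm = [a for a in profile.attributes if "RHYTHM" in a.label.value]
        assert len(rate) == len(profile.windows) == 2
        assert all(a.label is AttributeLabel.NORMAL_RATE for a in rate)
        assert all(a.label is AttributeLabel.REGULAR_RHYTHM for a in rhythm)

    def test_isolated_ectopy_is_noted_rather_than_classified(self):
        seq = typed_sequence([AF] + [SA] * 9)
        profile = attribute_profile(seq, CFG)
        labels = {a.label for a in profile.attributes}
        assert AttributeLabel.CHRONIC_AF not in labels
        assert AttributeLabel.PAROXYSMAL_AF not in labels
        assert any("isolated ectopy" in n for n in profile.notes)

    def test_profile_is_deterministic(self):
        seq = typed_sequence([AF] * 3 + [SA] * 4 + [AF] * 3, duration=0.7)
        p1 = attribute_profile(seq, CFG)
        p2 = attribute_profile(seq, CFG)
        assert [a.label for a in p1.attributes] == [a.label for a in p2.attributes]


class TestThresholdConfig:
    def test_inverted_band_rejected(self):
        with pytest.raises(ValidationError):
            ThresholdConfig(normal_low=110, normal_high=100)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValidationError):
            ThresholdConfig(rhythm_cv_threshold=-0.1)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            ThresholdConfig.from_mapping({"normal_lo": 50})

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("thresholds:\n  normal_low: 50\n  rhythm_cv_threshold: 0.2\n")
        cfg = ThresholdConfig.from_yaml(path)
        assert cfg.normal_low == 50
        assert cfg.rhythm_cv_threshold == 0.2
        assert cfg.normal_high == 100
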