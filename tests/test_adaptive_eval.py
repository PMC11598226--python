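"""Adaptive evaluation: debounce, transition durations, conservation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnoposture import EvalState, UNKNOWN, finalize, step
from somnoposture.adaptive_eval import (
    SEGMENT,
    TRANSITION,
    clock_ticks,
    evaluate_labels,
    pose_period_difference,
)

PERIOD = 1.0 / 6.0


def labelled(runs: list[tuple[str, int]]) -> list[tuple[float, str]]:
    """Expand (label, count) runs into a uniformly sampled (t, label) list."""
    out = []
    k = 0
    for label, count in runs:
        for _ in range(count):
            out.append((k * PERIOD, label))
            k += 1
    return out


class TestPosePeriodDifference:
    @pytest.mark.parametrize(
        "a, b, expected", [(10.0, 10.0, 0.0), (21.44, 10.0, 11.44), (5.0, 10.0, -5.0)]
    )
    def test_signed_subtraction(self, a, b, expected):
        assert pose_period_difference(a, b) == pytest.approx(expected)


class TestStep:
    def test_constant_stream_single_segment_no_transitions(self):
        events = evaluate_labels(labelled([("LY", 60)]), count_step1=3)
        assert [e.kind for e in events] == [SEGMENT]
        assert events[0].label == "LY"
        assert events[0].duration == pytest.approx(10.0, abs=PERIOD + 1e-9)

    def test_gap_transition_duration(self):
        events = evaluate_labels(
            labelled([("LY", 60), (UNKNOWN, 30), ("RY", 60)]), count_step1=3
        )
        transitions = [e for e in events if e.kind == TRANSITION]
        assert len(transitions) == 1
        td = transitions[0]
        assert (td.from_label, td.to_label) == ("LY", "RY")
        assert td.duration == pytest.approx(30 * PERIOD, abs=PERIOD + 1e-9)

    def test_single_frame_flicker_is_debounced(self):
        events = evaluate_labels(
            labelled([("LY", 60), ("RY", 1), ("LY", 60)]), count_step1=3
        )
        assert all(e.kind == SEGMENT and e.label == "LY" for e in events)
        assert len(events) == 1

    def test_flicker_shorter_than_threshold_never_emits(self):
        events = evaluate_labels(
            labelled([("LY", 30), ("RY", 2), ("SP", 2), ("LY", 30)]), count_step1=3
        )
        assert {e.label for e in events if e.kind == SEGMENT} == {"LY"}

    def test_count_step1_one_degenerates_to_edge_detection(self):
        events = evaluate_labels(
            labelled([("LY", 5), ("RY", 5), ("SP", 5)]), count_step1=1
        )
        segments = [e.label for e in events if e.kind == SEGMENT]
        assert segments == ["LY", "RY", "SP"]
        assert sum(e.kind == TRANSITION for e in events) == 2

    def test_two_segment_scenario_event_bookkeeping(self):
        events = evaluate_labels(labelled([("LY", 60), ("RY", 60)]), count_step1=3)
        kinds = [e.kind for e in events]
        assert kinds == [SEGMENT, TRANSITION, SEGMENT]
        seg_ly, trans, seg_ry = events
        assert seg_ly.end == trans.start and trans.end == seg_ry.start

    def test_unknown_only_stream_emits_nothing(self):
        assert evaluate_labels(labelled([(UNKNOWN, 40)])) == []

    def test_non_increasing_time_rejected(self):
        state = EvalState()
        step(state, "LY", 1.0)
        with pytest.raises(ValueError, match="increasing"):
            step(state, "LY", 1.0)

    def test_invalid_count_step1_rejected(self):
        with pytest.raises(ValueError):
            EvalState(count_step1=0)


class TestFinalize:
    def test_open_segment_closed_at_t_end(self):
        state = EvalState(count_step1=1)
        for k in range(10):
            step(state, "SP", k * PERIOD)
        events = finalize(state, 30.0)
        assert [(e.kind, e.label, e.start, e.end) for e in events] == [
            (SEGMENT, "SP", 0.0, 30.0)
        ]

    def test_no_confirmed_pose_yields_nothing(self):
        state = EvalState(count_step1=3)
        step(state, "SP", 0.0)  # one sample: not yet confirmed
        assert finalize(state, 1.0) == []


class TestConservation:
    @given(
        runs=st.lists(
            st.tuples(
                st.sampled_from(["LY", "RY", "SP", "FP", UNKNOWN]),
                st.integers(min_value=1, max_value=12),
            ),
            min_size=1,
            max_size=12,
        ),
        count_step1=st.integers(min_value=1, max_value=4),
    )
    @settings(max_examples=80, derandomize=True)
    def test_durations_tile_the_confirmed_span(self, runs, count_step1):
        """Segment dwell plus transition TDs must tile the span from the
        first to the last confirmed sample, one period of slack per
        boundary."""
        events = evaluate_labels(labelled(runs), count_step1=count_step1)
        segments = [e for e in events if e.kind == SEGMENT]
        if not segments:
            return
        span = segments[-1].end - segments[0].start
        total = sum(e.duration for e in events)
        boundaries = len(events) + 1
        assert abs(total - span) <= boundaries * PERIOD + 1e-9
        # events are contiguous and ordered
        for a, b in zip(events, events[1:]):
            assert b.start == pytest.approx(a.end)


def test_clock_tick_display_parity():
    # 1 s at the 100 MHz device clock
    assert clock_ticks(1.0) == 100_000_000
    assert clock_ticks(11.44) == 1_144_000_000
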