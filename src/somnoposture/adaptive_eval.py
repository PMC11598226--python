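"""Time-variant posture evaluation: debounced segments and transition timing.

Per-sample posture labels stream in at the uniform sampling period.  The
evaluator tracks the confirmed current pose; a different label must persist
for ``count_step1`` consecutive samples before the change is confirmed.  On
confirmation it closes the previous posture SEGMENT and emits a TRANSITION
whose duration (TD) spans the gap between the old segment's end and the new
segment's start — the quantity a bedside display would show as the time the
subject spent moving.  UNKNOWN labels extend that gap without contributing
to any segment, and a label flicker shorter than the debounce threshold
leaves no trace.

Counters tick per sample (1/6 s each at the default rate), not per device
clock; :func:`clock_ticks` converts a duration to 100 MHz clock ticks for
display parity with a hardware counter.  Hardware counters are 8-bit and
saturate at 255; here they are unbounded integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .postures import UNKNOWN

#: Default debounce threshold, samples (0.5 s at the 1/6 s period), matching
#: the 3-deep stability FIFO of the learning stage.
COUNT_STEP1 = 3

#: Device clock frequency used for tick conversion, Hz.
DEVICE_CLOCK_HZ = 100e6

SEGMENT = "SEGMENT"
TRANSITION = "TRANSITION"


@dataclass(frozen=True)
class PostureEvent:
    """A confirmed posture segment or a posture-to-posture transition."""

    kind: str  # SEGMENT or TRANSITION
    start: float
    end: float
    label: str | None = None  # SEGMENT only
    from_label: str | None = None  # TRANSITION only
    to_label: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in (SEGMENT, TRANSITION):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.end < self.start:
            raise ValueError("event end must not precede start")

    @property
    def duration(self) -> float:
        """Elapsed seconds; for a TRANSITION this is the TD."""
        return self.end - self.start

    def to_dict(self) -> dict:
        d: dict = {
            "kind": self.kind,
            "start": round(self.start, 9),
            "end": round(self.end, 9),
            "duration": round(self.duration, 9),
        }
        if self.kind == SEGMENT:
            d["label"] = self.label
        else:
            d["from"] = self.from_label
            d["to"] = self.to_label
        return d

    def display_line(self) -> str:
        """Human-readable log line mirroring the bedside display."""
        if self.kind == SEGMENT:
            return (
                f"posture {self.label} held {self.duration:.2f} s "
                f"[{self.start:.2f}-{self.end:.2f}]"
            )
        return (
            f"past posture {self.from_label} -> current posture "
            f"{self.to_label}, TD {self.duration:.2f} s"
        )


@dataclass
class EvalState:
    """Mutable evaluator state: confirmed pose, counters, pending candidate."""

    count_step1: int = COUNT_STEP1
    pose_current: str = UNKNOWN
    pose_past: str = UNKNOWN
    count_1: int = 0  # dwell counter, samples in the confirmed pose
    count: int = 0  # debounce counter of the pending candidate
    seg_start: float = 0.0
    seg_end: float = 0.0
    pending_label: str | None = None
    pending_start: float = 0.0
    last_t: float | None = None

    def __post_init__(self) -> None:
        if self.count_step1 < 1:
            raise ValueError("count_step1 must be at least 1")


def pose_period_difference(t_a: float, t_b: float) -> float:
    """Signed difference of two pose timestamps, seconds.

    The hardware computes this with a two's-complement adder; here it is a
    plain subtraction.
    """
    return t_a - t_b


def clock_ticks(duration: float, clock_hz: float = DEVICE_CLOCK_HZ) -> int:
    """Duration expressed in device clock ticks (100 MHz by default)."""
    return round(duration * clock_hz)


def step(state: EvalState, label: str, t: float) -> list[PostureEvent]:
    """Feed one per-sample label; return any events confirmed by it.

    Labels must arrive with strictly increasing timestamps.  A change of
    pose is confirmed once the candidate label has persisted for
    ``count_step1`` consecutive samples; with ``count_step1 = 1`` the
    evaluator degenerates to edge detection.
    """
    if state.last_t is not None and t <= state.last_t:
        raise ValueError(
            f"timestamps must be strictly increasing (got {t} after {state.last_t})"
        )
    state.last_t = t
    events: list[PostureEvent] = []

    if label == state.pose_current and label != UNKNOWN:
        state.count_1 += 1
        state.seg_end = t
        state.pending_label = None
        state.count = 0
        return events

    if label == UNKNOWN:
        # gap frames: kill any pending candidate, extend no segment
        state.pending_label = None
        state.count = 0
        return events

    if label == state.pending_label:
        state.count += 1
    else:
        state.pending_label = label
        state.pending_start = t
        state.count = 1

    if state.count >= state.count_step1:
        if state.pose_current != UNKNOWN:
            events.append(
                PostureEvent(
                    kind=SEGMENT,
                    label=state.pose_current,
                    start=state.seg_start,
                    end=state.seg_end,
                )
            )
            events.append(
                PostureEvent(
                    kind=TRANSITION,
                    from_label=state.pose_current,
                    to_label=label,
                    start=state.seg_end,
                    end=state.pending_start,
                )
            )
        state.pose_past = state.pose_current
        state.pose_current = label
        state.seg_start = state.pending_start
        state.seg_end = t
        state.count_1 = state.count
        state.pending_label = None
        state.count = 0
    return events


def finalize(state: EvalState, t_end: float) -> list[PostureEvent]:
    """Close the open segment at stream end; unconfirmed candidates drop."""
    if state.pose_current == UNKNOWN:
        return []
    return [
        PostureEvent(
            kind=SEGMENT,
            label=state.pose_current,
            start=state.seg_start,
            end=t_end,
        )
    ]


def evaluate_labels(
    labels: list[tuple[float, str]],
    count_step1: int = COUNT_STEP1,
    t_end: float | None = None,
) -> list[PostureEvent]:
    """Run the evaluator over a whole (t, label) sequence and finalize.

    ``t_end`` defaults to the timestamp of the last sample that belongs to
    the confirmed pose.
    """
    state = EvalState(count_step1=count_step1)
    events: list[PostureEvent] = []
    for t, label in labels:
        events.extend(step(state, label, t))
    if labels:
        events.extend(finalize(state, t_end if t_end is not None else state.seg_end))
    return events
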