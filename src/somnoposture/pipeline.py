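"""End-to-end orchestration: stream -> fusion -> learn/classify -> events.

Software analog of the accelerator's control unit.  Three run modes:

* ``simulate`` — render a scenario into a sensor-stream CSV;
* ``learn``    — feed a stream through fusion + stability detection and
  register the stable postures in a subject's profile;
* ``monitor``  — classify each occupied frame and run the adaptive
  evaluator, emitting posture segments and transitions.

The hardware's concurrent processing elements become sequential per-frame
stages; at six frames per second there is no throughput constraint worth
preserving.  Display/Wi-Fi outputs become log lines and JSONL events with
the same fields (past posture, current posture, TD).
"""

from __future__ import annotations

import difflib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import adaptive_eval, fusion, hbc, learning, sim
from .adaptive_eval import SEGMENT, EvalState, PostureEvent
from .errors import ConfigError, DataError
from .geometry import Geometry
from .postures import STANDARD_POSTURES, UNKNOWN

logger = logging.getLogger("somnoposture")

#: CSV stream dialect: header and column order.
STREAM_COLUMNS = ["t", "pir", "d_HR", "d_HL", "d_AR", "d_AL", "d_RL", "d_LL"]


# ---------------------------------------------------------------------------
# stream and scenario I/O


def write_stream(frames: list[sim.SensorFrame], path: str | Path) -> None:
    """Write frames as CSV (full float precision, lossless round trip)."""
    rows = [[f.t, f.pir, *f.distances] for f in frames]
    df = pd.DataFrame(rows, columns=STREAM_COLUMNS)
    df["pir"] = df["pir"].astype(int) if len(df) else df["pir"]
    # %.17g round-trips any double exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_stream(path: str | Path) -> list[sim.SensorFrame]:
    """Read a sensor-stream CSV; validate columns and time ordering."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise DataError(f"cannot parse stream CSV {path}: {exc}") from exc
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"stream {path} lacks columns {missing}")
    frames: list[sim.SensorFrame] = []
    prev_t: float | None = None
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            t = float(getattr(row, "t"))
            pir = int(getattr(row, "pir"))
            distances = tuple(
                float(getattr(row, c)) for c in STREAM_COLUMNS[2:]
            )
            frame = sim.SensorFrame(t=t, pir=pir, distances=distances)
        except (TypeError, ValueError) as exc:
            raise DataError(f"stream {path} line {i}: {exc}") from exc
        if prev_t is not None and t <= prev_t:
            raise DataError(
                f"stream {path} line {i}: timestamps must be strictly "
                f"increasing ({t} after {prev_t})"
            )
        prev_t = t
        frames.append(frame)
    return frames


def write_words(words: list[fusion.FusionWord], path: str | Path) -> None:
    """Optional fused-word CSV: t, pir, 6-char bit string (H_R first)."""
    df = pd.DataFrame(
        [[w.t, w.pir, w.word] for w in words], columns=["t", "pir", "word"]
    )
    df.to_csv(path, index=False)


def write_events(events: list[PostureEvent], path: str | Path) -> None:
    """Write events as JSONL, one event object per line."""
    with open(path, "w") as fh:
        for event in events:
            fh.write(json.dumps(event.to_dict()) + "\n")


def load_scenario(path: str | Path) -> sim.Scenario:
    """Load a scenario from a YAML or JSON file."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse scenario file {path}: {exc}") from exc
    return scenario_from_dict(data)


def scenario_from_dict(data: dict) -> sim.Scenario:
    if not isinstance(data, dict):
        raise ConfigError("scenario file must hold a mapping at top level")
    try:
        return sim.Scenario(**data)
    except ValidationError as exc:
        raise ConfigError(f"invalid scenario: {exc}") from exc


# ---------------------------------------------------------------------------
# configuration and summary


class RunConfig(BaseModel):
    """Validated run configuration for the three pipeline modes."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    mode: Literal["simulate", "learn", "monitor"]
    scenario: Optional[sim.Scenario] = None
    stream_path: Optional[str] = None
    subject_id: Optional[str] = None
    profiles_path: Optional[str] = None
    geometry: Geometry = Field(default_factory=Geometry)
    truth_table: Optional[dict[str, str]] = None
    count_step1: int = adaptive_eval.COUNT_STEP1
    strict: bool = False
    now: float = 0.0  # wall-clock stand-in for profile last_used stamps
    stream_out: Optional[str] = None
    events_out: Optional[str] = None
    summary_out: Optional[str] = None
    profiles_out: Optional[str] = None

    @model_validator(mode="after")
    def _check_mode_fields(self) -> "RunConfig":
        if self.count_step1 < 1:
            raise ValueError("count_step1 must be at least 1")
        if self.mode == "simulate" and self.scenario is None:
            raise ValueError("simulate mode requires a scenario")
        if self.mode in ("learn", "monitor"):
            if self.scenario is None and self.stream_path is None:
                raise ValueError(f"{self.mode} mode requires a stream or scenario")
        if self.mode == "learn" and self.subject_id is None:
            raise ValueError("learn mode requires a subject_id")
        return self


@dataclass
class RunSummary:
    """Counts and dwell statistics consistent with the event log."""

    mode: str
    frames: int = 0
    occupied_frames: int = 0
    segment_counts: dict[str, int] = field(default_factory=dict)
    dwell_seconds: dict[str, float] = field(default_factory=dict)
    transitions: int = 0
    learned_labels: list[str] = field(default_factory=list)
    recovered_segments: int | None = None
    scheduled_segments: int | None = None
    recovery_accuracy_pct: float | None = None

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "frames": self.frames,
            "occupied_frames": self.occupied_frames,
            "segment_counts": self.segment_counts,
            "dwell_seconds": {k: round(v, 6) for k, v in self.dwell_seconds.items()},
            "transitions": self.transitions,
            "learned_labels": self.learned_labels,
        }
        if self.recovery_accuracy_pct is not None:
            d["recovered_segments"] = self.recovered_segments
            d["scheduled_segments"] = self.scheduled_segments
            d["recovery_accuracy_pct"] = round(self.recovery_accuracy_pct, 4)
        return d


# ---------------------------------------------------------------------------
# core passes


def _resolve_table(config: RunConfig) -> hbc.PostureTruthTable:
    if config.truth_table is None:
        return hbc.DEFAULT_TABLE
    return hbc.PostureTruthTable(config.truth_table)


def _load_frames(config: RunConfig) -> list[sim.SensorFrame]:
    if config.stream_path is not None:
        return read_stream(config.stream_path)
    assert config.scenario is not None
    return sim.generate_stream(config.scenario)


def monitor_frames(
    frames: list[sim.SensorFrame],
    geometry: Geometry | None = None,
    tree: hbc.HBCTree | None = None,
    strict: bool = False,
    count_step1: int = adaptive_eval.COUNT_STEP1,
    profile: learning.SubjectProfile | None = None,
) -> tuple[list[PostureEvent], int]:
    """Classify frames and run the adaptive evaluator.

    Returns (events, occupied frame count).  When a subject profile is
    supplied, a word exactly matching one of its learned adaptive (New_k)
    patterns takes that slot's label before the tree is consulted — the
    early-exit tree is total over all 64 words and would otherwise absorb
    learned novel postures into a standard leaf.
    """
    geometry = geometry or Geometry()
    tree = tree or hbc.DEFAULT_TREE
    state = EvalState(count_step1=count_step1)
    events: list[PostureEvent] = []
    occupied = 0
    last_occupied_t: float | None = None
    for frame in frames:
        word = fusion.frame_to_word(frame, geometry)
        if not word.occupied:
            # WAIT_PIR: idle until the bed is occupied again
            events.extend(adaptive_eval.step(state, UNKNOWN, frame.t))
            continue
        occupied += 1
        last_occupied_t = frame.t
        label = UNKNOWN
        if profile is not None:
            slot = profile.lookup(word.word)
            if slot in profile.adaptive_slots:
                label = slot
        if label == UNKNOWN:
            label = hbc.classify(word, tree, strict=strict)
        events.extend(adaptive_eval.step(state, label, frame.t))
    if last_occupied_t is not None:
        events.extend(adaptive_eval.finalize(state, state.seg_end))
    for event in events:
        logger.info(event.display_line())
    return events, occupied


def learn_frames(
    frames: list[sim.SensorFrame],
    profile: learning.SubjectProfile,
    table: hbc.PostureTruthTable | None = None,
    geometry: Geometry | None = None,
) -> tuple[list[str], int]:
    """Stability-gated learning pass; returns (labels registered, occupied)."""
    geometry = geometry or Geometry()
    table = table or hbc.DEFAULT_TABLE
    fifo = learning.MatchFIFO()
    registered: list[str] = []
    occupied = 0
    for frame in frames:
        word = fusion.frame_to_word(frame, geometry)
        if not word.occupied:
            fifo.clear()  # WAIT_PIR resets the match FIFO
            continue
        occupied += 1
        if fifo.push(word):
            label = learning.register_posture(profile, word, table)
            if label not in registered:
                registered.append(label)
    return registered, occupied


def schedule_recovery(
    scenario: sim.Scenario, events: list[PostureEvent]
) -> tuple[int, int]:
    """(recovered, scheduled) standard-posture segment labels, in order.

    Recovered segments are aligned to the scheduled labels with a longest
    common subsequence match, so a spurious or missed segment costs exactly
    the labels it displaces.
    """
    expected = [
        seg.label for seg in scenario.schedule if seg.label in STANDARD_POSTURES
    ]
    got = [e.label for e in events if e.kind == SEGMENT]
    matcher = difflib.SequenceMatcher(a=expected, b=got, autojunk=False)
    recovered = sum(block.size for block in matcher.get_matching_blocks())
    return recovered, len(expected)


# ---------------------------------------------------------------------------
# orchestration


def run(config: RunConfig) -> tuple[list[PostureEvent], RunSummary]:
    """Execute one pipeline run; write any configured outputs."""
    events: list[PostureEvent] = []
    summary = RunSummary(mode=config.mode)

    if config.mode == "simulate":
        frames = sim.generate_stream(config.scenario)
        summary.frames = len(frames)
        summary.occupied_frames = sum(f.pir for f in frames)
        if config.stream_out:
            write_stream(frames, config.stream_out)
    elif config.mode == "learn":
        frames = _load_frames(config)
        table = _resolve_table(config)
        store = (
            learning.ProfileStore.load(config.profiles_path)
            if config.profiles_path and Path(config.profiles_path).exists()
            else learning.ProfileStore()
        )
        profile = store.match_or_create_subject(config.subject_id, config.now)
        registered, occupied = learn_frames(
            frames, profile, table, config.geometry
        )
        summary.frames = len(frames)
        summary.occupied_frames = occupied
        summary.learned_labels = registered
        out = config.profiles_out or config.profiles_path
        if out:
            store.save(out)
    else:  # monitor
        frames = _load_frames(config)
        table = _resolve_table(config)
        tree = hbc.build_tree(table)
        profile = None
        if config.subject_id is not None:
            if not config.profiles_path or not Path(config.profiles_path).exists():
                raise DataError(
                    f"monitor mode: no profile store for subject "
                    f"{config.subject_id!r}"
                )
            store = learning.ProfileStore.load(config.profiles_path)
            if config.subject_id not in store.subjects:
                raise DataError(
                    f"monitor mode: subject {config.subject_id!r} has no "
                    f"stored profile"
                )
            profile = store.subjects[config.subject_id]
        events, occupied = monitor_frames(
            frames,
            geometry=config.geometry,
            tree=tree,
            strict=config.strict,
            count_step1=config.count_step1,
            profile=profile,
        )
        summary.frames = len(frames)
        summary.occupied_frames = occupied
        for event in events:
            if event.kind == SEGMENT:
                summary.segment_counts[event.label] = (
                    summary.segment_counts.get(event.label, 0) + 1
                )
                summary.dwell_seconds[event.label] = (
                    summary.dwell_seconds.get(event.label, 0.0) + event.duration
                )
            else:
                summary.transitions += 1
        if config.scenario is not None and config.stream_path is None:
            recovered, scheduled = schedule_recovery(config.scenario, events)
            summary.recovered_segments = recovered
            summary.scheduled_segments = scheduled
            if scheduled:
                summary.recovery_accuracy_pct = 100.0 * recovered / scheduled

    if config.events_out:
        write_events(events, config.events_out)
    if config.summary_out:
        Path(config.summary_out).write_text(
            json.dumps(summary.to_dict(), indent=2) + "\n"
        )
    return events, summary
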