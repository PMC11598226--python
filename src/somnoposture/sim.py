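"""Synthetic sensor-stream generation.

Emulates the contactless bed setup: six overhead ultrasonic channels
(H_R, H_L, A_R, A_L, R_L, L_L) at 2.4 m above the bed, sampled every 1/6 s,
plus a PIR occupancy flag.  A :class:`Scenario` is a schedule of posture
segments; :func:`generate_stream` turns it into a reproducible stream of
:class:`SensorFrame` with additive Gaussian distance noise.

The generator is deliberately simple acoustics-wise: each channel reads the
bed plane (``sensor_height``) or the body surface
(``sensor_height - body_elevation``), with no beam spread or multipath.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigError
from .geometry import Geometry
from .postures import (
    OFF_BED,
    SCHEDULE_LABELS,
    TABLE_PATTERNS,
    UNDEFINED,
)

#: Speed of sound used for echo timing, m/s.
SPEED_OF_SOUND = 340.0

#: Default sampling period of the sensor FIFO, seconds.
SAMPLE_PERIOD = 1.0 / 6.0


@dataclass(frozen=True)
class SensorFrame:
    """One timestamped sample: PIR flag plus six channel distances (m).

    Distances are ordered ``(H_R, H_L, A_R, A_L, R_L, L_L)``.
    """

    t: float
    pir: int
    distances: tuple[float, float, float, float, float, float]

    def __post_init__(self) -> None:
        if self.pir not in (0, 1):
            raise ValueError("pir must be 0 or 1")
        if len(self.distances) != 6:
            raise ValueError("a frame carries exactly six distances")
        for d in self.distances:
            if not math.isfinite(d) or d < 0:
                raise ValueError("distances must be finite and non-negative")


class Segment(BaseModel):
    """One schedule entry: a posture label held over ``[start, end)`` seconds."""

    model_config = ConfigDict(frozen=True)

    label: str
    start: float = Field(ge=0)
    end: float = Field(ge=0)

    @model_validator(mode="after")
    def _check(self) -> "Segment":
        if self.label not in SCHEDULE_LABELS:
            raise ValueError(
                f"unknown schedule label {self.label!r}; "
                f"expected one of {SCHEDULE_LABELS}"
            )
        if self.end < self.start:
            raise ValueError("segment end must not precede start")
        return self

    @property
    def duration(self) -> float:
        return self.end - self.start


class Scenario(BaseModel):
    """A simulation scenario: schedule, geometry, noise, seed."""

    model_config = ConfigDict(frozen=True)

    schedule: tuple[Segment, ...] = ()
    sample_period: float = SAMPLE_PERIOD
    noise_sd: float = 0.02
    seed: int = 0
    geometry: Geometry = Field(default_factory=Geometry)

    @model_validator(mode="after")
    def _check(self) -> "Scenario":
        if self.sample_period <= 0:
            raise ValueError("sample_period must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for prev, cur in zip(self.schedule, self.schedule[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    "schedule segments must be sorted and non-overlapping"
                )
        return self

    @property
    def span(self) -> tuple[float, float]:
        """(start, end) of the whole schedule; (0, 0) when empty."""
        if not self.schedule:
            return (0.0, 0.0)
        return (self.schedule[0].start, self.schedule[-1].end)


def posture_to_distances(label: str, geometry: Geometry) -> tuple[float, ...]:
    """Noise-free channel distances for a posture label.

    A channel whose truth-table bit is 1 reads the body surface,
    ``sensor_height - body_elevation``; a 0 bit reads the bed plane,
    ``sensor_height``.  The supine don't-care head bits are emitted as 1
    (the head is physically present; the classifier masks them).  OFF_BED
    leaves every channel at bed height, and UNDEFINED — the stand-in for
    mid-transition frames where limbs sit between sensor footprints — emits
    the all-zeros pattern (every channel at bed height).
    """
    if label == OFF_BED or label == UNDEFINED:
        bits = "000000"
    elif label in TABLE_PATTERNS:
        bits = TABLE_PATTERNS[label].replace("X", "1")
    else:
        raise ConfigError(f"unknown posture label {label!r}")
    on = geometry.sensor_height - geometry.body_elevation
    off = geometry.sensor_height
    return tuple(on if b == "1" else off for b in bits)


def echo_from_distance(d: float, speed: float = SPEED_OF_SOUND) -> float:
    """Round-trip time of flight (s) for a target at distance ``d`` metres.

    Inverse of the ranging rule distance = speed x ToF / 2.
    """
    if speed <= 0:
        raise ValueError("signal speed must be positive")
    if d < 0:
        raise ValueError("distance must be non-negative")
    return 2.0 * d / speed


def random_scenario(
    n_segments: int = 30,
    seed: int = 0,
    noise_sd: float = 0.02,
    min_duration: float = 3.0,
    max_duration: float = 8.0,
    sample_period: float = SAMPLE_PERIOD,
    geometry: Geometry | None = None,
) -> Scenario:
    """Randomized back-to-back schedule over the eight standard postures.

    Adjacent segments always carry different labels (equal neighbours would
    merge into one dwell segment and be indistinguishable downstream).
    Segment durations are uniform on [min_duration, max_duration] seconds.
    """
    from .postures import STANDARD_POSTURES

    if n_segments < 0:
        raise ConfigError("n_segments must be non-negative")
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    t = 0.0
    prev = None
    for _ in range(n_segments):
        choices = [p for p in STANDARD_POSTURES if p != prev]
        label = str(rng.choice(choices))
        duration = float(rng.uniform(min_duration, max_duration))
        segments.append(Segment(label=label, start=t, end=t + duration))
        t += duration
        prev = label
    return Scenario(
        schedule=tuple(segments),
        sample_period=sample_period,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
        geometry=geometry or Geometry(),
    )


def _label_at(schedule: Sequence[Segment], t: float) -> str:
    """Active label at time ``t``; holes between segments read UNDEFINED."""
    for seg in schedule:
        if seg.start <= t < seg.end:
            return seg.label
    return UNDEFINED


def generate_stream(scenario: Scenario) -> list[SensorFrame]:
    """Generate the frame stream for a scenario.

    Frames are placed at integer multiples of ``sample_period`` inside the
    half-open schedule span ``[start, end)``, so adjacent segments never
    double-sample a boundary instant.  Per-frame distances are the posture's
    noise-free distances plus i.i.d. Gaussian noise (sd = ``noise_sd``,
    seeded, clipped at zero).  PIR reads 0 during OFF_BED segments and 1
    otherwise.  An empty schedule yields an empty stream.
    """
    if not scenario.schedule:
        return []
    t0, t_end = scenario.span
    period = scenario.sample_period
    rng = np.random.default_rng(scenario.seed)
    eps = period * 1e-9

    frames: list[SensorFrame] = []
    k = math.ceil(t0 / period - 1e-9)
    while True:
        t = k * period
        if t >= t_end - eps:
            break
        label = _label_at(scenario.schedule, t)
        base = np.array(posture_to_distances(label, scenario.geometry))
        if scenario.noise_sd > 0:
            base = base + rng.normal(0.0, scenario.noise_sd, size=6)
        base = np.maximum(base, 0.0)
        frames.append(
            SensorFrame(
                t=t,
                pir=0 if label == OFF_BED else 1,
                distances=tuple(float(d) for d in base),
            )
        )
        k += 1
    return frames
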