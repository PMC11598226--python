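"""Sensor fusion: echo timing to distance, range validation, bit-word fusion.

The ranging rule is distance = speed x time-of-flight / 2.  Each of the six
channel distances is validated against the sensor's usable window and
thresholded into a presence bit; the six bits form a :class:`FusionWord`
gated by the PIR occupancy flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .geometry import Geometry
from .sim import SPEED_OF_SOUND, SensorFrame


@dataclass(frozen=True)
class FusionWord:
    """Ordered 6-bit presence word (H_R, H_L, A_R, A_L, R_L, L_L).

    A word produced while the PIR flag is 0 is meaningless — no subject is
    on the bed — and carries all-zero bits with ``occupied`` False.
    """

    bits: tuple[int, int, int, int, int, int]
    pir: int = 1
    t: float = 0.0

    def __post_init__(self) -> None:
        if len(self.bits) != 6 or any(b not in (0, 1) for b in self.bits):
            raise ValueError("a fusion word has exactly six bits in {0, 1}")
        if self.pir not in (0, 1):
            raise ValueError("pir must be 0 or 1")

    @classmethod
    def from_string(cls, word: str, pir: int = 1, t: float = 0.0) -> "FusionWord":
        """Build from a 6-character bit string, H_R first."""
        if len(word) != 6 or any(c not in "01" for c in word):
            raise ValueError(f"not a 6-bit word: {word!r}")
        return cls(bits=tuple(int(c) for c in word), pir=pir, t=t)

    @property
    def word(self) -> str:
        """The word as a 6-character bit string, H_R first."""
        return "".join(str(b) for b in self.bits)

    @property
    def occupied(self) -> bool:
        return self.pir == 1


def tof_to_distance(tof: float, speed: float = SPEED_OF_SOUND) -> float:
    """Distance (m) from a round-trip echo time of flight (s)."""
    if speed <= 0:
        raise ValueError("signal speed must be positive")
    if tof < 0:
        raise ValueError("time of flight must be non-negative")
    return speed * tof / 2.0


def validate_range(d: float, geometry: Geometry) -> tuple[float, bool]:
    """Flag whether a distance lies inside the sensor's usable window.

    The window is inclusive on both ends.  Invalid readings are flagged,
    never raised: a streaming system must tolerate dropouts, and downstream
    an invalid channel simply reads as absence.
    """
    if not math.isfinite(d):
        return (d, False)
    return (d, geometry.valid_min <= d <= geometry.valid_max)


def frame_to_word(frame: SensorFrame, geometry: Geometry | None = None) -> FusionWord:
    """Fuse one sensor frame into a PIR-gated presence word.

    A channel bit is 1 iff its distance is inside the valid window and at
    most ``sensor_height - presence_margin`` (something is standing proud of
    the bed plane).  When PIR is 0 the word is emitted unoccupied with all
    bits forced to 0.
    """
    geometry = geometry or Geometry()
    if frame.pir == 0:
        return FusionWord(bits=(0,) * 6, pir=0, t=frame.t)
    threshold = geometry.presence_threshold
    bits = []
    for d in frame.distances:
        _, valid = validate_range(d, geometry)
        bits.append(1 if valid and d <= threshold else 0)
    return FusionWord(bits=tuple(bits), pir=1, t=frame.t)
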