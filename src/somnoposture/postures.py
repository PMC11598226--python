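"""Posture vocabulary and the canonical sensor-fusion truth table.

The monitored bed is scanned by six overhead ultrasonic channels in a fixed
order: head-right, head-left, abdomen-right, abdomen-left, right-leg,
left-leg.  A posture is encoded as a 6-bit presence word over those channels
(1 = body part detected under that sensor).  Eight standard sleep postures
are distinguished; the supine pattern carries don't-care head bits because a
supine sleeper trips both or either head sensor without changing the
posture.
"""

from __future__ import annotations

#: Channel names, in word order (bit 0 is H_R, bit 5 is L_L).
CHANNELS: tuple[str, ...] = ("H_R", "H_L", "A_R", "A_L", "R_L", "L_L")

#: The eight standard sleep postures.
STANDARD_POSTURES: tuple[str, ...] = (
    "RY",   # right yearner
    "LY",   # left yearner
    "LF",   # left fetal
    "RF",   # right fetal
    "RLP",  # right lateral posture
    "LLP",  # left lateral posture
    "SP",   # supine posture
    "FP",   # frog posture
)

#: Canonical presence patterns, one row per standard posture.  'X' marks a
#: don't-care bit (only the supine head bits).
TABLE_PATTERNS: dict[str, str] = {
    "RY": "110101",
    "LY": "111010",
    "LF": "111101",
    "RF": "111110",
    "RLP": "101010",
    "LLP": "010101",
    "SP": "XX1111",
    "FP": "111100",
}

#: Adaptive posture slot labels, New_1 (lowest) through New_8.
ADAPTIVE_SLOTS: tuple[str, ...] = tuple(f"New_{k}" for k in range(1, 9))

UNKNOWN = "UNKNOWN"

# Scenario-only labels understood by the simulator.
OFF_BED = "OFF_BED"
UNDEFINED = "UNDEFINED"

#: Labels a simulation schedule segment may carry.
SCHEDULE_LABELS: tuple[str, ...] = STANDARD_POSTURES + (OFF_BED, UNDEFINED)


def pattern_matches(pattern: str, bits: str) -> bool:
    """True if the 6-bit string ``bits`` matches ``pattern`` (X = don't-care)."""
    if len(pattern) != 6 or len(bits) != 6:
        raise ValueError("patterns and words are exactly 6 symbols long")
    return all(p in ("X", b) for p, b in zip(pattern, bits))
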