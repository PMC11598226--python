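"""Posture learning: FIFO stability detection and bounded subject profiles.

A new posture is accepted only after the fused word has been stable for
three consecutive samples (a 3-deep match FIFO — 0.5 s at the 1/6 s
sampling period).  A stable word matching a standard truth-table row is
registered generically under that label; a stable word matching no row is
an adaptive posture and goes into the lowest free New_1..New_8 slot of the
subject's profile.  At most eight subjects are kept; when a ninth arrives
the least-recently-used profile is evicted.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from .errors import DataError, SlotExhaustedError
from .fusion import FusionWord
from .hbc import DEFAULT_TABLE, PostureTruthTable, classify_by_table
from .postures import ADAPTIVE_SLOTS, STANDARD_POSTURES, UNKNOWN

#: Consecutive identical samples required before a word counts as stable.
STABILITY_DEPTH = 3

#: Capacity bounds of the profile store.
MAX_SUBJECTS = 8
MAX_ADAPTIVE_SLOTS = 8


class MatchFIFO:
    """The three most recent fusion words (slots N-2, N-1, N).

    Capacity is exactly three; pushing evicts the oldest.  The FIFO is
    stable when it is full and all three words are bitwise equal.
    """

    def __init__(self) -> None:
        self._slots: deque[FusionWord] = deque(maxlen=STABILITY_DEPTH)

    def push(self, word: FusionWord) -> bool:
        """Push a word; return True when the FIFO has become stable."""
        if not word.occupied:
            raise ValueError("only occupied (PIR = 1) words enter the FIFO")
        self._slots.append(word)
        return self.stable

    @property
    def stable(self) -> bool:
        if len(self._slots) < STABILITY_DEPTH:
            return False
        first = self._slots[0].bits
        return all(w.bits == first for w in self._slots)

    @property
    def words(self) -> tuple[FusionWord, ...]:
        return tuple(self._slots)

    def clear(self) -> None:
        self._slots.clear()


def push_and_check_stable(fifo: MatchFIFO, word: FusionWord) -> tuple[MatchFIFO, bool]:
    """Functional wrapper around :meth:`MatchFIFO.push`."""
    return fifo, fifo.push(word)


@dataclass
class SubjectProfile:
    """Learned postures of one subject.

    ``learned`` maps standard labels to full 6-bit patterns (generic
    learning); ``adaptive_slots`` maps New_1..New_8 to novel patterns
    (adaptive learning).  Patterns never contain don't-cares: they are
    observed words.
    """

    subject_id: str
    learned: dict[str, str] = field(default_factory=dict)
    adaptive_slots: dict[str, str] = field(default_factory=dict)
    last_used: float = 0.0

    def lookup(self, bits: str) -> str:
        """Label under which this exact pattern is stored, else UNKNOWN."""
        for label, pattern in self.learned.items():
            if pattern == bits:
                return label
        for slot, pattern in self.adaptive_slots.items():
            if pattern == bits:
                return slot
        return UNKNOWN


def register_posture(
    profile: SubjectProfile,
    word: FusionWord,
    table: PostureTruthTable | None = None,
) -> str:
    """Register a stable word in the profile; return the label it got.

    Words matching a standard table row overwrite that label's stored
    pattern (re-learning).  Novel words reuse the slot already holding the
    same pattern, or claim the lowest free New_k slot.
    """
    table = table or DEFAULT_TABLE
    bits = word.word
    label = classify_by_table(bits, table)
    if label in STANDARD_POSTURES:
        profile.learned[label] = bits
        return label
    for slot, pattern in profile.adaptive_slots.items():
        if pattern == bits:
            return slot
    for slot in ADAPTIVE_SLOTS:
        if slot not in profile.adaptive_slots:
            profile.adaptive_slots[slot] = bits
            return slot
    raise SlotExhaustedError(
        f"all {MAX_ADAPTIVE_SLOTS} adaptive slots of subject "
        f"{profile.subject_id!r} are occupied; cannot learn {bits}"
    )


class ProfileStore:
    """Bounded store of subject profiles (at most eight subjects)."""

    def __init__(self) -> None:
        self.subjects: dict[str, SubjectProfile] = {}

    def __len__(self) -> int:
        return len(self.subjects)

    def match_or_create_subject(self, subject_id: str, now: float) -> SubjectProfile:
        """Fetch (touching ``last_used``) or create a subject profile.

        A new subject arriving at capacity evicts the least-recently-used
        profile — the reading of "replace unused subject data".
        """
        if subject_id in self.subjects:
            profile = self.subjects[subject_id]
            profile.last_used = now
            return profile
        if len(self.subjects) >= MAX_SUBJECTS:
            lru = min(self.subjects.values(), key=lambda p: p.last_used)
            del self.subjects[lru.subject_id]
        profile = SubjectProfile(subject_id=subject_id, last_used=now)
        self.subjects[subject_id] = profile
        return profile

    def best_match(self, word: FusionWord) -> tuple[str, str, int] | None:
        """Heuristic: (subject_id, label, Hamming distance) of the stored
        pattern closest to ``word``, or None when the store is empty.

        The original system never defines subject recognition; this helper
        only reports the nearest stored pattern and must not be mistaken
        for biometric identification.
        """
        best: tuple[str, str, int] | None = None
        for profile in self.subjects.values():
            entries = list(profile.learned.items()) + list(
                profile.adaptive_slots.items()
            )
            for label, pattern in entries:
                dist = sum(a != b for a, b in zip(pattern, word.word))
                if best is None or dist < best[2]:
                    best = (profile.subject_id, label, dist)
        return best

    # -- persistence ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "subjects": [
                {
                    "subject_id": p.subject_id,
                    "learned": dict(p.learned),
                    "adaptive_slots": dict(p.adaptive_slots),
                    "last_used": datetime.fromtimestamp(
                        p.last_used, tz=timezone.utc
                    ).isoformat(),
                }
                for p in self.subjects.values()
            ]
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ProfileStore":
        store = cls()
        try:
            entries = data["subjects"]
        except (TypeError, KeyError) as exc:
            raise DataError("profile store JSON lacks a 'subjects' list") from exc
        if len(entries) > MAX_SUBJECTS:
            raise DataError(
                f"profile store holds {len(entries)} subjects; limit is "
                f"{MAX_SUBJECTS}"
            )
        for entry in entries:
            try:
                profile = SubjectProfile(
                    subject_id=entry["subject_id"],
                    learned=dict(entry.get("learned", {})),
                    adaptive_slots=dict(entry.get("adaptive_slots", {})),
                    last_used=datetime.fromisoformat(
                        entry["last_used"]
                    ).timestamp(),
                )
            except (TypeError, KeyError, ValueError) as exc:
                raise DataError(f"malformed subject entry: {entry!r}") from exc
            if len(profile.adaptive_slots) > MAX_ADAPTIVE_SLOTS:
                raise DataError(
                    f"subject {profile.subject_id!r} exceeds the "
                    f"{MAX_ADAPTIVE_SLOTS}-slot adaptive bound"
                )
            store.subjects[profile.subject_id] = profile
        return store

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ProfileStore":
        try:
            data = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise DataError(f"invalid profile store JSON at {path}") from exc
        return cls.from_dict(data)
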