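"""Posture learning: FIFO stability, generic/adaptive registration, bounds."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnoposture import (
    FusionWord,
    MatchFIFO,
    ProfileStore,
    SlotExhaustedError,
    SubjectProfile,
    TABLE_PATTERNS,
    generate_stream,
    register_posture,
)
from somnoposture.learning import MAX_ADAPTIVE_SLOTS, MAX_SUBJECTS
from somnoposture.pipeline import learn_frames


def word(bits: str) -> FusionWord:
    return FusionWord.from_string(bits)


class TestMatchFIFO:
    def test_three_identical_pushes_are_stable(self):
        fifo = MatchFIFO()
        assert not fifo.push(word("110101"))
        assert not fifo.push(word("110101"))
        assert fifo.push(word("110101"))

    def test_two_pushes_not_stable(self):
        fifo = MatchFIFO()
        fifo.push(word("110101"))
        assert not fifo.push(word("110101"))

    def test_mismatch_breaks_stability(self):
        fifo = MatchFIFO()
        for bits in ("110101", "110101", "111010"):
            stable = fifo.push(word(bits))
        assert not stable

    def test_oldest_evicted_on_push(self):
        fifo = MatchFIFO()
        for bits in ("111010", "110101", "110101", "110101"):
            stable = fifo.push(word(bits))
        assert stable  # the odd word aged out of the 3-deep window

    def test_unoccupied_word_rejected(self):
        with pytest.raises(ValueError, match="PIR"):
            MatchFIFO().push(FusionWord.from_string("110101", pir=0))


class TestRegisterPosture:
    def test_standard_word_learned_under_its_label(self):
        profile = SubjectProfile("s1")
        assert register_posture(profile, word("110101")) == "RY"
        assert profile.learned["RY"] == "110101"
        assert profile.adaptive_slots == {}

    def test_novel_word_takes_lowest_free_slot(self):
        profile = SubjectProfile("s1")
        assert register_posture(profile, word("100110")) == "New_1"
        assert register_posture(profile, word("100111")) == "New_2"
        assert profile.adaptive_slots["New_1"] == "100110"

    def test_generic_relearning_is_idempotent(self):
        profile = SubjectProfile("s1")
        register_posture(profile, word("110101"))
        snapshot = (dict(profile.learned), dict(profile.adaptive_slots))
        register_posture(profile, word("110101"))
        assert (dict(profile.learned), dict(profile.adaptive_slots)) == snapshot

    def test_known_novel_word_reuses_its_slot(self):
        profile = SubjectProfile("s1")
        register_posture(profile, word("100110"))
        assert register_posture(profile, word("100110")) == "New_1"
        assert len(profile.adaptive_slots) == 1

    def test_ninth_novel_word_exhausts_slots(self):
        profile = SubjectProfile("pat")
        novel = ["100110", "100111", "001001", "010010", "011011",
                 "000001", "000010", "000100"]
        for bits in novel:
            register_posture(profile, word(bits))
        assert len(profile.adaptive_slots) == MAX_ADAPTIVE_SLOTS
        with pytest.raises(SlotExhaustedError, match="pat"):
            register_posture(profile, word("001100"))


class TestProfileStore:
    def test_known_id_returns_same_profile_and_touches_it(self):
        store = ProfileStore()
        p1 = store.match_or_create_subject("a", now=1.0)
        p2 = store.match_or_create_subject("a", now=2.0)
        assert p1 is p2
        assert p1.last_used == 2.0
        assert len(store) == 1

    def test_ninth_subject_evicts_least_recently_used(self):
        store = ProfileStore()
        for i in range(MAX_SUBJECTS):
            store.match_or_create_subject(f"s{i}", now=float(i))
        store.match_or_create_subject("s0", now=100.0)  # refresh the oldest
        store.match_or_create_subject("s8", now=101.0)
        assert len(store) == MAX_SUBJECTS
        assert "s1" not in store.subjects  # the stale one went
        assert "s0" in store.subjects and "s8" in store.subjects

    @given(
        ops=st.lists(
            st.tuples(st.integers(0, 11), st.sampled_from(["110101", "100110",
                                                           "011011", "000111"])),
            max_size=60,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_capacity_bounds_hold_under_random_sequences(self, ops):
        store = ProfileStore()
        now = 0.0
        for subject, bits in ops:
            now += 1.0
            profile = store.match_or_create_subject(f"s{subject}", now)
            try:
                register_posture(profile, word(bits))
            except SlotExhaustedError:
                pass
            assert len(store) <= MAX_SUBJECTS
            assert all(
                len(p.adaptive_slots) <= MAX_ADAPTIVE_SLOTS
                for p in store.subjects.values()
            )

    def test_json_round_trip(self, tmp_path):
        store = ProfileStore()
        profile = store.match_or_create_subject("s1", now=1700000000.0)
        register_posture(profile, word("110101"))
        register_posture(profile, word("100110"))
        path = tmp_path / "profiles.json"
        store.save(path)
        loaded = ProfileStore.load(path)
        again = loaded.subjects["s1"]
        assert again.learned == {"RY": "110101"}
        assert again.adaptive_slots == {"New_1": "100110"}
        assert again.last_used == pytest.approx(1700000000.0)
        # persisted form is readable JSON with ISO timestamps
        raw = json.loads(path.read_text())
        assert raw["subjects"][0]["last_used"].startswith("2023-")

    def test_best_match_reports_nearest_pattern(self):
        store = ProfileStore()
        profile = store.match_or_create_subject("s1", now=1.0)
        register_posture(profile, word("110101"))
        subject, label, dist = store.best_match(word("110100"))
        assert (subject, label, dist) == ("s1", "RY", 1)


class TestLearningRoundTrip:
    @pytest.mark.parametrize("label", sorted(TABLE_PATTERNS))
    def test_zero_noise_stream_learns_the_table_row(
        self, single_segment_scenario, label
    ):
        frames = generate_stream(single_segment_scenario(label=label, duration=2.0))
        profile = SubjectProfile("s1")
        registered, occupied = learn_frames(frames, profile)
        assert registered == [label]
        assert occupied == len(frames)
        assert profile.learned[label] == TABLE_PATTERNS[label].replace("X", "1")
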