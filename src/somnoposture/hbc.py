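"""Hierarchical binary classifier (HBC) over 6-bit posture words.

Two equivalent views of the same mapping:

* :class:`PostureTruthTable` — the canonical pattern table with don't-care
  bits, classified by linear scan (:func:`classify_by_table`).  This is the
  oracle form.
* :class:`HBCTree` — the early-exit decision tree compiled from the table
  by :func:`build_tree`: the leg pair is tested first (00 = frog, 11 =
  supine), then the abdomen pair (11 = fetal), then the head pair (yearner
  vs lateral).  At most three two-bit tests decide any word.

:func:`classify` walks the tree.  In the default (non-strict) mode bits off
the tested path are ignored, mirroring the early exit; in strict mode the
tree's answer is additionally checked against the full table pattern and
demoted to UNKNOWN on mismatch, which is the right contract when a learned
reference must be a complete pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence, Union

from .errors import ConfigError
from .fusion import FusionWord
from .postures import (
    STANDARD_POSTURES,
    TABLE_PATTERNS,
    UNKNOWN,
    pattern_matches,
)

WordLike = Union[FusionWord, str, Sequence[int]]

#: Bit-pair levels in hierarchy order: legs first, then abdomen, then head.
_PAIR_LEVELS: tuple[tuple[str, tuple[int, int]], ...] = (
    ("legs", (4, 5)),
    ("abdomen", (2, 3)),
    ("head", (0, 1)),
)


def _as_bits(word: WordLike) -> str:
    if isinstance(word, FusionWord):
        return word.word
    if isinstance(word, str):
        if len(word) != 6 or any(c not in "01" for c in word):
            raise ValueError(f"not a 6-bit word: {word!r}")
        return word
    bits = "".join(str(int(b)) for b in word)
    if len(bits) != 6 or any(c not in "01" for c in bits):
        raise ValueError(f"not a 6-bit word: {word!r}")
    return bits


class PostureTruthTable:
    """Pattern rows (6 symbols over {0, 1, X}) mapped to posture labels.

    The default rows are the eight canonical standard-posture patterns.
    Construction rejects ambiguous tables: no 6-bit word may match two rows
    with different labels.
    """

    def __init__(self, rows: Mapping[str, str] | None = None) -> None:
        if rows is None:
            rows = {pattern: label for label, pattern in TABLE_PATTERNS.items()}
        self.rows: dict[str, str] = {}
        for pattern, label in rows.items():
            if len(pattern) != 6 or any(c not in "01X" for c in pattern):
                raise ConfigError(
                    f"invalid pattern {pattern!r}: 6 symbols over 0/1/X"
                )
            self.rows[pattern] = label
        # ambiguity guard: exhaustive scan of all 64 words
        for bits in ("".join(p) for p in product("01", repeat=6)):
            labels = {
                label
                for pattern, label in self.rows.items()
                if pattern_matches(pattern, bits)
            }
            if len(labels) > 1:
                raise ConfigError(
                    f"ambiguous truth table: word {bits} matches rows for "
                    f"{sorted(labels)}"
                )

    def pattern_for(self, label: str) -> str | None:
        for pattern, row_label in self.rows.items():
            if row_label == label:
                return pattern
        return None

    def matching_words(self) -> dict[str, str]:
        """All 6-bit words matching some row, mapped to their row label."""
        out = {}
        for bits in ("".join(p) for p in product("01", repeat=6)):
            for pattern, label in self.rows.items():
                if pattern_matches(pattern, bits):
                    out[bits] = label
        return out


DEFAULT_TABLE = PostureTruthTable()


def classify_by_table(
    word: WordLike, table: PostureTruthTable | None = None
) -> str:
    """Linear-scan oracle: the row label matching the full word, else UNKNOWN."""
    table = table or DEFAULT_TABLE
    bits = _as_bits(word)
    for pattern, label in table.rows.items():
        if pattern_matches(pattern, bits):
            return label
    return UNKNOWN


@dataclass(frozen=True)
class _Leaf:
    label: str


@dataclass(frozen=True)
class _PairTest:
    """Equality-test chain on one bit pair; unmatched values fall through."""

    level: str
    pair: tuple[int, int]
    branches: tuple[tuple[str, "_Node"], ...]
    default: "_Node"


_Node = Union[_Leaf, _PairTest]


@dataclass(frozen=True)
class HBCTree:
    """Early-exit decision tree, at most three two-bit tests deep."""

    root: _Node
    table: PostureTruthTable = field(default_factory=lambda: DEFAULT_TABLE)

    def walk(self, bits: str) -> str:
        node = self.root
        while isinstance(node, _PairTest):
            value = bits[node.pair[0]] + bits[node.pair[1]]
            for branch_value, child in node.branches:
                if value == branch_value:
                    node = child
                    break
            else:
                node = node.default
        return node.label


def _pair_values(pattern: str, pair: tuple[int, int]) -> list[str]:
    """Concrete 2-bit values a pattern's pair can take (X expands)."""
    choices = [("01" if pattern[i] == "X" else pattern[i]) for i in pair]
    return [a + b for a in choices[0] for b in choices[1]]


def _build(rows: list[tuple[str, str]], level: int) -> _Node:
    if len({label for _, label in rows}) == 1:
        return _Leaf(rows[0][1])
    if level >= len(_PAIR_LEVELS):
        raise ConfigError(
            "truth-table rows are not separable by the three bit-pair tests: "
            + ", ".join(f"{p}->{l}" for p, l in rows)
        )
    name, pair = _PAIR_LEVELS[level]
    groups: dict[str, list[tuple[str, str]]] = {}
    for pattern, label in rows:
        for value in _pair_values(pattern, pair):
            groups.setdefault(value, []).append((pattern, label))
    # early exit: test small groups first; the last group is the fall-through
    ordered = sorted(groups.items(), key=lambda kv: (len(kv[1]), kv[0]))
    branches = tuple(
        (value, _build(group, level + 1)) for value, group in ordered[:-1]
    )
    default = _build(ordered[-1][1], level + 1)
    return _PairTest(level=name, pair=pair, branches=branches, default=default)


def build_tree(table: PostureTruthTable | None = None) -> HBCTree:
    """Compile a truth table into the early-exit tree.

    The compiled tree is verified exhaustively: on every 6-bit word that
    matches some table row, the tree must return that row's label.  Tables
    whose rows cannot be separated by the leg/abdomen/head pair hierarchy
    are rejected.
    """
    table = table or DEFAULT_TABLE
    if not table.rows:
        raise ConfigError("cannot build a tree from an empty truth table")
    tree = HBCTree(root=_build(list(table.rows.items()), 0), table=table)
    for bits, label in table.matching_words().items():
        if tree.walk(bits) != label:
            raise ConfigError(
                f"tree/table disagreement on {bits}: "
                f"tree={tree.walk(bits)} table={label}"
            )
    return tree


DEFAULT_TREE = build_tree(DEFAULT_TABLE)


def classify(
    word: FusionWord, tree: HBCTree | None = None, strict: bool = False
) -> str:
    """Classify a PIR-gated fusion word.

    Unoccupied words (PIR = 0) classify as UNKNOWN.  Non-strict mode
    returns the early-exit tree result, total over all 64 words; strict
    mode returns the tree result only when the full word matches that
    label's table pattern, else UNKNOWN.
    """
    tree = tree or DEFAULT_TREE
    if isinstance(word, FusionWord) and not word.occupied:
        return UNKNOWN
    bits = _as_bits(word)
    label = tree.walk(bits)
    if strict:
        pattern = tree.table.pattern_for(label)
        if pattern is None or not pattern_matches(pattern, bits):
            return UNKNOWN
    return label


__all__ = [
    "PostureTruthTable",
    "HBCTree",
    "DEFAULT_TABLE",
    "DEFAULT_TREE",
    "build_tree",
    "classify",
    "classify_by_table",
    "STANDARD_POSTURES",
    "UNKNOWN",
]
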