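"""Binary pattern strings and prediction-task sequences.

A pattern is a short binary motif with one third zeros and two thirds
ones.  Repeating a pattern yields a *periodic* task sequence; shuffling
that sequence uniformly yields the frequency-matched *shuffled* control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_PATTERN_LENGTHS",
    "CANONICAL_SEQUENCE_LENGTH",
    "LENGTH3_PATTERNS",
    "PatternString",
    "TaskSequence",
    "generate_pattern",
    "make_periodic_sequence",
    "shuffle_sequence",
    "read_pattern_file",
    "write_pattern_file",
    "sequence_to_csv",
    "sequence_from_csv",
]

#: Motif lengths used by the canonical experiment grid.
CANONICAL_PATTERN_LENGTHS: tuple[int, ...] = (3, 9, 27, 81, 243, 729)

#: Total length of every canonical task sequence.
CANONICAL_SEQUENCE_LENGTH: int = 2916

#: The only three binary strings of length 3 with a single zero.
LENGTH3_PATTERNS: tuple[str, ...] = ("011", "101", "110")


def _as_rng(rng: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class PatternString:
    """An ordered binary motif.

    Parameters
    ----------
    digits
        Tuple of 0/1 integers.  Canonical patterns have exactly
        ``len(digits) / 3`` zeros, but arbitrary compositions are
        accepted to support generalisation experiments.
    """

    digits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.digits) == 0:
            raise ValueError("pattern must contain at least one digit")
        if any(d not in (0, 1) for d in self.digits):
            raise ValueError("pattern digits must be 0 or 1")
        object.__setattr__(self, "digits", tuple(int(d) for d in self.digits))

    @classmethod
    def from_string(cls, text: str) -> "PatternString":
        text = text.strip()
        if not text or set(text) - {"0", "1"}:
            raise ValueError(f"not a binary string: {text!r}")
        return cls(tuple(int(c) for c in text))

    @property
    def length(self) -> int:
        return len(self.digits)

    @property
    def n_zeros(self) -> int:
        return self.length - sum(self.digits)

    @property
    def is_canonical_composition(self) -> bool:
        """True when exactly one third of the digits are zeros."""
        return self.length % 3 == 0 and self.n_zeros * 3 == self.length

    def __str__(self) -> str:
        return "".join(str(d) for d in self.digits)

    def __len__(self) -> int:
        return len(self.digits)


@dataclass(frozen=True, eq=False)
class TaskSequence:
    """A full-length binary sequence an animat is asked to predict."""

    elements: np.ndarray
    kind: str  # "periodic" | "shuffled"
    source_pattern: PatternString

    def __post_init__(self) -> None:
        elements = np.ascontiguousarray(self.elements, dtype=np.int8)
        if elements.ndim != 1 or elements.size == 0:
            raise ValueError("sequence must be a non-empty 1-D array")
        if not np.isin(elements, (0, 1)).all():
            raise ValueError("sequence elements must be 0 or 1")
        if self.kind not in ("periodic", "shuffled"):
            raise ValueError(f"unknown sequence kind: {self.kind!r}")
        elements.setflags(write=False)
        object.__setattr__(self, "elements", elements)

    @property
    def length(self) -> int:
        return int(self.elements.size)

    @property
    def n_ones(self) -> int:
        return int(self.elements.sum())

    @property
    def n_zeros(self) -> int:
        return self.length - self.n_ones

    def __len__(self) -> int:
        return self.length

    def __str__(self) -> str:
        return "".join(str(int(e)) for e in self.elements)


def generate_pattern(
    length: int,
    rng: int | np.random.Generator | np.random.SeedSequence,
    *,
    n_zeros: int | None = None,
) -> PatternString:
    """Draw a uniformly random pattern with a fixed digit composition.

    By default the composition is the canonical one third zeros / two
    thirds ones, which requires ``length`` to be a positive multiple of
    3.  Pass ``n_zeros`` explicitly to generalise.
    """
    if n_zeros is None:
        if length < 3 or length % 3 != 0:
            raise ValueError(
                f"canonical pattern length must be >= 3 and divisible by 3, got {length}"
            )
        n_zeros = length // 3
    if not 0 <= n_zeros <= length:
        raise ValueError(f"n_zeros={n_zeros} out of range for length {length}")
    digits = np.ones(length, dtype=np.int8)
    digits[:n_zeros] = 0
    digits = _as_rng(rng).permutation(digits)
    return PatternString(tuple(int(d) for d in digits))


def make_periodic_sequence(
    pattern: PatternString | str,
    total_length: int = CANONICAL_SEQUENCE_LENGTH,
) -> TaskSequence:
    """Repeat ``pattern`` until the sequence reaches ``total_length``."""
    if isinstance(pattern, str):
        pattern = PatternString.from_string(pattern)
    if total_length <= 0 or total_length % pattern.length != 0:
        raise ValueError(
            f"total length {total_length} is not a positive multiple of the "
            f"pattern length {pattern.length}"
        )
    reps = total_length // pattern.length
    elements = np.tile(np.asarray(pattern.digits, dtype=np.int8), reps)
    return TaskSequence(elements=elements, kind="periodic", source_pattern=pattern)


def shuffle_sequence(
    sequence: TaskSequence,
    rng: int | np.random.Generator | np.random.SeedSequence,
) -> TaskSequence:
    """Uniform random permutation of a sequence's elements.

    Destroys periodic structure while preserving the digit multiset.
    """
    shuffled = _as_rng(rng).permutation(sequence.elements)
    return TaskSequence(
        elements=shuffled, kind="shuffled", source_pattern=sequence.source_pattern
    )


# ---------------------------------------------------------------------------
# plain-text I/O

def read_pattern_file(path) -> list[PatternString]:
    """Read one binary string per non-empty line."""
    with open(path) as fh:
        return [PatternString.from_string(line) for line in fh if line.strip()]


def write_pattern_file(patterns, path) -> None:
    with open(path, "w") as fh:
        for p in patterns:
            fh.write(f"{p}\n")


def sequence_to_csv(sequence: TaskSequence, path) -> None:
    """Dump as a two-column CSV: 0-based time index, element."""
    frame = pd.DataFrame(
        {"t": np.arange(sequence.length), "element": sequence.elements}
    )
    frame.to_csv(path, index=False)


def sequence_from_csv(path, *, kind: str, source_pattern: PatternString) -> TaskSequence:
    frame = pd.read_csv(path)
    frame = frame.sort_values("t")
    return TaskSequence(
        elements=frame["element"].to_numpy(dtype=np.int8),
        kind=kind,
        source_pattern=source_pattern,
    )
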