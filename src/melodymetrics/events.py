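"""Monophonic note-event representation.

All timing is in seconds; tick arithmetic lives at the MIDI I/O boundary
only, so every downstream measure is tempo-map agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from melodymetrics.errors import DomainError, InsufficientDataError

SESSIONS = ("m0", "m3", "m6", "m9", "m12", "m15", "m18")
INSTRUMENTS = ("kbipK", "kbipI")


@dataclass(frozen=True)
class NoteEvent:
    """One sounded note.

    pitch     MIDI note number, 0-127 (semitone units; 60 = C4)
    onset     start time in seconds, >= 0
    offset    end time in seconds, strictly > onset
    velocity  MIDI key velocity, 1-127 (loudness proxy)
    """

    pitch: int
    onset: float
    offset: float
    velocity: int = 64

    def __post_init__(self) -> None:
        if not 0 <= self.pitch <= 127:
            raise DomainError(f"pitch {self.pitch} outside MIDI range 0-127")
        if not 1 <= self.velocity <= 127:
            raise DomainError(f"velocity {self.velocity} outside MIDI range 1-127")
        if self.onset < 0:
            raise DomainError(f"onset {self.onset} < 0")
        if self.offset <= self.onset:
            raise DomainError(
                f"offset {self.offset} must exceed onset {self.onset}"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class PerformanceMetadata:
    """Session bookkeeping attached to a performance.

    imprct / repct are the counts of completed 3-month improvisation and
    replication training blocks (each 0-2, sum <= 4); nimptasks is the
    number of improvisation methods the performer claims to have applied;
    claimed_tasks the identities of those methods (1-14).
    """

    participant_id: Optional[str] = None
    group: Optional[str] = None
    session: Optional[str] = None
    item: Optional[int] = None
    instrument: Optional[str] = None
    imprct: Optional[int] = None
    repct: Optional[int] = None
    nimptasks: Optional[int] = None
    claimed_tasks: tuple = ()

    def __post_init__(self) -> None:
        if self.session is not None and self.session not in SESSIONS:
            raise DomainError(f"session {self.session!r} not in {SESSIONS}")
        if self.instrument is not None and self.instrument not in INSTRUMENTS:
            raise DomainError(f"instrument {self.instrument!r} not in {INSTRUMENTS}")
        if self.item is not None and not 1 <= self.item <= 5:
            raise DomainError(f"item {self.item} outside 1-5")
        if (
            self.imprct is not None
            and self.repct is not None
            and self.imprct + self.repct > 4
        ):
            raise DomainError("imprct + repct exceeds the 4 training blocks")
        if any(not 1 <= t <= 14 for t in self.claimed_tasks):
            raise DomainError("claimed_tasks entries must be in 1-14")


def _sorted_notes(notes: Iterable[NoteEvent]) -> list[NoteEvent]:
    return sorted(notes, key=lambda n: (n.onset, n.pitch))


@dataclass
class Performance:
    """Ordered monophonic note sequence plus metadata.

    Notes are kept sorted by onset (ties broken by pitch). Monophony is
    not enforced at construction; ``extract_monophonic`` resolves
    overlaps explicitly.
    """

    notes: list[NoteEvent] = field(default_factory=list)
    metadata: PerformanceMetadata = field(default_factory=PerformanceMetadata)

    def __post_init__(self) -> None:
        self.notes = _sorted_notes(self.notes)

    def __len__(self) -> int:
        return len(self.notes)

    @property
    def pitches(self) -> np.ndarray:
        return np.array([n.pitch for n in self.notes], dtype=int)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([n.onset for n in self.notes], dtype=float)

    @property
    def offsets(self) -> np.ndarray:
        return np.array([n.offset for n in self.notes], dtype=float)

    @property
    def velocities(self) -> np.ndarray:
        return np.array([n.velocity for n in self.notes], dtype=int)

    @property
    def durations(self) -> np.ndarray:
        return self.offsets - self.onsets

    def is_monophonic(self) -> bool:
        return all(
            a.offset <= b.onset for a, b in zip(self.notes, self.notes[1:])
        )

    def shifted(self, dt: float) -> "Performance":
        """Return a copy with all times shifted by ``dt`` seconds."""
        return Performance(
            [replace(n, onset=n.onset + dt, offset=n.offset + dt) for n in self.notes],
            self.metadata,
        )


def extract_monophonic(performance: Performance) -> Performance:
    """Resolve overlaps by truncating the earlier note at the next onset.

    Truncation (rather than deletion) preserves the pitch sequence, which
    the replication measures privilege over duration. Notes whose
    truncated duration would be zero or negative are dropped. Idempotent.
    """
    out: list[NoteEvent] = []
    notes = performance.notes
    for i, note in enumerate(notes):
        offset = note.offset
        if i + 1 < len(notes):
            offset = min(offset, notes[i + 1].onset)
        if offset > note.onset:
            out.append(replace(note, offset=offset))
    return Performance(out, performance.metadata)


def compute_iois(performance: Performance | Sequence[NoteEvent]) -> np.ndarray:
    """Inter-onset intervals: time between successive note onsets.

    Returns n-1 values for n notes; raises if fewer than two notes.
    """
    notes = performance.notes if isinstance(performance, Performance) else list(performance)
    if len(notes) < 2:
        raise InsufficientDataError("need >= 2 notes to compute inter-onset intervals")
    onsets = np.array([n.onset for n in notes], dtype=float)
    return np.diff(onsets)
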