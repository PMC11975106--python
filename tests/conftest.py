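"""Shared fixtures and performance-building helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from melodymetrics.events import NoteEvent, Performance

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_performance(
    pitches,
    iois=0.5,
    durations=None,
    velocities=64,
    start=0.0,
) -> Performance:
    """Build a monophonic performance from parallel per-note values.

    Scalars broadcast; ``iois`` gives the onset spacing (the last note's
    slot too), ``durations`` default to 0.9 x IOI.
    """
    n = len(pitches)
    iois = np.broadcast_to(np.asarray(iois, float), (n,)).copy()
    if durations is None:
        durations = 0.9 * iois
    durations = np.broadcast_to(np.asarray(durations, float), (n,)).copy()
    velocities = np.broadcast_to(np.asarray(velocities, int), (n,)).copy()
    notes = []
    onset = start
    for p, ioi, dur, vel in zip(pitches, iois, durations, velocities):
        notes.append(NoteEvent(int(p), onset, onset + min(dur, ioi), int(vel)))
        onset += ioi
    return Performance(notes)


@pytest.fixture
def scale_run() -> Performance:
    """An ascending C-major-ish run, isochronous."""
    return make_performance([60, 62, 64, 65, 67, 69, 71, 72])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
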