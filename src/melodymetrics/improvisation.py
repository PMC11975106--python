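"""Improvisation feature measures.

Eighteen "scoretypes" quantifying the structured variation a monophonic
improvisation contains. The M-number in a field name indicates which of
the 14 taught melodic-variation methods the measure is most selective
for (repeats, passing notes, interval spread, rhythm, dynamics, accents,
rests, tempo variation, articulation, retrograde, sequence,
modulation); ``TASK_SCORETYPE`` maps each method to its designated
measure. Measures whose preconditions are not met are flagged missing
(NaN), never silently zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from melodymetrics.errors import InsufficientDataError
from melodymetrics.events import Performance, compute_iois
from melodymetrics.replication import IOI_BIN_EDGES

RUN_MIN = 3  # minimum notes in a crescendo/diminuendo run
VEL_MIN = 10  # minimum total velocity change across a run
ACCENT_DELTA = 15  # velocity excess over local context to count as accent
ACCENT_WINDOW = 5  # centred context window (self excluded) for accents
PASSING_MAX_STEP = 2  # semitone ceiling for a "passing/neighbour" step
IOI_WINDOW = 4  # IOIs per sliding window for the tempo-variation stats
PATTERN_MIN_LEN = 3  # minimum notes in a retrograde/sequence occurrence

# Taught method -> scoretype index (1-based position in SCORETYPE_ORDER).
# Several articulation methods (9-11) share scoretype 17, and the
# modulation method (14) shares the interval-range scoretype with
# method 3.
TASK_SCORETYPE = {
    1: 8, 2: 9, 3: 3, 4: 4, 5: 10, 6: 11, 7: 12,
    8: 18, 9: 17, 10: 17, 11: 17, 12: 15, 13: 16, 14: 3,
}

SCORETYPE_ORDER = (
    "NumNotes",
    "M1pintervaldivers",
    "M1pintervalrange",
    "M2ioidivers",
    "M2ioirange",
    "M3pitchdivers",
    "M3prange",
    "M4repeatnotes",
    "M5Passnotesprop",
    "M6crescdim",
    "M7AccentProp",
    "M8silenceprop",
    "M9windioirange",
    "M12VaryStaccLeg",
    "M13retronotes",
    "M14sequences",
    "M12aStaccLegabsdiff",
    "M9aWindioiabsdiff",
)


@dataclass
class ImprovScores:
    NumNotes: float
    M1pintervaldivers: float
    M1pintervalrange: float
    M2ioidivers: float
    M2ioirange: float
    M3pitchdivers: float
    M3prange: float
    M4repeatnotes: float
    M5Passnotesprop: float
    M6crescdim: float
    M7AccentProp: float
    M8silenceprop: float
    M9windioirange: float
    M12VaryStaccLeg: float
    M13retronotes: float
    M14sequences: float
    M12aStaccLegabsdiff: float
    M9aWindioiabsdiff: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in SCORETYPE_ORDER}

    def by_index(self, scoretype: int) -> float:
        """Scoretype by its 1-based index in the canonical ordering."""
        return getattr(self, SCORETYPE_ORDER[scoretype - 1])


def num_notes(perf: Performance) -> int:
    return len(perf)


def diversity(values: Sequence) -> float:
    """Shannon entropy (bits) of the value distribution.

    Degenerate (all-identical) input scores 0; k equally frequent
    distinct values score log2(k).
    """
    values = list(values)
    if not values:
        raise InsufficientDataError("diversity of an empty sequence")
    _, counts = np.unique(np.asarray(values), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def value_range(values: Sequence[float]) -> float:
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise InsufficientDataError("range of an empty sequence")
    return float(values.max() - values.min())


def _discretize_iois(iois: np.ndarray) -> np.ndarray:
    """Bin IOIs by log2 ratio to the median (13 fixed bins)."""
    ratios = np.log2(iois / np.median(iois))
    return np.digitize(ratios, IOI_BIN_EDGES[1:-1])


def repeat_notes(perf: Performance) -> int:
    """Notes whose pitch equals the immediately preceding note's pitch."""
    if len(perf) == 0:
        raise InsufficientDataError("repeat count of an empty performance")
    p = perf.pitches
    return int(np.count_nonzero(p[1:] == p[:-1]))


def passing_notes_prop(perf: Performance) -> float:
    """Proportion of notes within 1-2 semitones of their antecedent."""
    if len(perf) < 2:
        raise InsufficientDataError("passing-note proportion needs >= 2 notes")
    steps = np.abs(np.diff(perf.pitches))
    return float(np.count_nonzero((steps >= 1) & (steps <= PASSING_MAX_STEP)) / steps.size)


def cresc_dim_count(perf: Performance) -> int:
    """Count of crescendos/diminuendos: maximal strictly monotone
    velocity runs of >= RUN_MIN notes spanning >= VEL_MIN velocity units."""
    v = perf.velocities
    if v.size < RUN_MIN:
        return 0
    count = 0
    for direction in (1, -1):
        start = 0
        for i in range(1, v.size + 1):
            if i == v.size or (v[i] - v[i - 1]) * direction <= 0:
                if i - start >= RUN_MIN and abs(int(v[i - 1]) - int(v[start])) >= VEL_MIN:
                    count += 1
                start = i - 1 if i < v.size else i
    return count


def accent_prop(perf: Performance) -> float:
    """Proportion of notes >= ACCENT_DELTA louder than their local context.

    Context is a centred ACCENT_WINDOW-note window, edge-truncated and
    excluding the note itself.
    """
    if len(perf) < 3:
        raise InsufficientDataError("accent proportion needs >= 3 notes")
    v = perf.velocities.astype(float)
    half = ACCENT_WINDOW // 2
    accents = 0
    for i in range(v.size):
        lo, hi = max(0, i - half), min(v.size, i + half + 1)
        context = np.concatenate([v[lo:i], v[i + 1 : hi]])
        if v[i] - context.mean() >= ACCENT_DELTA:
            accents += 1
    return accents / v.size


def silence_prop(perf: Performance) -> float:
    """Proportion of performed time (first onset to last offset) silent."""
    if len(perf) < 2:
        raise InsufficientDataError("silence proportion needs >= 2 notes")
    gaps = perf.onsets[1:] - perf.offsets[:-1]
    span = perf.offsets[-1] - perf.onsets[0]
    return float(np.clip(gaps, 0.0, None).sum() / span)


def windowed_ioi_stats(perf: Performance, window: int = IOI_WINDOW) -> tuple[float, float]:
    """Tempo-variation stats over sliding windows of IOIs.

    Window means of ``window`` consecutive IOIs (step 1); returns
    (range of the means, mean absolute successive-mean difference) in
    seconds.
    """
    if len(perf) < window + 1:
        raise InsufficientDataError(f"windowed IOI stats need >= {window + 1} notes")
    iois = compute_iois(perf)
    means = np.convolve(iois, np.ones(window) / window, mode="valid")
    rng = float(means.max() - means.min())
    absdiff = float(np.abs(np.diff(means)).mean()) if means.size > 1 else 0.0
    return rng, absdiff


def articulation_stats(perf: Performance) -> tuple[float, float]:
    """Staccato/legato stats from duration-to-IOI ratios.

    The articulation ratio a_i = duration_i / ioi_i (capped at 1) is 1
    for fully legato and small for staccato. Returns (population SD of
    a_i, mean |duration_{i+1} - duration_i| / ioi_i over adjacent
    pairs); absolute values keep both measures non-negative.
    """
    if len(perf) < 3:
        raise InsufficientDataError("articulation stats need >= 3 notes")
    iois = compute_iois(perf)
    durations = perf.durations
    ratios = np.minimum(durations[:-1] / iois, 1.0)
    sd = float(ratios.std())
    absdiff = float(np.mean(np.abs(np.diff(durations)) / iois))
    return sd, absdiff


def _greedy_pattern_notes(pitches: np.ndarray, min_len: int, matcher) -> int:
    """Greedy left-to-right scan for later occurrences of earlier material.

    At each position the longest claimable segment is taken (leftmost
    source on ties); claimed (later) occurrences do not overlap each
    other or their source. Returns total notes in later occurrences.
    """
    n = pitches.size
    count = 0
    i = 0
    claimed_until = 0
    while i <= n - min_len:
        if i < claimed_until:
            i = claimed_until
            continue
        best_len = 0
        for length in range(n - i, min_len - 1, -1):
            found = False
            for s in range(0, i - length + 1):
                if matcher(pitches, s, i, length):
                    found = True
                    break
            if found:
                best_len = length
                break
        if best_len:
            count += best_len
            claimed_until = i + best_len
            i += best_len
        else:
            i += 1
    return count


def _is_retrograde(p: np.ndarray, s: int, i: int, length: int) -> bool:
    return bool(np.array_equal(p[s : s + length][::-1], p[i : i + length]))


def _is_sequence(p: np.ndarray, s: int, i: int, length: int) -> bool:
    a, b = p[s : s + length], p[i : i + length]
    return bool(
        np.array_equal(np.diff(a), np.diff(b)) and a[0] != b[0]
    )


def retrograde_notes(perf: Performance, min_len: int = PATTERN_MIN_LEN) -> int:
    """Notes in contiguous segments that exactly reverse earlier segments.

    Greedy non-overlapping scan; only the later (retrograde) occurrence
    is counted. Returns 0 when the performance is too short to contain
    both a source and its reversal.
    """
    pitches = perf.pitches
    if pitches.size < 2 * min_len:
        return 0
    return _greedy_pattern_notes(pitches, min_len, _is_retrograde)


def sequence_notes(perf: Performance, min_len: int = PATTERN_MIN_LEN) -> int:
    """Notes in segments repeating an earlier interval pattern transposed.

    The transposition must be non-zero (a literal repeat is the repeat
    measure's business, not a musical sequence). Greedy, non-overlapping,
    later occurrences counted.
    """
    pitches = perf.pitches
    if pitches.size < 2 * min_len:
        return 0
    return _greedy_pattern_notes(pitches, min_len, _is_sequence)


def _maybe(fn, *args):
    try:
        return float(fn(*args))
    except InsufficientDataError:
        return float("nan")


def score_improvisation(
    perf: Performance, prompt: Optional[Performance] = None
) -> ImprovScores:
    """All 18 improvisation scoretypes for one performance.

    The aural prompt, when given, is carried for bookkeeping only: every
    measure is a property of the improvisation itself. Fields whose
    preconditions fail (too few notes) are NaN.
    """
    if len(perf) < 2:
        raise InsufficientDataError("improvisation scoring needs >= 2 notes")
    pitches = perf.pitches
    intervals = np.diff(pitches)
    iois = compute_iois(perf)
    wind = _maybe(lambda: windowed_ioi_stats(perf)[0])
    wind_abs = _maybe(lambda: windowed_ioi_stats(perf)[1])
    artic = _maybe(lambda: articulation_stats(perf)[0])
    artic_abs = _maybe(lambda: articulation_stats(perf)[1])
    return ImprovScores(
        NumNotes=float(num_notes(perf)),
        M1pintervaldivers=_maybe(diversity, intervals),
        M1pintervalrange=_maybe(value_range, intervals),
        M2ioidivers=_maybe(diversity, _discretize_iois(iois)),
        M2ioirange=_maybe(value_range, iois),
        M3pitchdivers=_maybe(diversity, pitches),
        M3prange=_maybe(value_range, pitches),
        M4repeatnotes=float(repeat_notes(perf)),
        M5Passnotesprop=_maybe(passing_notes_prop, perf),
        M6crescdim=float(cresc_dim_count(perf)),
        M7AccentProp=_maybe(accent_prop, perf),
        M8silenceprop=_maybe(silence_prop, perf),
        M9windioirange=wind,
        M12VaryStaccLeg=artic,
        M13retronotes=float(retrograde_notes(perf)),
        M14sequences=float(sequence_notes(perf)),
        M12aStaccLegabsdiff=artic_abs,
        M9aWindioiabsdiff=wind_abs,
    )
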