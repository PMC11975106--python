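"""Replication-fidelity measures.

Eight scores comparing a performance to a reference melody, each in
[0, 1]:

==================  ==========================================================
pitchdtwsim         subsequence-DTW similarity of the pitch sequence
palignedprop        proportion of the reference matched under the alignment
pitchdtwladj        pitchdtwsim x palignedprop (length-adjusted similarity)
pioidtwsim          DTW similarity on joint (pitch, log-IOI) features
pioialignedprop     reference proportion matched under the joint alignment
pioidtwladj         pioidtwsim x pioialignedprop
klpitchsim          exp(-Jeffreys divergence) of the two pitch histograms
klioisim            exp(-Jeffreys divergence) of the two log-IOI histograms
==================  ==========================================================

The DTW is subsequence-style (open begin/end on the reference) so a
correctly played fragment aligns to its best reference segment and is
scored on that segment alone; the aligned proportion then charges for
how little of the reference was covered. Distributional (KL) measures
ignore order entirely and capture pitch-set / timing-set similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import rel_entr

from melodymetrics.errors import DomainError, InsufficientDataError
from melodymetrics.events import Performance, compute_iois

COST_CAP = 12.0  # semitone cap on a single pitch mismatch (octave slip)
MATCH_TOL = 0.0  # exact pitch for the aligned proportion
JOINT_IOI_CAP = 2.0  # cap on |delta log2 IOI ratio| (two octaves of tempo)
JOINT_W_IOI = 1.0  # weight of the timing component in the joint cost
JOINT_MATCH_TOL = 0.1  # combined-cost tolerance for the joint aligned prop
IOI_BIN_EDGES = np.linspace(-3.0, 3.0, 14)  # 13 bins over log2(ioi/median)
KL_ALPHA = 0.5  # additive smoothing for the distributional measures
KL_MIN_NOTES = 4  # below this, distributions are flagged low-information


@dataclass
class AlignmentResult:
    """Optimal subsequence-DTW alignment of a performance to a reference.

    ``path`` is the list of (perf_index, ref_index) pairs along the
    optimal warping path; ``normalized_distance`` is the cumulative local
    cost divided by (path length x local-cost cap), hence in [0, 1];
    ``matched_ref_indices`` are the reference positions whose paired
    local cost fell within the match tolerance.
    """

    path: list[tuple[int, int]]
    normalized_distance: float
    matched_ref_indices: frozenset[int]


@dataclass
class ReplicationScores:
    pitchdtwsim: float
    palignedprop: float
    pitchdtwladj: float
    pioidtwsim: float
    pioialignedprop: float
    pioidtwladj: float
    klpitchsim: float
    klioisim: float

    FIELDS = (
        "pitchdtwsim",
        "palignedprop",
        "pitchdtwladj",
        "pioidtwsim",
        "pioialignedprop",
        "pioidtwladj",
        "klpitchsim",
        "klioisim",
    )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.FIELDS}


def _subsequence_dtw(
    perf: Sequence,
    ref: Sequence,
    local_cost: Callable[[object, object], float],
    cost_cap: float,
    match_tol: float,
) -> AlignmentResult:
    """Subsequence DTW, open begin/end on the reference.

    A path starts at (0, j0) for any j0, ends at (m-1, j1), and moves by
    diagonal, vertical or horizontal unit steps (symmetric, unit
    weights). Among minimum-cumulative-cost paths the shortest is taken,
    making the path-length-normalised distance deterministic.
    """
    m, n = len(perf), len(ref)
    if m == 0 or n == 0:
        raise InsufficientDataError("DTW requires non-empty sequences")

    cost = [[local_cost(perf[i], ref[j]) for j in range(n)] for i in range(m)]
    INF = (math.inf, 0)
    acc: list[list[tuple[float, int]]] = [[INF] * n for _ in range(m)]
    back: list[list[tuple[int, int] | None]] = [[None] * n for _ in range(m)]

    for j in range(n):
        best = (cost[0][j], 1)  # open begin: free entry anywhere in row 0
        prev = None
        if j > 0:
            horiz = (acc[0][j - 1][0] + cost[0][j], acc[0][j - 1][1] + 1)
            if horiz < best:
                best, prev = horiz, (0, j - 1)
        acc[0][j], back[0][j] = best, prev

    for i in range(1, m):
        for j in range(n):
            # tie-break: diagonal preferred over vertical over horizontal
            # (min() is stable), giving canonical alignments on ties
            candidates = []
            if j > 0:
                candidates.append(((i - 1, j - 1), acc[i - 1][j - 1]))
            candidates.append(((i - 1, j), acc[i - 1][j]))
            if j > 0:
                candidates.append(((i, j - 1), acc[i][j - 1]))
            prev_cell, (prev_cost, prev_len) = min(candidates, key=lambda c: c[1])
            acc[i][j] = (prev_cost + cost[i][j], prev_len + 1)
            back[i][j] = prev_cell

    # on ties prefer the latest end, so an exact rendition covers the
    # whole reference rather than stopping one repeated note short
    end_j = max(
        range(n), key=lambda j: (acc[m - 1][j] == min(acc[m - 1]), j)
    )
    total_cost, path_len = acc[m - 1][end_j]

    path: list[tuple[int, int]] = []
    cell: tuple[int, int] | None = (m - 1, end_j)
    while cell is not None:
        path.append(cell)
        cell = back[cell[0]][cell[1]]
    path.reverse()
    assert len(path) == path_len

    matched = frozenset(j for i, j in path if cost[i][j] <= match_tol)
    normalized = total_cost / (path_len * cost_cap)
    return AlignmentResult(path, normalized, matched)


def _pitch_cost(a, b) -> float:
    return min(abs(float(a) - float(b)), COST_CAP)


def _joint_cost(a, b) -> float:
    dp = min(abs(a[0] - b[0]), COST_CAP) / COST_CAP
    di = min(abs(a[1] - b[1]), JOINT_IOI_CAP) / JOINT_IOI_CAP
    return dp + JOINT_W_IOI * di


def dtw_align(
    perf_pitches: Sequence[int],
    ref_pitches: Sequence[int],
    match_tol: float = MATCH_TOL,
) -> AlignmentResult:
    """Align a performed pitch sequence to a reference pitch sequence.

    Local cost is the absolute semitone difference capped at
    ``COST_CAP`` (12), so an octave slip costs no more than any larger
    leap; the normalised distance divides by path length x cap and is
    therefore in [0, 1].
    """
    return _subsequence_dtw(
        list(perf_pitches), list(ref_pitches), _pitch_cost, COST_CAP, match_tol
    )


def pitch_similarity(alignment: AlignmentResult) -> float:
    """1 - normalised distance, clipped to [0, 1]."""
    return float(np.clip(1.0 - alignment.normalized_distance, 0.0, 1.0))


def aligned_proportion(alignment: AlignmentResult, ref_length: int) -> float:
    """Proportion of reference positions matched within tolerance."""
    if ref_length < 1:
        raise DomainError("ref_length must be >= 1")
    return len(alignment.matched_ref_indices) / ref_length


def length_adjusted(sim: float, prop: float) -> float:
    """Similarity discounted by the extent of the reference covered."""
    if not (0.0 <= sim <= 1.0 and 0.0 <= prop <= 1.0):
        raise DomainError("length_adjusted arguments must lie in [0, 1]")
    return sim * prop


def joint_features(performance: Performance) -> list[tuple[float, float]]:
    """Per-note (pitch, log2 IOI ratio-to-median) features.

    The log-median normalisation makes the timing component invariant to
    a uniform tempo change. The last note has no IOI and is dropped.
    """
    iois = compute_iois(performance)
    med = float(np.median(iois))
    pitches = performance.pitches
    return [
        (float(pitches[i]), math.log2(iois[i] / med)) for i in range(len(iois))
    ]


def pioi_scores(perf: Performance, ref: Performance) -> tuple[float, float, float]:
    """Joint pitch+timing DTW triple (sim, aligned proportion, product).

    Local cost sums the capped, unit-scaled pitch and log-IOI
    differences; the aligned proportion counts reference positions whose
    combined cost is within ``JOINT_MATCH_TOL``.
    """
    fp, fr = joint_features(perf), joint_features(ref)
    alignment = _subsequence_dtw(
        fp, fr, _joint_cost, 1.0 + JOINT_W_IOI, JOINT_MATCH_TOL
    )
    sim = pitch_similarity(alignment)
    prop = aligned_proportion(alignment, len(fr))
    return sim, prop, length_adjusted(sim, prop)


def pitch_distribution(
    performance: Performance,
    support: Sequence[int] | None = None,
    alpha: float = 0.0,
) -> np.ndarray:
    """Relative-frequency histogram of absolute MIDI pitch.

    With no ``support`` the vector spans all 128 MIDI pitches. For the
    KL comparison, the two performances' pitch-set union is passed as
    the support and additive smoothing ``alpha`` keeps every cell
    positive.
    """
    if len(performance) == 0:
        raise InsufficientDataError("pitch distribution of an empty performance")
    pitches = performance.pitches
    if support is None:
        support = range(128)
    counts = np.array(
        [np.count_nonzero(pitches == p) + alpha for p in support], dtype=float
    )
    return counts / counts.sum()


def ioi_distribution(performance: Performance, alpha: float = 0.0) -> np.ndarray:
    """Histogram of log2(IOI / median IOI) over 13 fixed bins on [-3, 3].

    Bins are half-open with catch-all extremes, so the vector is
    invariant to a uniform tempo change (the median cancels).
    """
    iois = compute_iois(performance)
    ratios = np.log2(iois / np.median(iois))
    idx = np.digitize(ratios, IOI_BIN_EDGES[1:-1])
    counts = np.bincount(idx, minlength=13).astype(float) + alpha
    return counts / counts.sum()


def kl_similarity(p: np.ndarray, q: np.ndarray) -> float:
    """exp(-J) where J is the symmetrised (Jeffreys) KL divergence.

    Identical distributions score 1; the score decays towards 0 as the
    divergence grows. Inputs must be equal-length, normalised, strictly
    positive probability vectors (smoothing guarantees positivity).
    """
    p, q = np.asarray(p, float), np.asarray(q, float)
    if p.shape != q.shape:
        raise DomainError("distributions must have equal length")
    if abs(p.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
        raise DomainError("distributions must each sum to 1")
    if (p <= 0).any() or (q <= 0).any():
        raise DomainError("distributions must be strictly positive (smooth first)")
    j = 0.5 * float(rel_entr(p, q).sum()) + 0.5 * float(rel_entr(q, p).sum())
    return math.exp(-j)


def _kl_pitch(perf: Performance, ref: Performance) -> float:
    union = sorted(set(perf.pitches.tolist()) | set(ref.pitches.tolist()))
    p = pitch_distribution(perf, support=union, alpha=KL_ALPHA)
    q = pitch_distribution(ref, support=union, alpha=KL_ALPHA)
    return kl_similarity(p, q)


def _kl_ioi(perf: Performance, ref: Performance) -> float:
    p = ioi_distribution(perf, alpha=KL_ALPHA)
    q = ioi_distribution(ref, alpha=KL_ALPHA)
    return kl_similarity(p, q)


def score_replication(perf: Performance, ref: Performance) -> ReplicationScores:
    """All eight replication measures for one performance/reference pair.

    A one-note performance still yields the pitch-only DTW triple and
    the pitch KL similarity; every IOI-based field is flagged missing
    (NaN) rather than zero, so downstream standardisation is not biased.
    """
    if len(perf) < 1:
        raise InsufficientDataError("performance has no notes")
    if len(ref) < 2:
        raise InsufficientDataError("reference must have >= 2 notes")

    alignment = dtw_align(perf.pitches, ref.pitches)
    sim = pitch_similarity(alignment)
    prop = aligned_proportion(alignment, len(ref))
    ladj = length_adjusted(sim, prop)

    if len(perf) >= 2:
        psim, pprop, pladj = pioi_scores(perf, ref)
        klioi = _kl_ioi(perf, ref)
    else:
        psim = pprop = pladj = klioi = float("nan")

    return ReplicationScores(
        pitchdtwsim=sim,
        palignedprop=prop,
        pitchdtwladj=ladj,
        pioidtwsim=psim,
        pioialignedprop=pprop,
        pioidtwladj=pladj,
        klpitchsim=_kl_pitch(perf, ref),
        klioisim=klioi,
    )
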