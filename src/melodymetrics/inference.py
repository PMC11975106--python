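"""Posterior-summary utilities.

Small helpers for expressing results from posterior draws: one-sided
evidence ratios (the posterior mass favouring a directional hypothesis
over the mass against it; a ratio above 19 corresponds to better than
95:5 odds and is conventionally "strong") and equal-tailed credibility
intervals. Fitting the models that produce the draws is out of scope.
"""

from __future__ import annotations

import math

import numpy as np

from melodymetrics.errors import DomainError, InsufficientDataError

MIN_DRAWS = 100
STRONG_EVIDENCE = 19.0  # 95:5 posterior odds


def evidence_ratio(draws, direction: str = "positive") -> float:
    """Ratio of draws on the hypothesised side to draws on the other.

    Draws exactly at zero are split half to each side. If every draw
    falls on the hypothesised side the ratio is infinite.
    """
    if direction not in ("positive", "negative"):
        raise DomainError("direction must be 'positive' or 'negative'")
    d = np.asarray(draws, dtype=float)
    if d.size == 0:
        raise InsufficientDataError("no posterior draws supplied")
    if d.size < MIN_DRAWS:
        raise InsufficientDataError(
            f"need >= {MIN_DRAWS} draws for a stable evidence ratio, got {d.size}"
        )
    if not np.isfinite(d).all():
        raise DomainError("draws must be finite")
    zeros = np.count_nonzero(d == 0) / 2.0
    pos = np.count_nonzero(d > 0) + zeros
    neg = np.count_nonzero(d < 0) + zeros
    favour, against = (pos, neg) if direction == "positive" else (neg, pos)
    if against == 0:
        return math.inf
    return favour / against


def credibility_interval(draws, level: float = 0.95) -> tuple[float, float, float]:
    """Equal-tailed credibility interval and median: (low, median, high)."""
    if not 0.0 < level < 1.0:
        raise DomainError("level must lie strictly between 0 and 1")
    d = np.asarray(draws, dtype=float)
    if d.size < MIN_DRAWS:
        raise InsufficientDataError(
            f"need >= {MIN_DRAWS} draws for a credibility interval, got {d.size}"
        )
    if not np.isfinite(d).all():
        raise DomainError("draws must be finite")
    tail = (1.0 - level) / 2.0
    lo, med, hi = np.quantile(d, [tail, 0.5, 1.0 - tail])
    return float(lo), float(med), float(hi)
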