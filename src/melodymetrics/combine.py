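"""Rescaling, standardisation and composite scores.

Heterogeneous measures are brought onto a common footing before
modelling: replication measures are min-max scaled to [0, 1] so they
can be weighted fairly against each other, improvisation measures are
standardised (mean 0, SD 1), and overlapping measures of the same
learning process are merged into one composite via variance-sharing
weights (squared loadings of the first principal axis of the
correlation matrix, normalised to sum to 1).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from melodymetrics.errors import DegenerateColumnError, DomainError


def scale_unit_interval(column) -> pd.Series:
    """Min-max scale to [0, 1] over non-missing cells; missing preserved."""
    s = pd.Series(column, dtype=float)
    valid = s.dropna()
    if valid.nunique() < 2:
        raise DegenerateColumnError("cannot unit-scale a constant column")
    lo, hi = valid.min(), valid.max()
    return (s - lo) / (hi - lo)


def standardize(column) -> pd.Series:
    """Z-scores with the population SD convention (divisor n)."""
    s = pd.Series(column, dtype=float)
    valid = s.dropna()
    if valid.nunique() < 2:
        raise DegenerateColumnError("cannot standardise a constant column")
    return (s - valid.mean()) / valid.std(ddof=0)


def variance_sharing_weights(matrix: pd.DataFrame) -> pd.Series:
    """Variance-sharing weights from the first principal axis.

    Squared loadings of the leading eigenvector of the
    pairwise-complete correlation matrix, shrunk towards equal weights
    by the fraction of variance the first axis does NOT share:
    w = s * loading^2 + (1 - s) / k with s = (lambda_1 - 1) / (k - 1).
    Columns sharing variance with the rest of the set receive large
    weights and a pure-noise column is down-weighted, while a set of
    mutually independent columns (lambda_1 -> 1, where the leading
    eigenvector is arbitrary) degrades gracefully to equal weights
    instead of inheriting the eigenvector's noise.
    """
    corr = matrix.corr(min_periods=2)
    if corr.isna().any().any():
        raise DegenerateColumnError("correlation matrix has missing entries")
    eigvals, eigvecs = np.linalg.eigh(corr.to_numpy())
    if eigvals[-1] <= 0:
        raise DegenerateColumnError("degenerate correlation matrix")
    k = corr.shape[0]
    loading_sq = eigvecs[:, -1] ** 2
    shared = float(np.clip((eigvals[-1] - 1.0) / (k - 1.0), 0.0, 1.0))
    weights = shared * loading_sq + (1.0 - shared) / k
    return pd.Series(weights / weights.sum(), index=matrix.columns)


def variance_sharing_combine(
    matrix: pd.DataFrame, columns: Sequence[str] | None = None
) -> pd.Series:
    """Composite score: variance-sharing weighted sum of standardised columns.

    Rows missing any selected column get a missing composite. The sign
    is fixed so the composite correlates positively with the plain
    column mean, making "higher = better" stable across eigenvector
    sign flips.
    """
    cols = list(columns) if columns is not None else list(matrix.columns)
    if len(cols) < 2:
        raise DomainError("need at least two columns to combine")
    std = pd.DataFrame({c: standardize(matrix[c]) for c in cols})
    weights = variance_sharing_weights(std)
    combined = std.mul(weights, axis=1).sum(axis=1, min_count=len(cols))
    anchor = std.mean(axis=1)
    mask = combined.notna() & anchor.notna()
    if mask.any() and np.corrcoef(combined[mask], anchor[mask])[0, 1] < 0:
        combined = -combined
    return combined


def combine_replication(matrix: pd.DataFrame) -> pd.Series:
    """Composite replication score from sequence + distributional similarity.

    Unit-interval scales pitchdtwladj and klpitchsim, then combines them
    with variance-sharing weights.
    """
    required = ["pitchdtwladj", "klpitchsim"]
    missing = [c for c in required if c not in matrix.columns]
    if missing:
        raise DomainError(f"matrix lacks required columns: {missing}")
    scaled = pd.DataFrame({c: scale_unit_interval(matrix[c]) for c in required})
    return variance_sharing_combine(scaled, required)
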