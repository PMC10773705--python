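"""ADEN: average-distance-between-events-and-non-events feature ranking.

A supervised filter score per feature column: z-score the column over the
training rows, then take the magnitude of Cohen's d between the event and
non-event class means of the z-scored values (pooled within-class SD).
The z-transform makes the score invariant to affine rescaling of any
column; the Cohen's d magnitude is the standardized average distance
between the two classes.  Scores are computed on training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import ValidationError

#: Cap for degenerate (zero within-class variance) separations, keeping the
#: ranking totally ordered.
SCORE_CAP = 1e6

K_MIN, K_MAX = 3, 6


@dataclass(frozen=True)
class ADENRanking:
    """Per-feature scores and the retained top-k column indices."""

    scores: np.ndarray
    selected: np.ndarray  # k indices, descending score, ties by lower index
    k: int


def aden_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """ADEN score for every column of ``X`` given binary event labels ``y``.

    Zero-variance columns score 0; perfectly separated columns with zero
    within-class variance are capped at :data:`SCORE_CAP`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")
    if n1 < 2 or n0 < 2:
        raise ValidationError("need >=2 rows per class to estimate within-class SD")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    nonconst = sd > 0
    Z = np.zeros_like(X)
    Z[:, nonconst] = (X[:, nonconst] - mean[nonconst]) / sd[nonconst]

    m1 = Z[y].mean(axis=0)
    m0 = Z[~y].mean(axis=0)
    v1 = Z[y].var(axis=0, ddof=1)
    v0 = Z[~y].var(axis=0, ddof=1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2))

    diff = np.abs(m1 - m0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(pooled > 0, diff / np.where(pooled > 0, pooled, 1.0), 0.0)
    # Separated but degenerate columns: nonzero distance, zero pooled SD.
    scores = np.where((pooled == 0) & (diff > 0), SCORE_CAP, scores)
    scores = np.minimum(scores, SCORE_CAP)
    scores[~nonconst] = 0.0
    return scores


def select_top_k(scores: np.ndarray, k: int) -> ADENRanking:
    """Indices of the k largest scores; ties broken by lower column index."""
    scores = np.asarray(scores, dtype=float)
    if not (K_MIN <= k <= K_MAX):
        raise ValidationError(f"k must be in [{K_MIN}, {K_MAX}], got {k}")
    if k > scores.size:
        raise ValidationError("k exceeds the number of feature columns")
    order = np.argsort(-scores, kind="stable")  # stable => lower index wins ties
    return ADENRanking(scores=scores, selected=order[:k].copy(), k=k)


def fit_ranking(X: np.ndarray, y: np.ndarray, k: int = K_MAX) -> ADENRanking:
    """Score all columns on training rows and retain the top k."""
    return select_top_k(aden_score(X, y), k)
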