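"""Information transfer rate (Wolpaw) and the global feature-type ranking.

ITR in bits/trial for an N-class selection with accuracy P, assuming
errors spread uniformly over the N-1 wrong classes::

    ITR = log2(N) + P*log2(P) + (1-P)*log2((1-P)/(N-1))

which is the mutual information of the symmetric confusion channel under a
uniform prior.  Bits/minute scales by 60 / trial duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aden import ADENRanking
from .features import feature_index
from .montage import ValidationError


@dataclass(frozen=True)
class ITRResult:
    n_classes: int
    accuracy: float
    bits_per_trial: float
    trial_seconds: float
    bits_per_minute: float


def itr_bits_per_trial(n_classes: int, accuracy: float) -> float:
    """Wolpaw ITR in bits per trial; limits 0*log2(0) taken as 0."""
    if n_classes < 2:
        raise ValidationError("need at least 2 classes")
    if not (0.0 <= accuracy <= 1.0):
        raise ValidationError(f"accuracy {accuracy} outside [0, 1]")
    p = accuracy
    bits = math.log2(n_classes)
    if p > 0:
        bits += p * math.log2(p)
    if p < 1:
        bits += (1.0 - p) * math.log2((1.0 - p) / (n_classes - 1))
    return bits


def itr_bits_per_minute(bits_per_trial: float, trial_seconds: float) -> float:
    if trial_seconds <= 0:
        raise ValidationError("trial duration must be positive")
    return bits_per_trial * 60.0 / trial_seconds


def itr_result(n_classes: int, accuracy: float, trial_seconds: float = 1.0) -> ITRResult:
    bpt = itr_bits_per_trial(n_classes, accuracy)
    return ITRResult(
        n_classes=n_classes,
        accuracy=accuracy,
        bits_per_trial=bpt,
        trial_seconds=trial_seconds,
        bits_per_minute=itr_bits_per_minute(bpt, trial_seconds),
    )


def symmetric_channel_mutual_information(n_classes: int, accuracy: float) -> float:
    """Brute-force mutual information of the symmetric confusion channel.

    Uniform prior over n_classes inputs; output equals input with
    probability ``accuracy`` and is uniform over the other classes
    otherwise.  Serves as an independent cross-check of the closed-form ITR.
    """
    if n_classes < 2:
        raise ValidationError("need at least 2 classes")
    p_in = 1.0 / n_classes
    joint = np.empty((n_classes, n_classes))
    for i in range(n_classes):
        for j in range(n_classes):
            cond = accuracy if i == j else (1.0 - accuracy) / (n_classes - 1)
            joint[i, j] = p_in * cond
    p_out = joint.sum(axis=0)
    mi = 0.0
    for i in range(n_classes):
        for j in range(n_classes):
            if joint[i, j] > 0:
                mi += joint[i, j] * math.log2(joint[i, j] / (p_in * p_out[j]))
    return mi


def rank_global_features(
    rankings: list[tuple[int, int, ADENRanking]],
    index: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate ADEN scores over all one-vs-rest problems and folds.

    Returns one row per (feature, channel) pair — window-resolved scores are
    averaged together — sorted by descending mean score, with the base band
    name attached so gamma-related entries are identifiable.
    """
    if not rankings:
        raise ValidationError("no rankings to aggregate")
    if index is None:
        index = feature_index()
    score_stack = np.vstack([r.scores for _, _, r in rankings])
    mean_scores = score_stack.mean(axis=0)
    frame = index.copy()
    frame["score"] = mean_scores
    grouped = (
        frame.groupby(["feature", "channel"], sort=False)
        .agg(score=("score", "mean"), band=("band", "first"), kind=("kind", "first"))
        .reset_index()
        .sort_values("score", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    grouped.insert(0, "rank", np.arange(1, len(grouped) + 1))
    return grouped


def top_features_view(ranking: pd.DataFrame, n: int = 125) -> pd.DataFrame:
    """The top-n slice of the global feature ranking."""
    return ranking.head(n).reset_index(drop=True)
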