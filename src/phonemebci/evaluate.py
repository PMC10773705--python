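"""One-vs-rest per-phoneme classification with 4-block cross-validation.

For each phoneme a binary event (that phoneme) vs non-event (all others)
problem is evaluated over a 4-block stratified split: per fold, the three
remaining blocks train and the held-out block validates.  The training
rows are class-balanced by undersampling the non-events; ADEN feature
selection is fitted on the balanced training rows only; the validation
block keeps its natural ~1:43 imbalance (so accuracy is prevalence-driven
while F1/AUC-ROC remain informative).

Classifiers: LDA (lsqr solver, automatic shrinkage), linear-kernel SVM
(C=1), and KNN (k=5, uniform votes), each behind a standardization step
fitted on the training rows.  All randomness fans out deterministically
from a single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .aden import ADENRanking, fit_ranking
from .features import FeatureMatrix
from .montage import ValidationError

logger = logging.getLogger(__name__)

N_BLOCKS = 4

CLASSIFIERS = ("lda", "svm", "knn")


def make_classifier(name: str):
    """A fresh classifier pipeline by short name (lda | svm | knn)."""
    if name == "lda":
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    elif name == "svm":
        clf = SVC(kernel="linear", C=1.0)
    elif name == "knn":
        clf = KNeighborsClassifier(n_neighbors=5, weights="uniform")
    else:
        raise ValidationError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _score_rows(pipeline: Pipeline, X: np.ndarray) -> np.ndarray:
    """Continuous event score: decision function or event-class probability."""
    clf = pipeline.named_steps["clf"]
    if hasattr(clf, "decision_function"):
        return pipeline.decision_function(X)
    proba = pipeline.predict_proba(X)
    event_col = list(pipeline.classes_).index(1)
    return proba[:, event_col]


@dataclass(frozen=True)
class CVPlan:
    """Stratified assignment of rows to 4 near-equal blocks."""

    blocks: np.ndarray  # block id 1..4 per row
    seed: int

    def fold_rows(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(training row indices, validation row indices) for one fold."""
        val = np.flatnonzero(self.blocks == fold)
        train = np.flatnonzero(self.blocks != fold)
        return train, val


def make_cv_plan(labels: np.ndarray, seed: int) -> CVPlan:
    """Stratified 4-block split, reproducible from the seed.

    Per class, rows are shuffled and dealt to blocks round-robin; the
    starting block rotates with the class rank so block totals stay
    near-equal even when class counts are not multiples of 4.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    blocks = np.zeros(labels.size, dtype=int)
    for rank, cls in enumerate(np.unique(labels)):
        rows = np.flatnonzero(labels == cls)
        if rows.size < N_BLOCKS:
            raise ValidationError(
                f"class {cls} has {rows.size} rows; need >= {N_BLOCKS} for 4-block CV"
            )
        rng.shuffle(rows)
        for i, row in enumerate(rows):
            blocks[row] = (i + rank) % N_BLOCKS + 1
    return CVPlan(blocks=blocks, seed=seed)


def balance_ovr(row_indices: np.ndarray, y_binary: np.ndarray, seed: int) -> np.ndarray:
    """Undersample non-events to the event count; events are all kept.

    ``y_binary`` is indexed by position within ``row_indices``.  Returns the
    balanced subset of ``row_indices`` (events first, then the sampled
    non-events), deterministic given the seed.
    """
    row_indices = np.asarray(row_indices)
    y_binary = np.asarray(y_binary).astype(bool)
    events = row_indices[y_binary]
    non_events = row_indices[~y_binary]
    if events.size == 0:
        raise ValidationError("cannot balance a problem with zero events")
    if non_events.size <= events.size:
        return row_indices.copy()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    sampled = rng.choice(non_events, size=events.size, replace=False)
    return np.concatenate([events, sampled])


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, y_score: np.ndarray
) -> tuple[float, float, float | None]:
    """(accuracy, F1 on the event class, AUC-ROC) for one validation fold.

    AUC is None when the validation fold contains a single class (undefined);
    callers exclude missing AUCs from aggregates.
    """
    y_true = np.asarray(y_true).astype(int)
    accuracy = float(accuracy_score(y_true, y_pred))
    f1 = float(f1_score(y_true, y_pred, zero_division=0))
    if np.unique(y_true).size < 2:
        return accuracy, f1, None
    auc = float(roc_auc_score(y_true, y_score))
    return accuracy, f1, auc


@dataclass
class EvaluationReport:
    """Per (phoneme, fold) metrics plus ADEN rankings for one classifier run."""

    mode: str
    classifier: str
    records: pd.DataFrame  # phoneme, fold, accuracy, f1, auc, n_val, n_events_val
    rankings: list[tuple[int, int, ADENRanking]] = field(default_factory=list)

    def aggregates(self) -> dict[str, float]:
        """Mean and SD over all (phoneme, fold) cells; missing AUCs excluded."""
        out: dict[str, float] = {}
        for metric in ("accuracy", "f1", "auc"):
            values = self.records[metric].dropna()
            out[f"mean_{metric}"] = float(values.mean())
            out[f"sd_{metric}"] = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        out["n_missing_auc"] = int(self.records["auc"].isna().sum())
        return out

    def summary_text(self) -> str:
        agg = self.aggregates()
        return (
            f"mode={self.mode} classifier={self.classifier} "
            f"accuracy={agg['mean_accuracy']:.3f} ± {agg['sd_accuracy']:.3f}  "
            f"F1={agg['mean_f1']:.3f} ± {agg['sd_f1']:.3f}  "
            f"AUC-ROC={agg['mean_auc']:.3f} ± {agg['sd_auc']:.3f}"
        )


def _derived_seed(seed: int, phoneme: int, fold: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(phoneme, fold))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_ovr_cv(
    matrix: FeatureMatrix,
    classifier: str = "knn",
    k_features: int = 6,
    seed: int = 0,
    mode: str = "intrasubject",
    balance: bool = True,
) -> EvaluationReport:
    """Full one-vs-rest evaluation: 44 problems x 4 folds for one classifier.

    Per fold: balance the training rows, fit ADEN on the balanced training
    rows, restrict both splits to the selected features, fit the classifier,
    and score the untouched validation block.
    """
    make_classifier(classifier)  # validate the name before any work
    plan = make_cv_plan(matrix.labels, seed)
    records = []
    rankings: list[tuple[int, int, ADENRanking]] = []
    for phoneme in np.unique(matrix.labels):
        for fold in range(1, N_BLOCKS + 1):
            train_rows, val_rows = plan.fold_rows(fold)
            y_train = (matrix.labels[train_rows] == phoneme).astype(int)
            y_val = (matrix.labels[val_rows] == phoneme).astype(int)
            if np.unique(y_train).size < 2:
                logger.warning(
                    "phoneme %d fold %d: single-class training block, skipped",
                    phoneme, fold,
                )
                continue
            fold_seed = _derived_seed(seed, int(phoneme), fold)
            if balance:
                fit_rows = balance_ovr(train_rows, y_train.astype(bool), fold_seed)
            else:
                fit_rows = train_rows
            y_fit = (matrix.labels[fit_rows] == phoneme).astype(int)
            ranking = fit_ranking(matrix.X[fit_rows], y_fit, k=k_features)
            rankings.append((int(phoneme), fold, ranking))
            cols = ranking.selected
            pipeline = make_classifier(classifier)
            pipeline.fit(matrix.X[np.ix_(fit_rows, cols)], y_fit)
            X_val = matrix.X[np.ix_(val_rows, cols)]
            y_pred = pipeline.predict(X_val)
            y_score = _score_rows(pipeline, X_val)
            accuracy, f1, auc = compute_metrics(y_val, y_pred, y_score)
            records.append(
                {
                    "phoneme": int(phoneme),
                    "fold": fold,
                    "accuracy": accuracy,
                    "f1": f1,
                    "auc": auc,
                    "n_val": int(val_rows.size),
                    "n_events_val": int(y_val.sum()),
                }
            )
    if not records:
        raise ValidationError("no evaluable (phoneme, fold) cells")
    return EvaluationReport(
        mode=mode,
        classifier=classifier,
        records=pd.DataFrame(records),
        rankings=rankings,
    )
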