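"""Repeated Random-Forest and city-subsampled SVM prediction with per-sample
consolidation.

Both classifiers are run R times (10,000 in a full analysis; far fewer in
tests), each repetition with fresh randomness:

* Random Forest: a new forest (1000 trees, 20 variables per split) is fitted
  on all training samples; the overall and per-city out-of-bag (OOB) error
  and the normalized variable importance are recorded, and every test sample
  is predicted.
* SVM: each repetition randomly drops about 1/fold of each city's training
  samples (5-fold city scheme), fits a radial-kernel SVM (cost 1000,
  gamma = 1/#variables) on standardized features and predicts the test
  samples.  No predictions are produced for the dropped training samples.

The per-sample stream of R predicted labels is consolidated into a
prediction score (modal count / R) and the number of departures (distinct
predicted cities minus one); these feed the adjusted-score voting stage.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .preprocess import LogCpmMatrix
from .tables import ValidationError

__all__ = [
    "ClassifierConfig",
    "ConsolidationRecord",
    "CvErrorRecord",
    "ImportanceRanking",
    "rf_repeat",
    "svm_repeat",
    "consolidate",
    "consolidate_all",
]

logger = logging.getLogger(__name__)


@dataclass
class ClassifierConfig:
    rf_n_trees: int = 1000
    rf_vars_per_split: int = 20
    svm_cost: float = 1000.0
    svm_gamma: float | None = None  # resolved to 1/#variables at fit time
    svm_city_fold: int = 5
    repetitions: int = 10_000
    seed: int = 0
    rf_refit_each_repetition: bool = True

    def __post_init__(self) -> None:
        if min(self.rf_n_trees, self.rf_vars_per_split, self.svm_city_fold) <= 0:
            raise ValidationError("classifier sizes must be positive")
        if self.repetitions <= 0:
            raise ValidationError("repetitions must be positive")
        if self.svm_cost <= 0:
            raise ValidationError("svm_cost must be positive")


@dataclass
class ConsolidationRecord:
    sample_id: str
    classifier: str  # "RF" or "SVM"
    city_hits: dict[str, int]
    top_city: str
    score: float
    distinct_cities: int
    departures: int
    tie: bool = False

    @property
    def repetitions(self) -> int:
        return sum(self.city_hits.values())


@dataclass
class CvErrorRecord:
    repetition: int
    oob_overall: float
    oob_per_city: dict[str, float]


@dataclass
class ImportanceRanking:
    """Mean normalized variable importance across repetitions."""

    mean_importance: pd.Series  # index species, normalized to sum 1 per repetition

    def rank_order(self) -> list[str]:
        return list(self.mean_importance.sort_values(ascending=False).index)

    def top(self, n: int) -> list[str]:
        return self.rank_order()[:n]


def _check_alignment(train: LogCpmMatrix, test: LogCpmMatrix) -> None:
    if list(train.species_ids) != list(test.species_ids):
        raise ValidationError("train and test matrices have different species columns")


def _check_labels(labels: pd.Series, train: LogCpmMatrix) -> pd.Series:
    labels = labels.loc[train.sample_ids]
    if labels.isna().any():
        raise ValidationError("training samples with missing city label")
    if labels.nunique() < 2:
        raise ValidationError("training set must contain at least 2 cities")
    return labels.astype(str)


def rf_repeat(
    train: LogCpmMatrix,
    labels: pd.Series,
    test: LogCpmMatrix,
    config: ClassifierConfig,
) -> tuple[pd.DataFrame, list[CvErrorRecord], ImportanceRanking]:
    """Repeatedly refit a Random Forest and predict the test samples.

    Returns a repetitions x test-samples frame of predicted labels, the
    per-repetition OOB error records, and the averaged normalized importance.
    With ``config.rf_refit_each_repetition`` False a single forest is fitted
    and its (deterministic) predictions are repeated — a cheap mode for
    pipelines that only need the voting arithmetic exercised.
    """
    _check_alignment(train, test)
    labels = _check_labels(labels, train)
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        logger.warning(
            "cities with <2 training samples (per-city OOB may be degenerate): %s",
            list(small.index),
        )
    X = train.values.to_numpy(dtype=float)
    Xt = test.values.to_numpy(dtype=float)
    y = labels.to_numpy()
    max_features = min(config.rf_vars_per_split, X.shape[1])

    rng = np.random.default_rng(config.seed)
    n_fits = config.repetitions if config.rf_refit_each_repetition else 1
    fit_seeds = rng.integers(0, 2**31 - 1, size=n_fits)

    predictions = np.empty((config.repetitions, Xt.shape[0]), dtype=object)
    errors: list[CvErrorRecord] = []
    importance_sum = np.zeros(X.shape[1])

    for r in range(n_fits):
        forest = RandomForestClassifier(
            n_estimators=config.rf_n_trees,
            max_features=max_features,
            oob_score=True,
            bootstrap=True,
            random_state=int(fit_seeds[r]),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            # few-tree test runs can leave samples with no OOB vote
            warnings.simplefilter("ignore", UserWarning)
            forest.fit(X, y)
        oob_votes = forest.oob_decision_function_
        has_vote = oob_votes.sum(axis=1) > 0
        oob_pred = np.array(
            [
                forest.classes_[np.argmax(oob_votes[i])] if has_vote[i] else None
                for i in range(len(y))
            ]
        )
        valid = has_vote
        overall = float(np.mean(oob_pred[valid] != y[valid])) if valid.any() else float("nan")
        per_city = {}
        for city in np.unique(y):
            m = (y == city) & valid
            per_city[city] = (
                float(np.mean(oob_pred[m] != y[m])) if m.any() else float("nan")
            )
        errors.append(CvErrorRecord(repetition=r, oob_overall=overall, oob_per_city=per_city))
        imp = forest.feature_importances_
        total = imp.sum()
        if total > 0:
            importance_sum += imp / total
        predictions[r] = forest.predict(Xt)

    if not config.rf_refit_each_repetition:
        predictions[:] = predictions[0]

    importance = ImportanceRanking(
        mean_importance=pd.Series(importance_sum / n_fits, index=train.species_ids)
    )
    pred_frame = pd.DataFrame(predictions, columns=test.sample_ids)
    return pred_frame, errors, importance


def svm_repeat(
    train: LogCpmMatrix,
    labels: pd.Series,
    test: LogCpmMatrix,
    config: ClassifierConfig,
) -> pd.DataFrame:
    """Repeated city-subsampled radial-kernel SVM prediction.

    Each repetition drops ``floor(n_city / fold)`` randomly chosen samples
    from each city, standardizes features on the retained training samples,
    fits an SVM (one-vs-one multiclass) with the configured cost and
    gamma = 1/#variables, and predicts every test sample.
    """
    _check_alignment(train, test)
    labels = _check_labels(labels, train)
    counts = labels.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValidationError(
            f"cities with a single training sample: {list(singletons.index)}"
        )
    X = train.values.to_numpy(dtype=float)
    Xt = test.values.to_numpy(dtype=float)
    y = labels.to_numpy()
    gamma = config.svm_gamma if config.svm_gamma is not None else 1.0 / X.shape[1]

    rng = np.random.default_rng(config.seed + 1)  # independent of the RF stream
    city_indices = {c: np.flatnonzero(y == c) for c in np.unique(y)}

    predictions = np.empty((config.repetitions, Xt.shape[0]), dtype=object)
    for r in range(config.repetitions):
        keep: list[np.ndarray] = []
        for c, idx in city_indices.items():
            n_drop = len(idx) // config.svm_city_fold
            n_drop = min(n_drop, len(idx) - 1)  # keep at least one sample per city
            perm = rng.permutation(idx)
            keep.append(perm[n_drop:])
        keep_idx = np.sort(np.concatenate(keep))
        Xk, yk = X[keep_idx], y[keep_idx]
        mu = Xk.mean(axis=0)
        sd = Xk.std(axis=0)
        sd[sd == 0] = 1.0
        model = SVC(C=config.svm_cost, kernel="rbf", gamma=gamma)
        model.fit((Xk - mu) / sd, yk)
        predictions[r] = model.predict((Xt - mu) / sd)

    return pd.DataFrame(predictions, columns=test.sample_ids)


def consolidate(
    sample_id: str,
    classifier: str,
    predictions,
    repetitions: int | None = None,
) -> ConsolidationRecord:
    """Consolidate one sample's stream of predicted labels.

    score = modal-city count / repetitions; departures = distinct cities
    predicted minus one.  Modal ties break lexicographically with the tie
    flag set.
    """
    predictions = list(predictions)
    if not predictions:
        raise ValidationError(f"sample {sample_id!r}: empty prediction list")
    if repetitions is not None and len(predictions) != repetitions:
        raise ValidationError(
            f"sample {sample_id!r}: got {len(predictions)} predictions, "
            f"expected {repetitions}"
        )
    hits = Counter(str(p) for p in predictions)
    top_count = max(hits.values())
    winners = sorted(c for c, n in hits.items() if n == top_count)
    top_city = winners[0]
    n = len(predictions)
    return ConsolidationRecord(
        sample_id=sample_id,
        classifier=classifier,
        city_hits=dict(hits),
        top_city=top_city,
        score=top_count / n,
        distinct_cities=len(hits),
        departures=len(hits) - 1,
        tie=len(winners) > 1,
    )


def consolidate_all(
    pred_frame: pd.DataFrame, classifier: str
) -> dict[str, ConsolidationRecord]:
    """Consolidate a repetitions x samples prediction frame per sample."""
    return {
        sid: consolidate(sid, classifier, pred_frame[sid].tolist())
        for sid in pred_frame.columns
    }
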