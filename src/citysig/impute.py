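"""City-restricted predictive-mean-matching (PMM) imputation of zero counts
and the imputation x zero-city prediction-score scan.

Imputing every zero in a zero-inflated city table rewrites the very
presence/absence signatures the classifiers rely on; restricting imputation
to the cities whose zeros are plausibly technical (heavily under-sampled
cities) can instead recover signal.  Zeros in the target cities are marked
missing and filled by chained PMM: per variable, a linear predictor on the
other variables is fitted over rows where the variable is observed, and each
recipient copies the observed value of one of the k nearest-predicted donors
(random choice, seeded).  Non-target cities are never modified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import LogCpmMatrix, log2cpm, select_city_common, zero_city_family
from .classify import ClassifierConfig, rf_repeat, svm_repeat, consolidate_all
from .vote import vote_all, evaluate
from .tables import TaxaCountTable, ValidationError, city_labels

__all__ = [
    "ImputationConfig",
    "pmm_impute_values",
    "pmm_impute",
    "impute_zero_city_scan",
]

logger = logging.getLogger(__name__)


@dataclass
class ImputationConfig:
    target_cities: set[str] = field(default_factory=set)
    k_donors: int = 5
    chained_iterations: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_donors < 1:
            raise ValidationError("k_donors must be >= 1")
        if not self.target_cities:
            raise ValidationError("target_cities must be non-empty")


def _pmm_one_variable(
    X: np.ndarray,
    col: int,
    missing_rows: np.ndarray,
    observed_rows: np.ndarray,
    k_donors: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """PMM draws for one variable; returns imputed values for missing_rows."""
    predictors = np.delete(X, col, axis=1)
    A = np.column_stack([np.ones(len(observed_rows)), predictors[observed_rows]])
    yobs = X[observed_rows, col]
    coef, *_ = np.linalg.lstsq(A, yobs, rcond=None)
    pred_obs = A @ coef
    B = np.column_stack([np.ones(len(missing_rows)), predictors[missing_rows]])
    pred_mis = B @ coef
    k = min(k_donors, len(observed_rows))
    out = np.empty(len(missing_rows))
    for r, p in enumerate(pred_mis):
        nearest = np.argsort(np.abs(pred_obs - p), kind="stable")[:k]
        out[r] = yobs[nearest[rng.integers(0, k)]]
    return out


def pmm_impute_values(
    values: pd.DataFrame, missing_mask: pd.DataFrame, config: ImputationConfig
) -> pd.DataFrame:
    """Chained PMM on an arbitrary numeric frame with an explicit mask.

    Cells where ``missing_mask`` is True are treated as missing; everything
    else is bitwise unchanged in the result.  Deterministic under
    ``config.seed``.
    """
    mask = missing_mask.to_numpy(dtype=bool)
    X = values.to_numpy(dtype=float).copy()
    n, m = X.shape
    cols_with_missing = [j for j in range(m) if mask[:, j].any()]
    for j in cols_with_missing:
        observed = np.flatnonzero(~mask[:, j])
        if observed.size == 0:
            raise ValidationError(
                f"variable {values.columns[j]!r} has no observed donor values"
            )
    rng = np.random.default_rng(config.seed)
    # initialize missing cells at their variable's observed mean
    for j in cols_with_missing:
        observed = ~mask[:, j]
        X[mask[:, j], j] = X[observed, j].mean()
    for _ in range(config.chained_iterations):
        for j in cols_with_missing:
            missing_rows = np.flatnonzero(mask[:, j])
            observed_rows = np.flatnonzero(~mask[:, j])
            X[missing_rows, j] = _pmm_one_variable(
                X, j, missing_rows, observed_rows, config.k_donors, rng
            )
    result = values.to_numpy(dtype=float).copy()
    result[mask] = X[mask]
    return pd.DataFrame(result, index=values.index, columns=values.columns)


def pmm_impute(
    table: TaxaCountTable,
    labels: pd.Series | pd.DataFrame,
    config: ImputationConfig,
) -> LogCpmMatrix:
    """Impute zeros of the target cities in log2-cpm space.

    The table is normalized to log2-cpm; cells with raw count 0 in samples
    whose city is in ``config.target_cities`` are treated as missing and
    filled by chained PMM.  Samples from other cities are never modified.
    """
    if isinstance(labels, pd.DataFrame):
        labels = city_labels(labels, table.sample_ids)
    labels = labels.loc[table.sample_ids].astype(str)
    matrix = log2cpm(table)
    in_target = labels.isin(config.target_cities).to_numpy()
    mask = pd.DataFrame(
        (table.counts.to_numpy() == 0) & in_target[:, None],
        index=matrix.values.index,
        columns=matrix.values.columns,
    )
    imputed = pmm_impute_values(matrix.values, mask, config)
    return LogCpmMatrix(values=imputed, library_sizes=matrix.library_sizes)


def impute_zero_city_scan(
    bundle,
    impute_config: ImputationConfig | None,
    classifier_config: ClassifierConfig,
    kmax: int | None = None,
) -> pd.DataFrame:
    """Prediction accuracy as a function of the zero-city dataset index k.

    For each k, the species set Dk is built on the training table, the
    training (and test) matrices are restricted to it, optionally imputed,
    both classifiers are run and voted, and the proportion of correctly
    labeled test samples is recorded for RF alone, SVM alone and the vote.
    Returns a frame with columns k, n_species, rf_score, svm_score,
    voted_score.
    """
    meta = bundle.metadata
    train_table = bundle.main_train
    test_table = bundle.mystery1_test
    train_labels = city_labels(meta, train_table.sample_ids)
    truth = (
        meta.set_index("sample_id")["true_city"].loc[test_table.sample_ids]
    )

    family = zero_city_family(train_table, train_labels, kmax=kmax)
    if impute_config is not None:
        train_full = pmm_impute(train_table, train_labels, impute_config)
    else:
        train_full = log2cpm(train_table)
    test_full = log2cpm(test_table)

    rows = []
    for k, species in enumerate(family.datasets):
        if not species:
            rows.append(
                {"k": k, "n_species": 0, "rf_score": float("nan"),
                 "svm_score": float("nan"), "voted_score": float("nan")}
            )
            continue
        train = train_full.subset_species(species)
        test = test_full.subset_species(species)
        rf_pred, _, _ = rf_repeat(train, train_labels, test, classifier_config)
        svm_pred = svm_repeat(train, train_labels, test, classifier_config)
        rf_rec = consolidate_all(rf_pred, "RF")
        svm_rec = consolidate_all(svm_pred, "SVM")
        votes = vote_all(rf_rec, svm_rec)
        summary = evaluate(votes, truth)
        rf_correct = np.mean(
            [rf_rec[s].top_city == str(truth[s]) for s in truth.index]
        )
        svm_correct = np.mean(
            [svm_rec[s].top_city == str(truth[s]) for s in truth.index]
        )
        rows.append(
            {
                "k": k,
                "n_species": len(species),
                "rf_score": float(rf_correct),
                "svm_score": float(svm_correct),
                "voted_score": summary.proportion_correct,
            }
        )
    return pd.DataFrame(rows)
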