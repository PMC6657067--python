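"""Compositional differential abundance between city pairs (ANCOM-style)
and its concordance with classifier variable importance.

For two groups of samples and m species on the log2-cpm scale, every ordered
species pair (i, j) is tested for a group difference of the log-ratio
value_i − value_j (differences of log-scale values are log-ratios, which
honors the compositional constraint).  Per reference species i the m−1
p-values are Benjamini–Hochberg adjusted; W_i counts the rejections at the
chosen significance level.  A species is called significantly differentially
abundant when W_i reaches a detection fraction of m−1 (0.7 by default).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import LogCpmMatrix
from .classify import ImportanceRanking
from .tables import ValidationError, city_labels

__all__ = [
    "AncomPairResult",
    "PairwiseSummary",
    "ancom_two_group",
    "pairwise_city_summary",
    "importance_concordance",
]

logger = logging.getLogger(__name__)


@dataclass
class AncomPairResult:
    pair: tuple[str, str]
    W: pd.Series  # per species, count of rejected log-ratio hypotheses
    significant: pd.Series  # per species, W >= detection_fraction * (m - 1)
    alpha: float
    detection_fraction: float


@dataclass
class PairwiseSummary:
    grid: pd.DataFrame  # species x pair booleans, species sorted by counts desc
    counts: pd.Series  # per species, number of significant pairs
    n_pairs: int
    pair_results: list[AncomPairResult]


def _log_ratio_pvalues(
    a: np.ndarray, b: np.ndarray, test: str
) -> np.ndarray:
    """p-value matrix P[i, j] for the group difference of value_i − value_j."""
    if test not in ("wilcoxon", "ttest"):
        raise ValidationError(f"unknown test {test!r}")
    m = a.shape[1]
    P = np.ones((m, m))
    for i in range(m):
        da = a[:, [i]] - a  # log-ratios of species i vs every other species
        db = b[:, [i]] - b
        with np.errstate(divide="ignore", invalid="ignore"):
            if test == "wilcoxon":
                p = stats.mannwhitneyu(
                    da, db, alternative="two-sided", method="asymptotic", axis=0
                ).pvalue
            else:
                p = stats.ttest_ind(da, db, equal_var=False, axis=0).pvalue
        # constant log-ratio across both groups: no evidence either way
        const = np.ptp(np.vstack([da, db]), axis=0) == 0
        p = np.where(const | np.isnan(p), 1.0, p)
        p[i] = 1.0
        P[i] = p
    return P


def ancom_two_group(
    data: LogCpmMatrix,
    group_labels: pd.Series,
    alpha: float = 0.2,
    detection_fraction: float = 0.7,
    test: str = "wilcoxon",
) -> AncomPairResult:
    """Two-group compositional test returning the per-species W statistic.

    ``group_labels`` must take exactly two values over the matrix's samples,
    each with at least 2 samples.  ``alpha`` is the per-reference-species BH
    level; ``detection_fraction`` thresholds W against m − 1.
    """
    labels = group_labels.loc[data.sample_ids].astype(str)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {groups}")
    sizes = labels.value_counts()
    if sizes.min() < 2:
        raise ValidationError(f"each group needs >= 2 samples, got {dict(sizes)}")
    species = data.species_ids
    m = len(species)
    if m < 2:
        raise ValidationError("need at least 2 species")

    X = data.values.to_numpy(dtype=float)
    a = X[(labels == groups[0]).to_numpy()]
    b = X[(labels == groups[1]).to_numpy()]
    P = _log_ratio_pvalues(a, b, test)

    W = np.zeros(m, dtype=np.int64)
    for i in range(m):
        pvals = np.delete(P[i], i)
        reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        W[i] = int(reject.sum())
    W_series = pd.Series(W, index=species)
    threshold = detection_fraction * (m - 1)
    return AncomPairResult(
        pair=(groups[0], groups[1]),
        W=W_series,
        significant=W_series >= threshold,
        alpha=alpha,
        detection_fraction=detection_fraction,
    )


def pairwise_city_summary(
    data: LogCpmMatrix,
    labels: pd.Series | pd.DataFrame,
    alpha: float = 0.2,
    detection_fraction: float = 0.7,
    test: str = "wilcoxon",
) -> PairwiseSummary:
    """Run the two-group test for every unordered city pair.

    Returns the species x pair significance grid with species sorted by
    descending per-species significant-pair count (ties by species id), the
    counts themselves, and C(#cities, 2).
    """
    if isinstance(labels, pd.DataFrame):
        labels = city_labels(labels, data.sample_ids)
    labels = labels.loc[data.sample_ids].astype(str)
    cities = sorted(labels.unique())
    if len(cities) < 2:
        raise ValidationError("need at least 2 cities")
    results = []
    columns = {}
    for a, b in itertools.combinations(cities, 2):
        mask = labels.isin([a, b])
        sub = data.subset_samples(labels.index[mask])
        res = ancom_two_group(
            sub, labels[mask], alpha=alpha,
            detection_fraction=detection_fraction, test=test,
        )
        results.append(res)
        columns[f"{a}|{b}"] = res.significant
    grid = pd.DataFrame(columns)
    counts = grid.sum(axis=1).astype(int)
    order = sorted(grid.index, key=lambda s: (-counts[s], s))
    grid = grid.loc[order]
    counts = counts.loc[order]
    return PairwiseSummary(
        grid=grid, counts=counts, n_pairs=len(columns), pair_results=results
    )


def importance_concordance(
    summary: PairwiseSummary, importance: ImportanceRanking, top_n: int = 10
) -> dict:
    """Rank concordance between significance counts and mean RF importance.

    Returns the Spearman correlation over the shared species universe and
    the size of the intersection of the two top-``top_n`` lists.
    """
    shared = [s for s in summary.counts.index if s in importance.mean_importance.index]
    if not shared:
        raise ValidationError("no shared species between summary and importance")
    counts = summary.counts.loc[shared]
    imp = importance.mean_importance.loc[shared]
    if counts.nunique() == 1 or imp.nunique() == 1:
        rho = float("nan")  # rank correlation undefined for a constant ranking
    else:
        rho = float(stats.spearmanr(counts, imp).statistic)
    top_counts = set(
        sorted(shared, key=lambda s: (-counts[s], s))[:top_n]
    )
    top_imp = set(
        sorted(shared, key=lambda s: (-imp[s], s))[:top_n]
    )
    return {
        "spearman_rho": rho,
        "overlap_at_top_n": len(top_counts & top_imp),
        "top_n": top_n,
    }
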