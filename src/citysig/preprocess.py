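"""Confidence filtering, rank aggregation, log2-cpm normalization, variable
selection, the zero-city dataset family, missingness profiling, and a PCA
summary.

The normalization is the voom transform: for count ``c`` in a sample with
library size ``L``,

    log2cpm = log2( (c + 0.5) / (L + 1) * 1e6 )

which keeps the logarithm finite at zero counts.  Library sizes are computed
on the species-aggregated table *before* any variable selection, so dropping
variables never changes the normalization of those that remain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import TaxaCountTable, ValidationError, city_labels, lineage_rank_label, RANKS

__all__ = [
    "LogCpmMatrix",
    "ZeroCityFamily",
    "MissingnessProfile",
    "filter_confidence",
    "aggregate_species",
    "aggregate_rank",
    "log2cpm",
    "select_city_common",
    "zero_city_count",
    "zero_city_family",
    "missingness_profile",
    "pca_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class LogCpmMatrix:
    """Samples x species matrix of log2 counts-per-million values."""

    values: pd.DataFrame
    library_sizes: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_species(self, species_ids) -> "LogCpmMatrix":
        return LogCpmMatrix(
            values=self.values[list(species_ids)].copy(),
            library_sizes=self.library_sizes.copy(),
        )

    def subset_samples(self, sample_ids) -> "LogCpmMatrix":
        sample_ids = list(sample_ids)
        return LogCpmMatrix(
            values=self.values.loc[sample_ids].copy(),
            library_sizes=self.library_sizes.loc[sample_ids].copy(),
        )

    def zero_value(self, sample_id: str) -> float:
        """The log2-cpm value a zero count maps to for this sample."""
        L = float(self.library_sizes.loc[sample_id])
        return float(np.log2(0.5 / (L + 1.0) * 1e6))


@dataclass
class ZeroCityFamily:
    """Nested species sets D0 ⊆ D1 ⊆ … ⊆ Dkmax.

    ``datasets[k]`` contains every species whose number of all-zero cities is
    at most ``k`` and which, within each city where it is not all-zero, has
    at least one sample with count >= 2.
    """

    datasets: list[list[str]]
    zero_city_count: pd.Series

    @property
    def kmax(self) -> int:
        return len(self.datasets) - 1

    def sizes(self) -> list[int]:
        return [len(d) for d in self.datasets]

    def to_json_dict(self) -> dict[str, list[str]]:
        return {str(k): list(d) for k, d in enumerate(self.datasets)}


@dataclass
class MissingnessProfile:
    per_variable_zero_fraction: pd.Series
    per_city_distribution: dict[str, pd.Series]
    per_city_median: dict[str, float]
    per_city_low_missing_count: dict[str, int] = field(default_factory=dict)


def filter_confidence(table: TaxaCountTable, threshold: float = 0.5) -> TaxaCountTable:
    """Retain the features whose classifier confidence is >= ``threshold``.

    Features with confidence strictly below the threshold are removed from
    further analysis; counts of retained features are untouched.
    """
    keep = [
        fid
        for fid in table.feature_ids
        if table.confidence.get(fid, 0.0) >= threshold
    ]
    if not keep:
        logger.warning("confidence filter at %.3g removed every feature", threshold)
    return table.subset_features(keep)


def aggregate_rank(table: TaxaCountTable, rank: str = "species") -> TaxaCountTable:
    """Aggregate feature counts to a taxonomic rank.

    At rank ``"species"`` the new feature label is the concatenated
    ``genus_species`` pair and features lacking either a genus or a species
    assignment are dropped.  At coarser ranks the label is the rank's own
    lineage label and features unassigned at that rank are dropped.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}")
    label_of: dict[str, str] = {}
    lineage_of: dict[str, tuple[str, ...]] = {}
    idx = RANKS.index(rank)
    for fid in table.feature_ids:
        lineage = table.taxonomy.get(fid, ())
        if rank == "species":
            genus = lineage_rank_label(lineage, "genus")
            species = lineage_rank_label(lineage, "species")
            if not genus or not species:
                continue
            label = f"{genus}_{species}"
        else:
            label = lineage_rank_label(lineage, rank)
            if not label:
                continue
        label_of[fid] = label
        lineage_of.setdefault(label, tuple(lineage[: idx + 1]))

    kept = [fid for fid in table.feature_ids if fid in label_of]
    if not kept:
        logger.warning("no features reach rank %r; result is empty", rank)
        empty = pd.DataFrame(index=table.counts.index)
        return TaxaCountTable(counts=empty, taxonomy={}, confidence={}, rank=rank)

    groups = pd.Index([label_of[fid] for fid in kept], name="feature_id")
    summed = table.counts[kept].T.groupby(groups, sort=False).sum().T
    return TaxaCountTable(
        counts=summed.astype(np.int64),
        taxonomy={label: lineage_of[label] for label in summed.columns},
        confidence={},
        rank=rank,
    )


def aggregate_species(table: TaxaCountTable) -> TaxaCountTable:
    """Aggregate to genus_species labels, summing counts within each label."""
    return aggregate_rank(table, "species")


def log2cpm(table: TaxaCountTable) -> LogCpmMatrix:
    """The voom transform: log2((count + 0.5) / (library_size + 1) * 1e6)."""
    libs = table.library_sizes()
    zero_lib = libs[libs <= 0]
    if len(zero_lib):
        raise ValidationError(
            f"zero library size for sample(s): {list(zero_lib.index)}"
        )
    values = np.log2(
        (table.counts.to_numpy(dtype=float) + 0.5)
        / (libs.to_numpy(dtype=float)[:, None] + 1.0)
        * 1e6
    )
    return LogCpmMatrix(
        values=pd.DataFrame(values, index=table.counts.index, columns=table.counts.columns),
        library_sizes=libs.astype(np.int64),
    )


def _cities_with_samples(labels: pd.Series) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for sid, city in labels.items():
        if pd.isna(city):
            raise ValidationError(f"sample {sid!r} has no city label")
        groups.setdefault(str(city), []).append(sid)
    return groups


def select_city_common(table: TaxaCountTable, labels: pd.Series | pd.DataFrame) -> list[str]:
    """Species present (count >= 2 in at least one sample) in every city.

    ``labels`` is either a Series of city per sample id or a metadata frame.
    The rule guarantees non-zero within-city variance for every retained
    variable.
    """
    if isinstance(labels, pd.DataFrame):
        labels = city_labels(labels, table.sample_ids)
    groups = _cities_with_samples(labels.loc[table.sample_ids])
    empty = [c for c, sids in groups.items() if not sids]
    if empty or not groups:
        raise ValidationError(f"cities without samples: {empty or 'no cities at all'}")
    keep_mask = np.ones(table.n_features, dtype=bool)
    for sids in groups.values():
        city_max = table.counts.loc[sids].max(axis=0).to_numpy()
        keep_mask &= city_max >= 2
    return [f for f, k in zip(table.feature_ids, keep_mask) if k]


def zero_city_count(table: TaxaCountTable, labels: pd.Series | pd.DataFrame) -> pd.Series:
    """Per species, the number of cities in which every sample has count 0."""
    if isinstance(labels, pd.DataFrame):
        labels = city_labels(labels, table.sample_ids)
    groups = _cities_with_samples(labels.loc[table.sample_ids])
    zeros = np.zeros(table.n_features, dtype=np.int64)
    for sids in groups.values():
        all_zero = (table.counts.loc[sids].sum(axis=0) == 0).to_numpy()
        zeros += all_zero
    return pd.Series(zeros, index=table.feature_ids)


def zero_city_family(
    table: TaxaCountTable,
    labels: pd.Series | pd.DataFrame,
    kmax: int | None = None,
) -> ZeroCityFamily:
    """The nested dataset family D0 ⊆ … ⊆ Dkmax.

    D0 is the city-common selection; Dk adds every species with exactly k
    all-zero cities, provided it has a count >= 2 in each city where it is
    not all-zero.
    """
    if isinstance(labels, pd.DataFrame):
        labels = city_labels(labels, table.sample_ids)
    labels = labels.loc[table.sample_ids]
    groups = _cities_with_samples(labels)
    n_cities = len(groups)
    if kmax is None:
        kmax = n_cities - 1
    if kmax >= n_cities:
        raise ValidationError(f"kmax={kmax} must be < number of cities ({n_cities})")

    zcc = zero_city_count(table, labels)
    # per species: in each non-all-zero city, is there a sample with count >= 2?
    ok_nonzero = np.ones(table.n_features, dtype=bool)
    for sids in groups.values():
        sub = table.counts.loc[sids]
        city_max = sub.max(axis=0).to_numpy()
        city_all_zero = sub.sum(axis=0).to_numpy() == 0
        ok_nonzero &= city_all_zero | (city_max >= 2)
    eligible = pd.Series(ok_nonzero, index=table.feature_ids)

    datasets = []
    for k in range(kmax + 1):
        members = [
            f for f in table.feature_ids if zcc[f] <= k and eligible[f]
        ]
        datasets.append(members)
    return ZeroCityFamily(datasets=datasets, zero_city_count=zcc)


def missingness_profile(
    table: TaxaCountTable, labels: pd.Series | pd.DataFrame, low_missing_cutoff: float = 0.25
) -> MissingnessProfile:
    """Zero-count fractions per variable, overall and within each city.

    Also reports, per city, the count of variables with at most
    ``low_missing_cutoff`` zeros (the variables with usable signal).
    """
    if isinstance(labels, pd.DataFrame):
        labels = city_labels(labels, table.sample_ids)
    labels = labels.loc[table.sample_ids]
    zero = table.counts == 0
    overall = zero.mean(axis=0)
    per_city: dict[str, pd.Series] = {}
    medians: dict[str, float] = {}
    low: dict[str, int] = {}
    for city, sids in _cities_with_samples(labels).items():
        frac = zero.loc[sids].mean(axis=0)
        per_city[city] = frac
        medians[city] = float(frac.median())
        low[city] = int((frac <= low_missing_cutoff).sum())
    return MissingnessProfile(
        per_variable_zero_fraction=overall,
        per_city_distribution=per_city,
        per_city_median=medians,
        per_city_low_missing_count=low,
    )


def pca_summary(
    matrix: LogCpmMatrix, n_components: int = 3, scale: bool = False
) -> dict:
    """Principal components of the centered log2-cpm matrix.

    Returns scores for the first ``n_components`` components, the loadings,
    and the fraction of total variance each reported component explains
    (eigenvalue over the eigenvalue total).  Variables are centered but not
    variance-scaled by default (log2-cpm is already on a common scale);
    pass ``scale=True`` for a correlation-based analysis.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples and 2 species")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValidationError("constant variable: cannot scale for PCA")
        X = X / sd
    if not np.any(X):
        raise ValidationError("degenerate (constant) matrix: PCA undefined")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign convention: largest-|loading| entry positive
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    var = s**2 / (X.shape[0] - 1)
    fractions = var / var.sum()
    k = min(n_components, len(s))
    scores = pd.DataFrame(
        U[:, :k] * s[:k],
        index=matrix.values.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    loadings = pd.DataFrame(
        Vt[:k].T,
        index=matrix.values.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return {
        "scores": scores,
        "loadings": loadings,
        "variance_fractions": fractions[:k],
        "all_variance_fractions": fractions,
    }
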