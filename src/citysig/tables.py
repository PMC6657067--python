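"""Count-table and sample-metadata containers with TSV and BIOM-v1-JSON I/O.

This module is the boundary between upstream bioinformatics (read QC, OTU
picking, taxonomy assignment — all out of scope here) and the analysis
pipeline.  A :class:`TaxaCountTable` holds a samples x features matrix of
non-negative integer counts together with per-feature taxonomy lineages and
the taxonomy classifier's bootstrap confidence score; a
:class:`SampleMetadata` table maps each sample to a city label and to one of
the four challenge sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "SET_NAMES",
    "TaxaCountTable",
    "ValidationError",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
]

#: Ordered taxonomic ranks carried in lineage strings.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: The four challenge set names: the 8-city main training set, its multi-city
#: test set, the secondary 3-city training set, and its test set (which may
#: contain samples from a city never seen in training).
SET_NAMES = ("training_main", "mystery1", "training_mystery2", "mystery3")

_RESERVED_COLUMNS = ("taxonomy", "confidence")


class ValidationError(ValueError):
    """Raised when a table or metadata file violates a structural invariant."""


@dataclass
class TaxaCountTable:
    """Samples x features table of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, one column per feature, integer dtype.
    taxonomy
        Per feature, the ordered lineage labels (tuple aligned with
        :data:`RANKS`; trailing ranks may be ``""`` when unassigned).
    confidence
        Per feature, the taxonomy classifier confidence in [0, 1].
    rank
        The taxonomic level the features currently represent (``"otu"`` for
        raw picked features, or an aggregated rank such as ``"species"``).
    """

    counts: pd.DataFrame
    taxonomy: dict[str, tuple[str, ...]] = field(default_factory=dict)
    confidence: dict[str, float] = field(default_factory=dict)
    rank: str = "otu"

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dupes}")
        values = counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise ValidationError("counts must be numeric")
            if np.any(values < 0):
                raise ValidationError("negative counts are not allowed")
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integral")
        for fid in counts.columns:
            conf = self.confidence.get(fid)
            if conf is not None and not (0.0 <= conf <= 1.0):
                raise ValidationError(
                    f"confidence for feature {fid!r} outside [0, 1]: {conf}"
                )

    # ------------------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        """Total counts per sample (the counts-per-million denominator)."""
        return self.counts.sum(axis=1)

    def subset_features(self, feature_ids) -> "TaxaCountTable":
        feature_ids = list(feature_ids)
        return TaxaCountTable(
            counts=self.counts[feature_ids].copy(),
            taxonomy={f: self.taxonomy[f] for f in feature_ids if f in self.taxonomy},
            confidence={
                f: self.confidence[f] for f in feature_ids if f in self.confidence
            },
            rank=self.rank,
        )

    def subset_samples(self, sample_ids) -> "TaxaCountTable":
        sample_ids = list(sample_ids)
        return TaxaCountTable(
            counts=self.counts.loc[sample_ids].copy(),
            taxonomy=dict(self.taxonomy),
            confidence=dict(self.confidence),
            rank=self.rank,
        )

    def equals(self, other: "TaxaCountTable", conf_tol: float = 1e-9) -> bool:
        if self.rank != other.rank:
            return False
        if not self.counts.equals(other.counts):
            return False
        if self.taxonomy != other.taxonomy:
            return False
        if set(self.confidence) != set(other.confidence):
            return False
        return all(
            abs(self.confidence[f] - other.confidence[f]) <= conf_tol
            for f in self.confidence
        )


def _lineage_to_string(lineage: tuple[str, ...]) -> str:
    # Trailing unassigned ranks are dropped so truncated lineages round-trip.
    parts = list(lineage)
    while parts and parts[-1] == "":
        parts.pop()
    return ";".join(parts)


def _string_to_lineage(text: str) -> tuple[str, ...]:
    if not text:
        return ()
    return tuple(part.strip() for part in str(text).split(";"))


def lineage_rank_label(lineage: tuple[str, ...], rank: str) -> str:
    """Label at ``rank`` in an ordered lineage, or ``""`` when unassigned."""
    idx = RANKS.index(rank)
    if idx < len(lineage):
        return lineage[idx]
    return ""


# ----------------------------------------------------------------------
# TSV dialect: features as rows, samples as columns, trailing reserved
# columns "taxonomy" (semicolon-separated lineage) and "confidence".
# ----------------------------------------------------------------------

def _read_tsv(path) -> TaxaCountTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise ValidationError("duplicate feature ids in TSV")
    sample_cols = [c for c in df.columns if c not in _RESERVED_COLUMNS]
    if len(set(sample_cols)) != len(sample_cols):
        raise ValidationError("duplicate sample ids in TSV header")
    counts = pd.DataFrame(index=df.index, columns=sample_cols, dtype=float)
    for col in sample_cols:
        try:
            counts[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"malformed numeric cell in column {col!r}, row(s) {list(bad)}"
            ) from exc
    values = counts.to_numpy()
    if values.size and (np.any(values < 0) or not np.allclose(values, np.round(values))):
        raise ValidationError("counts must be non-negative integers")
    taxonomy = {}
    confidence = {}
    if "taxonomy" in df.columns:
        taxonomy = {
            fid: _string_to_lineage(val if pd.notna(val) else "")
            for fid, val in df["taxonomy"].items()
        }
    if "confidence" in df.columns:
        confidence = {
            fid: float(val) for fid, val in df["confidence"].items() if pd.notna(val)
        }
    # features-as-rows on disk -> samples-as-rows in memory
    matrix = counts.T.astype(np.int64)
    matrix.index.name = "sample_id"
    return TaxaCountTable(
        counts=matrix, taxonomy=taxonomy, confidence=confidence, rank="otu"
    )


def _write_tsv(table: TaxaCountTable, path) -> None:
    df = table.counts.T.astype(np.int64).astype(object)
    df.insert(
        len(df.columns),
        "taxonomy",
        [_lineage_to_string(table.taxonomy.get(f, ())) for f in df.index],
    )
    df.insert(
        len(df.columns),
        "confidence",
        [
            "" if table.confidence.get(f) is None else format(table.confidence[f], ".6g")
            for f in df.index
        ],
    )
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


# ----------------------------------------------------------------------
# BIOM v1 JSON dialect (dense or sparse), taxonomy under observation
# metadata key "taxonomy", confidence under "confidence".
# ----------------------------------------------------------------------

def _read_biom_json(path) -> TaxaCountTable:
    with open(path) as handle:
        doc = json.load(handle)
    obs_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    shape = tuple(doc["shape"])
    matrix = np.zeros(shape, dtype=np.int64)
    data = doc["data"]
    if doc.get("matrix_type") == "sparse":
        for i, j, v in data:
            matrix[i, j] = v
    else:
        matrix[:, :] = np.asarray(data)
    taxonomy = {}
    confidence = {}
    for row in doc["rows"]:
        meta = row.get("metadata") or {}
        if "taxonomy" in meta and meta["taxonomy"] is not None:
            tax = meta["taxonomy"]
            if isinstance(tax, str):
                taxonomy[row["id"]] = _string_to_lineage(tax)
            else:
                taxonomy[row["id"]] = tuple(tax)
        if "confidence" in meta and meta["confidence"] is not None:
            confidence[row["id"]] = float(meta["confidence"])
    counts = pd.DataFrame(matrix.T, index=sample_ids, columns=obs_ids)
    counts.index.name = "sample_id"
    return TaxaCountTable(
        counts=counts, taxonomy=taxonomy, confidence=confidence, rank="otu"
    )


def _write_biom_json(table: TaxaCountTable, path) -> None:
    matrix = table.counts.T.to_numpy(dtype=np.int64)  # observations x samples
    data = [
        [int(i), int(j), int(matrix[i, j])]
        for i, j in zip(*np.nonzero(matrix))
    ]
    rows = []
    for fid in table.feature_ids:
        meta: dict = {}
        if fid in table.taxonomy:
            meta["taxonomy"] = list(table.taxonomy[fid])
        if fid in table.confidence:
            meta["confidence"] = table.confidence[fid]
        rows.append({"id": fid, "metadata": meta or None})
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "citysig",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [len(rows), table.n_samples],
        "rows": rows,
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    with open(path, "w") as handle:
        json.dump(doc, handle)


def read_count_table(path, format: str = "tsv") -> TaxaCountTable:
    """Read a count table from ``path`` in the declared dialect.

    ``format`` is ``"tsv"`` (features as rows, reserved trailing ``taxonomy``
    and ``confidence`` columns) or ``"biom-json"`` (standard v1 layout).
    Feature and sample order is preserved from the file.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown count-table format: {format!r}")


def write_count_table(table: TaxaCountTable, path, format: str = "tsv") -> None:
    """Write ``table`` so that :func:`read_count_table` recovers an equal table."""
    if format == "tsv":
        _write_tsv(table, path)
    elif format == "biom-json":
        _write_biom_json(table, path)
    else:
        raise ValueError(f"unknown count-table format: {format!r}")


# ----------------------------------------------------------------------
# Sample metadata
# ----------------------------------------------------------------------

def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "city", "set"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicated sample_id in metadata: {dupes}")
    bad_sets = set(meta["set"].dropna()) - set(SET_NAMES)
    if bad_sets:
        raise ValidationError(
            f"unknown set name(s) {sorted(bad_sets)}; expected one of {SET_NAMES}"
        )
    if "true_city" not in meta.columns:
        meta = meta.assign(true_city=pd.NA)
    training = meta["set"].isin(["training_main", "training_mystery2"])
    if meta.loc[training, "city"].isna().any():
        raise ValidationError("training samples must have a non-null city label")
    return meta


def read_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV (columns sample_id, city, set[, true_city])."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    cols = ["sample_id", "city", "set"]
    if "true_city" in meta.columns:
        cols.append("true_city")
    meta[cols].to_csv(path, sep="\t", index=False)


def metadata_for(meta: pd.DataFrame, table: TaxaCountTable) -> pd.DataFrame:
    """Metadata rows for the table's samples, in table order; errors if any are absent."""
    meta = meta.set_index("sample_id", drop=False)
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    return meta.loc[table.sample_ids].reset_index(drop=True)


def city_labels(meta: pd.DataFrame, sample_ids) -> pd.Series:
    """City label per sample id (index = sample id), from the ``city`` column."""
    lookup = meta.set_index("sample_id")["city"]
    missing = [s for s in sample_ids if s not in lookup.index]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    return lookup.loc[list(sample_ids)]
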