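"""End-to-end orchestration: preprocess -> classify -> vote -> evaluate ->
pairwise differential abundance -> importance concordance, with every output
declared in a checksummed MANIFEST.

Used by the ``run-all`` CLI subcommand and importable directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import preprocess, diff_abundance
from .classify import ClassifierConfig, rf_repeat, svm_repeat, consolidate_all
from .tables import read_count_table, read_metadata, city_labels, ValidationError
from .vote import vote_all, evaluate, votes_to_frame

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for a full run (YAML-serializable)."""

    train_table: str
    test_table: str
    metadata: str
    outdir: str
    table_format: str = "tsv"
    confidence_threshold: float = 0.5
    rank: str = "species"
    repetitions: int = 100
    rf_n_trees: int = 1000
    rf_vars_per_split: int = 20
    svm_cost: float = 1000.0
    svm_city_fold: int = 5
    ancom_alpha: float = 0.2
    ancom_detection_fraction: float = 0.7
    run_ancom: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            doc = yaml.safe_load(handle) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        missing = {"train_table", "test_table", "metadata", "outdir"} - set(doc)
        if missing:
            raise ValidationError(f"config missing required keys: {sorted(missing)}")
        return cls(**doc)

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            rf_n_trees=self.rf_n_trees,
            rf_vars_per_split=self.rf_vars_per_split,
            svm_cost=self.svm_cost,
            svm_city_fold=self.svm_city_fold,
            repetitions=self.repetitions,
            seed=self.seed,
        )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write its artifacts to ``outdir``.

    Returns a dict with the evaluation summary and paths of the written
    files.  Stage completions are recorded in MANIFEST.json together with a
    sha256 checksum per output file; a failed stage leaves the partial
    MANIFEST behind.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "files": {}}
    manifest_path = outdir / "MANIFEST.json"

    def checkpoint(stage: str, files: dict[str, Path]) -> None:
        manifest["stages"].append(stage)
        for name, path in files.items():
            manifest["files"][name] = {
                "path": str(path.relative_to(outdir)),
                "sha256": _sha256(path),
            }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    t0 = time.time()
    meta = read_metadata(config.metadata)
    train_raw = read_count_table(config.train_table, config.table_format)
    test_raw = read_count_table(config.test_table, config.table_format)

    # --- preprocess -------------------------------------------------
    train_filtered = preprocess.filter_confidence(train_raw, config.confidence_threshold)
    test_filtered = preprocess.filter_confidence(test_raw, config.confidence_threshold)
    train_agg = preprocess.aggregate_rank(train_filtered, config.rank)
    test_agg = preprocess.aggregate_rank(test_filtered, config.rank)
    train_labels = city_labels(meta, train_agg.sample_ids)
    selected = preprocess.select_city_common(train_agg, train_labels)
    shared = [s for s in selected if s in test_agg.counts.columns]
    if len(shared) < len(selected):
        logger.warning(
            "%d selected species absent from the test table were dropped",
            len(selected) - len(shared),
        )
    train_matrix = preprocess.log2cpm(train_agg).subset_species(shared)
    test_matrix = preprocess.log2cpm(test_agg).subset_species(shared)
    matrix_path = outdir / "train_log2cpm.tsv"
    train_matrix.values.to_csv(matrix_path, sep="\t")
    family = preprocess.zero_city_family(train_agg, train_labels)
    family_path = outdir / "zero_city_family.json"
    family_path.write_text(json.dumps(family.to_json_dict(), indent=0, sort_keys=True))
    checkpoint("preprocess", {"train_log2cpm": matrix_path, "zero_city_family": family_path})
    logger.info(
        "preprocess: %d species selected of %d aggregated (%.1fs)",
        len(shared), train_agg.n_features, time.time() - t0,
    )

    # --- classify ---------------------------------------------------
    t1 = time.time()
    clf_config = config.classifier_config()
    rf_pred, oob_records, importance = rf_repeat(
        train_matrix, train_labels, test_matrix, clf_config
    )
    svm_pred = svm_repeat(train_matrix, train_labels, test_matrix, clf_config)
    rf_records = consolidate_all(rf_pred, "RF")
    svm_records = consolidate_all(svm_pred, "SVM")
    importance_path = outdir / "rf_importance.tsv"
    importance.mean_importance.sort_values(ascending=False).to_csv(
        importance_path, sep="\t", header=["mean_normalized_importance"]
    )
    oob_path = outdir / "rf_oob_error.tsv"
    pd.DataFrame(
        [
            {"repetition": r.repetition, "oob_overall": r.oob_overall, **{
                f"oob_{c}": v for c, v in r.oob_per_city.items()
            }}
            for r in oob_records
        ]
    ).to_csv(oob_path, sep="\t", index=False)
    checkpoint("classify", {"rf_importance": importance_path, "rf_oob_error": oob_path})
    logger.info("classify: %d repetitions (%.1fs)", clf_config.repetitions, time.time() - t1)

    # --- vote + evaluate -------------------------------------------
    votes = vote_all(rf_records, svm_records)
    truth = meta.set_index("sample_id")["true_city"]
    truth = truth.loc[[v.sample_id for v in votes]]
    have_truth = truth.notna().all()
    if have_truth:
        summary = evaluate(votes, truth)
        eval_dict = {
            "n_samples": summary.n_samples,
            "n_correct": summary.n_correct,
            "proportion_correct": summary.proportion_correct,
            "upper_bound_correct": summary.upper_bound_correct,
            "n_inconclusive": summary.n_inconclusive,
        }
    else:
        for v in votes:
            v.true_city = None
        eval_dict = {"n_samples": len(votes)}
    votes_path = outdir / "votes.tsv"
    votes_to_frame(votes).to_csv(votes_path, sep="\t", index=False)
    eval_path = outdir / "evaluation.json"
    eval_path.write_text(json.dumps(eval_dict, indent=2, sort_keys=True))
    checkpoint("vote", {"votes": votes_path, "evaluation": eval_path})

    # --- differential abundance ------------------------------------
    result = {"evaluation": eval_dict, "outdir": str(outdir)}
    if config.run_ancom:
        t2 = time.time()
        summary_da = diff_abundance.pairwise_city_summary(
            train_matrix,
            train_labels,
            alpha=config.ancom_alpha,
            detection_fraction=config.ancom_detection_fraction,
        )
        grid_path = outdir / "ancom_grid.tsv"
        grid = summary_da.grid.astype(int)
        grid["n_significant_pairs"] = summary_da.counts
        grid.to_csv(grid_path, sep="\t")
        concord = diff_abundance.importance_concordance(summary_da, importance)
        concord_path = outdir / "concordance.json"
        concord_path.write_text(json.dumps(concord, indent=2, sort_keys=True))
        checkpoint("ancom", {"ancom_grid": grid_path, "concordance": concord_path})
        logger.info("ancom: %d pairs (%.1fs)", summary_da.n_pairs, time.time() - t2)
        result["concordance"] = concord
        result["n_pairs"] = summary_da.n_pairs
    return result
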