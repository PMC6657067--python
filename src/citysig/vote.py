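"""Adjusted-score computation, the two-classifier voting rule, and
evaluation against true labels.

For a consolidated prediction with score ``s`` in (0, 1] and ``d``
departures (distinct predicted cities minus one), the adjusted score is

    adjusted = s^2 / (d + 1)

i.e. the score squared divided by the number of distinct predicted cities.
Each test sample receives the label of whichever classifier (RF or SVM) has
the strictly higher adjusted score; when both adjusted scores are equal (to
3-decimal reporting precision) and the two classifiers name different
cities, the vote is INCONCLUSIVE, which never counts as correct.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .classify import ConsolidationRecord
from .tables import ValidationError

__all__ = [
    "INCONCLUSIVE",
    "VoteResult",
    "EvaluationSummary",
    "adjusted_score",
    "round_adjusted",
    "vote_sample",
    "vote_all",
    "evaluate",
    "upper_bound",
    "votes_to_frame",
    "load_published_votes",
]

INCONCLUSIVE = "Inconclusive"


def adjusted_score(score: float, departures: int) -> float:
    """score^2 / (departures + 1); raw (unrounded) value."""
    if not (0.0 < score <= 1.0):
        raise ValidationError(f"score must lie in (0, 1]: {score}")
    if departures < 0:
        raise ValidationError(f"departures must be >= 0: {departures}")
    return score * score / (departures + 1)


def round_adjusted(value: float, ndigits: int = 3) -> float:
    """Half-up rounding used for reported adjusted scores."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class VoteResult:
    sample_id: str
    rf_city: str
    rf_score: float
    rf_departures: int
    rf_adjusted: float
    svm_city: str
    svm_score: float
    svm_departures: int
    svm_adjusted: float
    final: str
    true_city: str | None = None

    @property
    def correct(self) -> bool | None:
        if self.true_city is None:
            return None
        return self.final != INCONCLUSIVE and self.final == self.true_city

    @property
    def status(self) -> str:
        if self.final == INCONCLUSIVE:
            return "INCONCLUSIVE"
        if self.true_city is None:
            return ""
        return "CORRECT" if self.correct else "WRONG"


@dataclass
class EvaluationSummary:
    n_samples: int
    n_correct: int
    proportion_correct: float
    upper_bound_correct: int
    n_inconclusive: int


def vote_sample(
    rf: ConsolidationRecord, svm: ConsolidationRecord, ndigits: int = 3
) -> VoteResult:
    """Vote between the two classifiers' consolidated predictions.

    Adjusted scores are compared at ``ndigits`` reporting precision; an
    exact tie with differing cities yields INCONCLUSIVE.
    """
    if rf.sample_id != svm.sample_id:
        raise ValidationError(
            f"sample id mismatch: {rf.sample_id!r} vs {svm.sample_id!r}"
        )
    rf_adj = adjusted_score(rf.score, rf.departures)
    svm_adj = adjusted_score(svm.score, svm.departures)
    rf_r = round_adjusted(rf_adj, ndigits)
    svm_r = round_adjusted(svm_adj, ndigits)
    if rf_r > svm_r:
        final = rf.top_city
    elif svm_r > rf_r:
        final = svm.top_city
    elif rf.top_city == svm.top_city:
        final = rf.top_city
    else:
        final = INCONCLUSIVE
    return VoteResult(
        sample_id=rf.sample_id,
        rf_city=rf.top_city,
        rf_score=rf.score,
        rf_departures=rf.departures,
        rf_adjusted=rf_adj,
        svm_city=svm.top_city,
        svm_score=svm.score,
        svm_departures=svm.departures,
        svm_adjusted=svm_adj,
        final=final,
    )


def vote_all(
    rf_records: dict[str, ConsolidationRecord],
    svm_records: dict[str, ConsolidationRecord],
) -> list[VoteResult]:
    if set(rf_records) != set(svm_records):
        raise ValidationError("RF and SVM records cover different samples")
    return [vote_sample(rf_records[sid], svm_records[sid]) for sid in rf_records]


def _attach_truth(votes: list[VoteResult], truth: pd.Series | dict) -> None:
    truth = dict(truth)
    missing = [v.sample_id for v in votes if v.sample_id not in truth]
    if missing:
        raise ValidationError(f"samples without a true label: {missing}")
    for v in votes:
        v.true_city = str(truth[v.sample_id])


def evaluate(
    votes: list[VoteResult],
    truth: pd.Series | dict,
    exclude: set[str] | None = None,
) -> EvaluationSummary:
    """Count correct votes; optionally exclude samples whose truth is in
    ``exclude`` (e.g. a city absent from training, which no classifier can
    name).  Also reports the optimized-voting upper bound: the number of
    samples where at least one classifier's top city equals the truth.
    """
    _attach_truth(votes, truth)
    kept = [
        v for v in votes if not (exclude and v.true_city in exclude)
    ]
    n_correct = sum(1 for v in kept if v.correct)
    ub = sum(
        1 for v in kept if v.true_city in (v.rf_city, v.svm_city)
    )
    n = len(kept)
    return EvaluationSummary(
        n_samples=n,
        n_correct=n_correct,
        proportion_correct=(n_correct / n) if n else float("nan"),
        upper_bound_correct=ub,
        n_inconclusive=sum(1 for v in kept if v.final == INCONCLUSIVE),
    )


def upper_bound(
    rf_records: dict[str, ConsolidationRecord],
    svm_records: dict[str, ConsolidationRecord],
    truth: pd.Series | dict,
) -> int:
    """Samples where at least one classifier's top city equals the truth."""
    if set(rf_records) != set(svm_records):
        raise ValidationError("RF and SVM records cover different samples")
    truth = dict(truth)
    missing = [sid for sid in rf_records if sid not in truth]
    if missing:
        raise ValidationError(f"samples without a true label: {missing}")
    return sum(
        1
        for sid in rf_records
        if str(truth[sid]) in (rf_records[sid].top_city, svm_records[sid].top_city)
    )


def votes_to_frame(votes: list[VoteResult]) -> pd.DataFrame:
    """Published-table-shaped frame: per sample, both classifiers' partial
    results, the voted final label, the truth and the status."""
    return pd.DataFrame(
        {
            "sample_id": [v.sample_id for v in votes],
            "rf_prediction": [v.rf_city for v in votes],
            "rf_score": [v.rf_score for v in votes],
            "rf_departures": [v.rf_departures for v in votes],
            "rf_adjusted": [round_adjusted(v.rf_adjusted) for v in votes],
            "svm_prediction": [v.svm_city for v in votes],
            "svm_score": [v.svm_score for v in votes],
            "svm_departures": [v.svm_departures for v in votes],
            "svm_adjusted": [round_adjusted(v.svm_adjusted) for v in votes],
            "final": [v.final for v in votes],
            "true_city": [v.true_city for v in votes],
            "status": [v.status for v in votes],
        }
    )


def load_published_votes() -> pd.DataFrame:
    """The packaged transcription of the published per-sample voting table.

    46 rows (30 first-test-set samples, 16 second-test-set samples) with
    each classifier's predicted city, prediction score, departures and
    reported adjusted score, plus the reported final vote and true label.
    """
    ref = importlib.resources.files("citysig").joinpath("data/published_votes.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("rf_score", "rf_adjusted", "svm_score", "svm_adjusted"):
        df[col] = df[col].astype(float)
    for col in ("rf_departures", "svm_departures"):
        df[col] = df[col].astype(int)
    return df


def published_records(df: pd.DataFrame) -> tuple[
    dict[str, ConsolidationRecord], dict[str, ConsolidationRecord], dict[str, str]
]:
    """Rebuild ConsolidationRecords from the published (printed) table.

    The printed score and departures determine the record exactly up to the
    full hit map, which the voting arithmetic never needs beyond the top
    city; synthetic hit maps consistent with (score, departures) are used.
    """
    rf, svm, truth = {}, {}, {}
    for _, row in df.iterrows():
        for clf, prefix, out in (("RF", "rf", rf), ("SVM", "svm", svm)):
            score = float(row[f"{prefix}_score"])
            dep = int(row[f"{prefix}_departures"])
            reps = 10_000
            top = int(round(score * reps))
            rest = reps - top
            hits = {str(row[f"{prefix}_prediction"]): top}
            for i in range(dep):
                share = rest // dep if i < dep - 1 else rest - (rest // dep) * (dep - 1)
                hits[f"_other{i}"] = share
            out[row["sample_id"]] = ConsolidationRecord(
                sample_id=row["sample_id"],
                classifier=clf,
                city_hits=hits,
                top_city=str(row[f"{prefix}_prediction"]),
                score=score,
                distinct_cities=dep + 1,
                departures=dep,
            )
        truth[row["sample_id"]] = str(row["true_city"])
    return rf, svm, truth
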