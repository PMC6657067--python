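"""Recompute the published per-sample voting table from its printed inputs.

Rebuilds each classifier's consolidated prediction from the printed
(city, score, departures) triples, recomputes adjusted scores and the voted
final label, and summarizes accuracy per test set.
"""

from citysig.vote import evaluate, load_published_votes, published_records, vote_all

table = load_published_votes()
rf, svm, truth = published_records(table)
votes = {v.sample_id: v for v in vote_all(rf, svm)}

for set_name, label in (("mystery1", "first test set"), ("mystery3", "second test set")):
    ids = table.loc[table["set"] == set_name, "sample_id"]
    summary = evaluate([votes[s] for s in ids], truth)
    print(
        f"{label}: {summary.n_correct}/{summary.n_samples} voted correctly "
        f"({100 * summary.proportion_correct:.1f}%), "
        f"optimized-voting upper bound {summary.upper_bound_correct}, "
        f"{summary.n_inconclusive} inconclusive"
    )

excl = evaluate(
    [votes[s] for s in table.loc[table["set"] == "mystery3", "sample_id"]],
    truth,
    exclude={"Bogota"},
)
print(
    f"second test set without the untrained city: "
    f"{excl.n_correct}/{excl.n_samples} = {100 * excl.proportion_correct:.1f}%"
)
# The voted accuracy is what the two-classifier adjusted-score vote achieves;
# the upper bound counts samples where at least one classifier was right.
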