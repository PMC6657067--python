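"""Simulate a challenge-shaped dataset and run the full prediction pipeline.

Generates 8 training cities (211 samples) plus a 30-sample multi-city test
set, preprocesses (confidence filter, species aggregation, log2-cpm,
city-common selection), runs both repeated classifiers at a reduced scale
(20 repetitions, 200-tree forests) and votes.
"""

from citysig import (
    ClassifierConfig,
    aggregate_species,
    consolidate_all,
    evaluate,
    filter_confidence,
    log2cpm,
    make_default_design,
    rf_repeat,
    select_city_common,
    simulate_challenge,
    svm_repeat,
    vote_all,
)
from citysig.tables import city_labels

design = make_default_design(seed=7)
bundle = simulate_challenge(design, seed=7)
meta = bundle.metadata

train = aggregate_species(filter_confidence(bundle.main_train))
test = aggregate_species(filter_confidence(bundle.mystery1_test))
labels = city_labels(meta, train.sample_ids)
selected = select_city_common(train, labels)
print(f"{train.n_features} species after aggregation, {len(selected)} city-common")

train_m = log2cpm(train).subset_species(selected)
test_m = log2cpm(test).subset_species(selected)

config = ClassifierConfig(repetitions=20, rf_n_trees=200, seed=7)
rf_pred, oob, importance = rf_repeat(train_m, labels, test_m, config)
svm_pred = svm_repeat(train_m, labels, test_m, config)

import numpy as np
oob_acc = 1 - np.mean([e.oob_overall for e in oob])
print(f"mean RF out-of-bag accuracy over {len(oob)} refits: {oob_acc:.3f}")

votes = vote_all(consolidate_all(rf_pred, "RF"), consolidate_all(svm_pred, "SVM"))
truth = meta.set_index("sample_id")["true_city"].loc[test_m.sample_ids]
summary = evaluate(votes, truth)
print(
    f"voted: {summary.n_correct}/{summary.n_samples} test samples correct "
    f"({100 * summary.proportion_correct:.1f}%), upper bound "
    f"{summary.upper_bound_correct}, {summary.n_inconclusive} inconclusive"
)
print("top 5 important species:", ", ".join(importance.top(5)))
# OOB accuracy reflects training-city separability; the voted accuracy is
# the fraction of unseen-provenance samples attributed to the right city.
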