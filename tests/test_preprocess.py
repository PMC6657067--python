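"""Filtering, aggregation, normalization, selection, zero-city family,
missingness and PCA."""

import numpy as np
import pandas as pd
import pytest

from citysig.preprocess import (
    aggregate_species,
    filter_confidence,
    log2cpm,
    missingness_profile,
    pca_summary,
    select_city_common,
    zero_city_count,
    zero_city_family,
)
from citysig.tables import TaxaCountTable, ValidationError
from conftest import make_matrix, random_table


def _table(counts, **kw):
    return TaxaCountTable(counts=pd.DataFrame(counts), **kw)


class TestFilterConfidence:
    def test_boundary_is_inclusive(self):
        """Features at exactly the threshold are kept; below it removed."""
        counts = pd.DataFrame([[1, 2, 3]], index=["s1"], columns=["a", "b", "c"])
        table = TaxaCountTable(
            counts=counts, confidence={"a": 0.49, "b": 0.50, "c": 0.51}
        )
        kept = filter_confidence(table, 0.5)
        assert kept.feature_ids == ["b", "c"]

    def test_all_confident_is_identity(self, toy_table):
        for f in toy_table.feature_ids:
            toy_table.confidence[f] = 1.0
        assert filter_confidence(toy_table).counts.equals(toy_table.counts)

    def test_all_removed_yields_empty(self, toy_table, caplog):
        for f in toy_table.feature_ids:
            toy_table.confidence[f] = 0.0
        with caplog.at_level("WARNING"):
            out = filter_confidence(toy_table)
        assert out.n_features == 0
        assert any("removed every feature" in r.message for r in caplog.records)


class TestAggregateSpecies:
    def test_counts_sum_within_genus_species_label(self, toy_table):
        out = aggregate_species(toy_table)
        # otu1 + otu2 share Pseudomonas stutzeri: 3+4, 2+0, 0+6
        assert out.counts["Pseudomonas_stutzeri"].tolist() == [7, 2, 6]
        assert out.rank == "species"

    def test_feature_without_species_assignment_dropped(self, toy_table):
        out = aggregate_species(toy_table)
        assert all("Janthinobacterium" not in f for f in out.feature_ids)

    def test_species_rank_table_identity_up_to_relabel(self):
        rng = np.random.default_rng(1)
        table = random_table(rng, n_samples=4, n_features=6)
        out = aggregate_species(table)
        assert out.n_features == 6
        np.testing.assert_array_equal(
            out.counts.to_numpy(), table.counts.to_numpy()
        )


class TestLog2Cpm:
    def test_zero_count_value(self):
        """count 0 with library size 999,999 gives exactly -1."""
        counts = pd.DataFrame(
            [[0, 999_999]], index=["s1"], columns=["a", "b"]
        )
        out = log2cpm(TaxaCountTable(counts=counts, rank="species"))
        assert out.values.loc["s1", "a"] == pytest.approx(-1.0)

    def test_direct_arithmetic(self):
        counts = pd.DataFrame(
            [[10, 999_989]], index=["s1"], columns=["a", "b"]
        )
        out = log2cpm(TaxaCountTable(counts=counts, rank="species"))
        assert out.values.loc["s1", "a"] == pytest.approx(np.log2(10.5), abs=1e-9)

    def test_monotone_in_count(self):
        counts = pd.DataFrame(
            [[5, 95], [10, 90]], index=["s1", "s2"], columns=["a", "b"]
        )
        out = log2cpm(TaxaCountTable(counts=counts, rank="species"))
        assert out.values.loc["s2", "a"] > out.values.loc["s1", "a"]

    def test_finite_everywhere(self, small_design):
        from citysig.synthetic import simulate_counts
        table, _ = simulate_counts(small_design, seed=2)
        out = log2cpm(aggregate_species(table))
        assert np.isfinite(out.values.to_numpy()).all()

    def test_zero_library_size_names_sample(self):
        counts = pd.DataFrame([[0, 0], [1, 2]], index=["bad", "ok"], columns=["a", "b"])
        with pytest.raises(ValidationError, match="bad"):
            log2cpm(TaxaCountTable(counts=counts))


class TestSelectCityCommon:
    def _labels(self, mapping):
        return pd.Series(mapping)

    def test_rule_satisfied_in_both_cities(self):
        counts = pd.DataFrame(
            {"sp": [0, 2, 3, 0]}, index=["a1", "a2", "b1", "b2"]
        )
        labels = self._labels({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        table = TaxaCountTable(counts=counts)
        assert select_city_common(table, labels) == ["sp"]

    def test_all_zero_city_drops_species(self):
        counts = pd.DataFrame(
            {"sp": [0, 0, 30, 40]}, index=["a1", "a2", "b1", "b2"]
        )
        labels = self._labels({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert select_city_common(TaxaCountTable(counts=counts), labels) == []

    def test_brute_force_on_random_tables(self):
        """Selection agrees with a per-species brute-force check of the rule."""
        rng = np.random.default_rng(33)
        for _ in range(10):
            table = random_table(rng, n_samples=9, n_features=15, max_count=4)
            labels = pd.Series(
                [f"C{i % 3}" for i in range(9)], index=table.sample_ids
            )
            expected = [
                f for f in table.feature_ids
                if all(
                    max(table.counts.loc[labels.index[labels == c], f]) >= 2
                    for c in ("C0", "C1", "C2")
                )
            ]
            assert select_city_common(table, labels) == expected

    def test_monotone_under_zeroing_a_city(self):
        rng = np.random.default_rng(7)
        table = random_table(rng, n_samples=6, n_features=10, max_count=5)
        labels = pd.Series(["A", "A", "A", "B", "B", "B"], index=table.sample_ids)
        before = set(select_city_common(table, labels))
        zeroed = table.counts.copy()
        zeroed.loc[["A" == labels[s] for s in table.sample_ids]] = 0
        after = set(
            select_city_common(TaxaCountTable(counts=zeroed), labels)
        )
        assert after <= before


class TestZeroCityFamily:
    def test_nesting_and_brute_force_membership(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            table = random_table(rng, n_samples=12, n_features=20, max_count=3)
            labels = pd.Series(
                [f"C{i % 4}" for i in range(12)], index=table.sample_ids
            )
            family = zero_city_family(table, labels)
            assert family.kmax == 3
            sets = [set(d) for d in family.datasets]
            for k in range(1, 4):
                assert sets[k - 1] <= sets[k]
            # brute force: zero-city count and the >=2 rule per non-zero city
            for f in table.feature_ids:
                col = table.counts[f]
                zero_cities = sum(
                    (col[labels == c] == 0).all() for c in ("C0", "C1", "C2", "C3")
                )
                ok = all(
                    (col[labels == c] == 0).all() or col[labels == c].max() >= 2
                    for c in ("C0", "C1", "C2", "C3")
                )
                for k in range(4):
                    assert (f in sets[k]) == (zero_cities <= k and ok)

    def test_d0_equals_selection(self):
        rng = np.random.default_rng(19)
        table = random_table(rng, n_samples=8, n_features=15, max_count=4)
        labels = pd.Series([f"C{i % 2}" for i in range(8)], index=table.sample_ids)
        family = zero_city_family(table, labels)
        assert family.datasets[0] == select_city_common(table, labels)

    def test_species_zero_in_one_city_first_appears_in_d1(self):
        counts = pd.DataFrame(
            {"sp": [0, 0, 5, 7]}, index=["a1", "a2", "b1", "b2"]
        )
        labels = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        family = zero_city_family(TaxaCountTable(counts=counts), labels)
        assert "sp" not in family.datasets[0]
        assert "sp" in family.datasets[1]

    def test_kmax_bound(self):
        counts = pd.DataFrame({"sp": [1, 1]}, index=["a1", "b1"])
        labels = pd.Series({"a1": "A", "b1": "B"})
        with pytest.raises(ValidationError):
            zero_city_family(TaxaCountTable(counts=counts), labels, kmax=2)

    def test_sizes_non_decreasing(self, small_design):
        from citysig.synthetic import simulate_counts
        from citysig.tables import city_labels
        table, meta = simulate_counts(small_design, seed=6)
        main = meta[meta["set"] == "training_main"]
        table = table.subset_samples(main["sample_id"])
        family = zero_city_family(table, city_labels(main, table.sample_ids))
        sizes = family.sizes()
        assert sizes == sorted(sizes)
        assert len(sizes) == 8


class TestMissingness:
    def test_all_zero_table(self):
        counts = pd.DataFrame(np.zeros((4, 3), dtype=int),
                              index=list("abcd"), columns=["x", "y", "z"])
        labels = pd.Series({"a": "A", "b": "A", "c": "B", "d": "B"})
        prof = missingness_profile(TaxaCountTable(counts=counts), labels)
        assert (prof.per_variable_zero_fraction == 1.0).all()
        assert prof.per_city_median == {"A": 1.0, "B": 1.0}

    def test_no_zero_table(self):
        counts = pd.DataFrame(np.ones((4, 3), dtype=int) * 5,
                              index=list("abcd"), columns=["x", "y", "z"])
        labels = pd.Series({"a": "A", "b": "A", "c": "B", "d": "B"})
        prof = missingness_profile(TaxaCountTable(counts=counts), labels)
        assert (prof.per_variable_zero_fraction == 0.0).all()
        assert prof.per_city_low_missing_count == {"A": 3, "B": 3}

    def test_high_inflation_city_has_higher_median(self, small_design):
        from citysig.synthetic import simulate_counts
        from citysig.tables import city_labels
        table, meta = simulate_counts(small_design, seed=8)
        main = meta[meta["set"] == "training_main"]
        table = table.subset_samples(main["sample_id"])
        prof = missingness_profile(table, city_labels(main, table.sample_ids))
        assert prof.per_city_median["HAM"] > prof.per_city_median["PXO"]


class TestPca:
    def test_rank_one_matrix(self):
        v = np.outer([1.0, 2.0, 3.0], [1.0, -1.0, 0.5])
        out = pca_summary(make_matrix(v))
        assert out["variance_fractions"][0] == pytest.approx(1.0)

    def test_duplicated_samples_have_identical_scores(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(4, 5))
        v[3] = v[0]
        out = pca_summary(make_matrix(v))
        np.testing.assert_allclose(
            out["scores"].iloc[0].to_numpy(), out["scores"].iloc[3].to_numpy(),
            atol=1e-10,
        )

    def test_variance_fractions_match_eigendecomposition(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=(20, 10))
        out = pca_summary(make_matrix(v))
        cov = np.cov(v - v.mean(axis=0), rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(
            out["all_variance_fractions"], eig / eig.sum(), atol=1e-10
        )
        assert out["all_variance_fractions"].sum() == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        v = np.ones((5, 4))
        with pytest.raises(ValidationError):
            pca_summary(make_matrix(v))


def test_per_sample_stages_commute_with_subsetting(toy_table):
    """filter -> aggregate -> log2cpm on a sample subset equals subsetting
    the full result (all three stages are per-sample computations)."""
    full = log2cpm(aggregate_species(filter_confidence(toy_table)))
    sub = log2cpm(
        aggregate_species(filter_confidence(toy_table.subset_samples(["s1", "s3"])))
    )
    np.testing.assert_allclose(
        full.values.loc[["s1", "s3"]].to_numpy(), sub.values.to_numpy()
    )


def test_zero_city_count_series(toy_table):
    labels = pd.Series({"s1": "A", "s2": "A", "s3": "B"})
    zcc = zero_city_count(toy_table, labels)
    # otu3: s1=0,s2=5 (A not all-zero), s3=2 -> 0 zero cities
    assert zcc["otu3"] == 0
    # otu4: s1=7,s2=0 -> A ok; s3=9 -> 0
    assert zcc["otu4"] == 0
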