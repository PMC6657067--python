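import numpy as np
import pandas as pd
import pytest

from citysig import (
    TaxaCountTable,
    make_default_design,
    simulate_challenge,
)
from citysig.preprocess import LogCpmMatrix


@pytest.fixture(scope="session")
def small_design():
    # compact design: 3 signature species per city keeps runtimes low
    return make_default_design(
        seed=20, n_species=150, n_signature_species_per_city=3,
        n_structural_zeros_per_city=8,
    )


@pytest.fixture(scope="session")
def small_bundle(small_design):
    return simulate_challenge(small_design, seed=21)


@pytest.fixture()
def toy_table():
    """3 samples x 4 OTUs with taxonomy down to species for two of them."""
    counts = pd.DataFrame(
        [[3, 4, 0, 7], [2, 0, 5, 0], [0, 6, 2, 9]],
        index=["s1", "s2", "s3"],
        columns=["otu1", "otu2", "otu3", "otu4"],
    )
    taxonomy = {
        "otu1": ("Bacteria", "P1", "C1", "O1", "F1", "Pseudomonas", "stutzeri"),
        "otu2": ("Bacteria", "P1", "C1", "O1", "F1", "Pseudomonas", "stutzeri"),
        "otu3": ("Bacteria", "P2", "C2", "O2", "F2", "Acinetobacter", "schindleri"),
        "otu4": ("Bacteria", "P2", "C2", "O2", "F2", "Janthinobacterium", ""),
    }
    confidence = {"otu1": 0.9, "otu2": 0.8, "otu3": 0.7, "otu4": 0.95}
    return TaxaCountTable(
        counts=counts, taxonomy=taxonomy, confidence=confidence, rank="otu"
    )


def random_table(rng, n_samples=8, n_features=12, max_count=30):
    counts = pd.DataFrame(
        rng.integers(0, max_count, size=(n_samples, n_features)),
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"f{j}" for j in range(n_features)],
    )
    taxonomy = {
        f"f{j}": ("Bacteria", "P", "C", "O", "F", f"Genus{j}", f"species{j}")
        for j in range(n_features)
    }
    confidence = {f"f{j}": float(rng.random()) for j in range(n_features)}
    return TaxaCountTable(
        counts=counts, taxonomy=taxonomy, confidence=confidence, rank="otu"
    )


def make_matrix(values: np.ndarray, prefix="s") -> LogCpmMatrix:
    n, m = values.shape
    idx = [f"{prefix}{i}" for i in range(n)]
    return LogCpmMatrix(
        values=pd.DataFrame(values, index=idx, columns=[f"v{j}" for j in range(m)]),
        library_sizes=pd.Series(10_000, index=idx),
    )
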