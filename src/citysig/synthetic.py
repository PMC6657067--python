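"""Synthetic challenge-shaped microbiome count tables.

The real challenge tables (FASTQ-derived OTU counts from urban-transit swabs)
are not redistributable at desk scale, so every downstream stage is exercised
on generated data that emulates their design: 8 training cities with unequal
sample sizes, a 30-sample multi-city test set, a secondary 3 x 12 training
set, and a 16-sample test set of which 5 samples come from a city absent from
training.  Each city carries a signature of elevated species, counts are
negative-binomial with log-normal library sizes, and zeros arise both
structurally (species absent from a city) and through per-city zero
inflation (emulating the extreme missingness observed for the New Zealand
cities in the real data).

Counts of exactly 1 are promoted to 2: in the upstream OTU-picking output
two is the minimum possible non-zero count, and the downstream
at-least-two-in-each-city selection rule assumes that property.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .tables import TaxaCountTable, ValidationError

__all__ = [
    "CityProfile",
    "SyntheticDesign",
    "ChallengeBundle",
    "MAIN_CITY_SIZES",
    "MYSTERY1_COMPOSITION",
    "MYSTERY2_CITIES",
    "MYSTERY3_COMPOSITION",
    "make_default_design",
    "simulate_counts",
    "simulate_challenge",
]

#: Main training design: 8 cities and their sample sizes (total 211).
MAIN_CITY_SIZES = {
    "AKL": 15,
    "HAM": 16,
    "NYC": 26,
    "OFA": 20,
    "PXO": 60,
    "SAC": 34,
    "SCL": 20,
    "TOK": 20,
}

#: Multi-city first test set: 30 samples.
MYSTERY1_COMPOSITION = {"NYC": 10, "OFA": 5, "PXO": 10, "SCL": 5}

#: Secondary training set: 3 cities x 12 samples.
MYSTERY2_CITIES = ("Ilorin", "Lisbon", "Boston")

#: Second test set: 16 samples, 5 of them from a city absent from training.
MYSTERY3_COMPOSITION = {"Boston": 3, "Ilorin": 4, "Lisbon": 4, "Bogota": 5}


@dataclass
class CityProfile:
    """Compositional profile of one city.

    ``log_mean_abundance`` is the natural-log relative abundance of each
    species; masked (structurally absent) species are excluded from the
    composition, which is renormalized over the remainder.
    """

    city: str
    n_samples: int
    log_mean_abundance: np.ndarray
    structural_zero_mask: np.ndarray
    zero_inflation: np.ndarray

    def __post_init__(self) -> None:
        self.log_mean_abundance = np.asarray(self.log_mean_abundance, dtype=float)
        self.structural_zero_mask = np.asarray(self.structural_zero_mask, dtype=bool)
        self.zero_inflation = np.asarray(self.zero_inflation, dtype=float)
        if self.n_samples <= 0:
            raise ValidationError("n_samples must be positive")
        if np.any((self.zero_inflation < 0) | (self.zero_inflation > 1)):
            raise ValidationError("zero_inflation must lie in [0, 1]")

    def relative_abundance(self) -> np.ndarray:
        """Composition over species: masked species 0, remainder sums to 1."""
        rel = np.exp(self.log_mean_abundance)
        rel[self.structural_zero_mask] = 0.0
        total = rel.sum()
        if total <= 0:
            raise ValidationError(f"city {self.city}: empty composition")
        return rel / total


@dataclass
class SyntheticDesign:
    city_profiles: list[CityProfile]
    n_species: int
    species_ids: list[str]
    species_taxonomy: dict[str, tuple[str, ...]]
    library_size_log_mean: float = float(np.log(5e4))
    library_size_log_sd: float = 0.4
    dispersion: float = 2.0  # NB size parameter: var = mu + mu^2 / dispersion
    n_signature_species_per_city: int = 10
    effect_size: float = 8.0
    confident_fraction: float = 0.9  # fraction of features with confidence >= 0.5
    unseen_city: CityProfile | None = None

    def __post_init__(self) -> None:
        profiles = list(self.city_profiles)
        if self.unseen_city is not None:
            profiles = profiles + [self.unseen_city]
        for prof in profiles:
            if prof.log_mean_abundance.shape != (self.n_species,):
                raise ValidationError(
                    f"profile {prof.city}: dimension mismatch with n_species"
                )
        if self.n_signature_species_per_city * len(self.city_profiles) > self.n_species:
            raise ValidationError("not enough species for disjoint city signatures")

    @property
    def cities(self) -> list[str]:
        return [p.city for p in self.city_profiles]

    def to_yaml(self, path) -> None:
        doc = {
            "n_species": self.n_species,
            "species_ids": list(self.species_ids),
            "library_size_log_mean": float(self.library_size_log_mean),
            "library_size_log_sd": float(self.library_size_log_sd),
            "dispersion": float(self.dispersion),
            "n_signature_species_per_city": int(self.n_signature_species_per_city),
            "effect_size": float(self.effect_size),
            "confident_fraction": float(self.confident_fraction),
            "cities": [
                {
                    "city": p.city,
                    "n_samples": int(p.n_samples),
                    "log_mean_abundance": [float(x) for x in p.log_mean_abundance],
                    "structural_zero_mask": [bool(x) for x in p.structural_zero_mask],
                    "zero_inflation": [float(x) for x in p.zero_inflation],
                }
                for p in self.city_profiles
            ]
            + (
                [
                    {
                        "city": self.unseen_city.city,
                        "n_samples": int(self.unseen_city.n_samples),
                        "log_mean_abundance": [
                            float(x) for x in self.unseen_city.log_mean_abundance
                        ],
                        "structural_zero_mask": [
                            bool(x) for x in self.unseen_city.structural_zero_mask
                        ],
                        "zero_inflation": [
                            float(x) for x in self.unseen_city.zero_inflation
                        ],
                        "unseen": True,
                    }
                ]
                if self.unseen_city is not None
                else []
            ),
        }
        with open(path, "w") as handle:
            yaml.safe_dump(doc, handle)


@dataclass
class ChallengeBundle:
    """The four generated sets, each a (TaxaCountTable, metadata) pair."""

    main_train: TaxaCountTable
    mystery1_test: TaxaCountTable
    mystery2_train: TaxaCountTable
    mystery3_test: TaxaCountTable
    metadata: pd.DataFrame


def _species_names(n_species: int) -> tuple[list[str], dict[str, tuple[str, ...]]]:
    # "GenusX speciesY" pairs so genus+species concatenation is exercised.
    ids = []
    taxonomy = {}
    for i in range(n_species):
        genus = f"Genus{i // 3}"
        species = f"species{i}"
        fid = f"sp{i:04d}"
        ids.append(fid)
        taxonomy[fid] = (
            "Bacteria",
            f"Phylum{i % 7}",
            f"Class{i % 11}",
            f"Order{i % 17}",
            f"Family{i % 29}",
            genus,
            species,
        )
    return ids, taxonomy


def _make_profile(
    city: str,
    n_samples: int,
    rng: np.random.Generator,
    base_log_abundance: np.ndarray,
    signature_idx: np.ndarray,
    effect_size: float,
    zero_inflation_level: float,
    n_structural_zeros: int,
) -> CityProfile:
    n_species = base_log_abundance.size
    log_mean = base_log_abundance + rng.normal(0.0, 0.25, size=n_species)
    log_mean[signature_idx] += np.log(effect_size)
    mask = np.zeros(n_species, dtype=bool)
    if n_structural_zeros > 0:
        candidates = np.setdiff1d(np.arange(n_species), signature_idx)
        mask[rng.choice(candidates, size=n_structural_zeros, replace=False)] = True
    zi = np.full(n_species, zero_inflation_level)
    zi[signature_idx] = min(zero_inflation_level, 0.05)  # signatures stay visible
    return CityProfile(
        city=city,
        n_samples=n_samples,
        log_mean_abundance=log_mean,
        structural_zero_mask=mask,
        zero_inflation=zi,
    )


def make_default_design(
    seed: int,
    n_species: int = 300,
    n_signature_species_per_city: int = 10,
    effect_size: float = 8.0,
    n_structural_zeros_per_city: int = 15,
) -> SyntheticDesign:
    """Default design mirroring the challenge shape.

    8 training cities with sample sizes {15, 16, 26, 20, 60, 34, 20, 20}
    (sum 211), plus the 3-city secondary profiles (12 samples each) and an
    unseen city used only in the second test set.  Each city receives
    ``n_signature_species_per_city`` disjoint signature species whose mean
    relative abundance is elevated ``effect_size``-fold.  Two cities (AKL,
    HAM) are generated with high zero inflation to emulate the heavily
    zero-inflated New Zealand samples of the real data.
    """
    rng = np.random.default_rng(seed)
    species_ids, taxonomy = _species_names(n_species)
    base = rng.normal(0.0, 1.0, size=n_species)

    all_cities = list(MAIN_CITY_SIZES) + list(MYSTERY2_CITIES) + ["Bogota"]
    n_sig_total = n_signature_species_per_city * len(all_cities)
    if n_sig_total > n_species:
        raise ValidationError("n_species too small for disjoint signatures")
    sig_pool = rng.permutation(n_species)[:n_sig_total]
    sig_by_city = {
        city: sig_pool[
            i * n_signature_species_per_city : (i + 1) * n_signature_species_per_city
        ]
        for i, city in enumerate(all_cities)
    }
    high_zero_cities = {"AKL", "HAM"}

    profiles = [
        _make_profile(
            city,
            n_samples,
            rng,
            base,
            sig_by_city[city],
            effect_size,
            zero_inflation_level=0.6 if city in high_zero_cities else 0.2,
            n_structural_zeros=n_structural_zeros_per_city,
        )
        for city, n_samples in MAIN_CITY_SIZES.items()
    ]
    secondary = [
        _make_profile(
            city, 12, rng, base, sig_by_city[city], effect_size,
            zero_inflation_level=0.2, n_structural_zeros=n_structural_zeros_per_city,
        )
        for city in MYSTERY2_CITIES
    ]
    unseen = _make_profile(
        "Bogota", 5, rng, base, sig_by_city["Bogota"], effect_size,
        zero_inflation_level=0.2, n_structural_zeros=n_structural_zeros_per_city,
    )
    return SyntheticDesign(
        city_profiles=profiles + secondary,
        n_species=n_species,
        species_ids=species_ids,
        species_taxonomy=taxonomy,
        n_signature_species_per_city=n_signature_species_per_city,
        effect_size=effect_size,
        unseen_city=unseen,
    )


def _simulate_city_block(
    profile: CityProfile,
    design: SyntheticDesign,
    rng: np.random.Generator,
    n_samples: int | None = None,
) -> np.ndarray:
    n = profile.n_samples if n_samples is None else n_samples
    rel = profile.relative_abundance()
    libs = rng.lognormal(
        design.library_size_log_mean, design.library_size_log_sd, size=n
    )
    mu = libs[:, None] * rel[None, :]
    size = design.dispersion
    # NB via gamma-Poisson mixture; mu == 0 stays exactly 0
    counts = np.zeros((n, design.n_species), dtype=np.int64)
    positive = mu > 0
    lam = np.zeros_like(mu)
    lam[positive] = rng.gamma(size, mu[positive] / size)
    counts[positive] = rng.poisson(lam[positive])
    dropout = rng.random((n, design.n_species)) < profile.zero_inflation[None, :]
    counts[dropout] = 0
    counts[:, profile.structural_zero_mask] = 0
    counts[counts == 1] = 2  # minimum observable non-zero count is 2
    return counts


def _confidences(
    design: SyntheticDesign, rng: np.random.Generator
) -> dict[str, float]:
    high = rng.random(design.n_species) < design.confident_fraction
    conf = np.where(
        high,
        0.5 + 0.5 * rng.random(design.n_species),
        0.5 * rng.random(design.n_species),
    )
    return {fid: float(c) for fid, c in zip(design.species_ids, conf)}


def simulate_counts(
    design: SyntheticDesign, seed: int
) -> tuple[TaxaCountTable, pd.DataFrame]:
    """Simulate the main training table (all design profiles, training sets).

    Deterministic: the same (design, seed) yields a bit-identical table.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    rows = []
    for profile in design.city_profiles:
        block = _simulate_city_block(profile, design, rng)
        blocks.append(block)
        set_name = (
            "training_mystery2" if profile.city in MYSTERY2_CITIES else "training_main"
        )
        for k in range(profile.n_samples):
            rows.append(
                {
                    "sample_id": f"{profile.city}.{k:03d}",
                    "city": profile.city,
                    "set": set_name,
                    "true_city": profile.city,
                }
            )
    counts = pd.DataFrame(
        np.vstack(blocks),
        index=[r["sample_id"] for r in rows],
        columns=design.species_ids,
    )
    counts.index.name = "sample_id"
    table = TaxaCountTable(
        counts=counts,
        taxonomy=dict(design.species_taxonomy),
        confidence=_confidences(design, rng),
        rank="otu",
    )
    return table, pd.DataFrame(rows)


def simulate_challenge(
    design: SyntheticDesign,
    seed: int,
    mystery1_composition: dict[str, int] | None = None,
    mystery3_composition: dict[str, int] | None = None,
) -> ChallengeBundle:
    """Generate the four-set challenge bundle.

    The first test set draws from the 8 training-city profiles; the second
    test set contains samples from the secondary training cities plus
    samples from the design's unseen city, whose label never occurs in any
    training set.  ``true_city`` is recorded in the metadata for evaluation;
    the ``city`` column is null for test samples.
    """
    if design.unseen_city is None:
        raise ValidationError("design has no unseen_city; cannot build mystery-3")
    mystery1_composition = dict(mystery1_composition or MYSTERY1_COMPOSITION)
    mystery3_composition = dict(mystery3_composition or MYSTERY3_COMPOSITION)

    rng = np.random.default_rng(seed)
    profile_by_city = {p.city: p for p in design.city_profiles}
    profile_by_city[design.unseen_city.city] = design.unseen_city

    main_cities = [c for c in design.cities if c in MAIN_CITY_SIZES]
    secondary_cities = [c for c in design.cities if c not in MAIN_CITY_SIZES]

    def build(cities_and_sizes, set_name, hide_city, prefix=None):
        blocks, rows = [], []
        idx = 0
        for city, n in cities_and_sizes:
            profile = profile_by_city[city]
            blocks.append(_simulate_city_block(profile, design, rng, n_samples=n))
            for _ in range(n):
                sid = (
                    f"{prefix}.{idx:03d}" if prefix else f"{city}.{idx:03d}"
                )
                rows.append(
                    {
                        "sample_id": sid,
                        "city": None if hide_city else city,
                        "set": set_name,
                        "true_city": city,
                    }
                )
                idx += 1
        counts = pd.DataFrame(
            np.vstack(blocks),
            index=[r["sample_id"] for r in rows],
            columns=design.species_ids,
        )
        counts.index.name = "sample_id"
        table = TaxaCountTable(
            counts=counts,
            taxonomy=dict(design.species_taxonomy),
            confidence=confidences,
            rank="otu",
        )
        return table, rows

    confidences = _confidences(design, rng)

    main_train, rows_main = build(
        [(c, profile_by_city[c].n_samples) for c in main_cities],
        "training_main",
        hide_city=False,
    )
    mystery1, rows_m1 = build(
        sorted(mystery1_composition.items()), "mystery1", hide_city=True, prefix="C1"
    )
    mystery2, rows_m2 = build(
        [(c, profile_by_city[c].n_samples) for c in secondary_cities],
        "training_mystery2",
        hide_city=False,
    )
    mystery3, rows_m3 = build(
        sorted(mystery3_composition.items()), "mystery3", hide_city=True, prefix="C5"
    )

    unseen_label = design.unseen_city.city
    train_labels = {r["city"] for r in rows_m2}
    if unseen_label in train_labels:
        raise ValidationError("unseen city appears in the secondary training set")

    metadata = pd.DataFrame(rows_main + rows_m1 + rows_m2 + rows_m3)
    return ChallengeBundle(
        main_train=main_train,
        mystery1_test=mystery1,
        mystery2_train=mystery2,
        mystery3_test=mystery3,
        metadata=metadata,
    )
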