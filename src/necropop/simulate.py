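"""Synthetic necropolis generator.

Emulates the statistical structure the analyses assume so that every pipeline
stage can be exercised end-to-end: a roster of ~38 individuals with four
cremations; 87Sr/86Sr enamel ratios drawn from a three-component mixture
(local / non-local / low-ratio outlier) with two teeth of different
mineralization rank per individual and five local-signal bone baselines;
binary dental-trait scores with group-specific presence probabilities; and a
grave-good incidence matrix whose inclusion probabilities are sex- and
age-structured but (in the default scenario) origin-neutral — the structure
the mortuary statistics are expected to recover.

Latent truth (origin component, injected mobility type, goods probability
tables) is returned alongside each dataset for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .records import (
    AgeClass,
    BinaryArtifactMatrix,
    IndividualRecord,
    IsotopeSample,
    Ritual,
    Sex,
    TraitDefinition,
    parse_tooth,
)

__all__ = [
    "SyntheticConfig",
    "Roster",
    "generate_individuals",
    "generate_isotopes",
    "generate_trait_scores",
    "generate_artifacts",
    "generate_dataset",
    "default_trait_probabilities",
]

# Age-class composition of the default roster mirrors the excavated one:
# 3 infants, 8 children, 2 adolescents, 8 young adults, 6 middle adults,
# 7 old adults among the 34 inhumations.
_AGE_WEIGHTS = {
    AgeClass.INFANT: 3,
    AgeClass.CHILD: 8,
    AgeClass.ADOLESCENT: 2,
    AgeClass.YOUNG_ADULT: 8,
    AgeClass.MIDDLE_ADULT: 6,
    AgeClass.OLD_ADULT: 7,
}


def default_trait_probabilities() -> dict:
    """Per-origin dental-trait presence probabilities.

    Locals take the MVL column of the packaged frequency table, non-locals
    (and the outlier) the MVNL column.
    """
    from .io import packaged_data, read_frequency_table

    groups, panel = read_frequency_table(packaged_data("table4_frequencies.csv"))
    by_name = {g.group: g for g in groups}
    out = {}
    for origin, source in (("local", "MVL"), ("nonlocal", "MVNL"), ("outlier", "MVNL")):
        freqs = by_name[source]
        out[origin] = {
            t: freqs.counts[t][0] / freqs.counts[t][1]
            for t in panel
            if freqs.counts[t][1] > 0
        }
    return out


@dataclass
class SyntheticConfig:
    """Study conditions for the generator (defaults emulate the source site)."""

    n_individuals: int = 38
    n_cremations: int = 4
    male_fraction: float = 0.5
    # origin mixture: local / nonlocal / outlier
    origin_weights: tuple = (0.52, 0.44, 0.04)
    # isotope mixture components, 87Sr/86Sr
    local_mean: float = 0.70880
    local_sigma: float = 0.00006
    nonlocal_mean: float = 0.70930
    nonlocal_sigma: float = 0.00015
    outlier_mean: float = 0.70853
    outlier_sigma: float = 0.00003
    measurement_two_se: float = 0.000006
    n_bone_baseline: int = 5
    # intra-individual mobility injection
    arrived_fraction: float = 0.4  # of non-local adults: early non-local, late local
    outbound_fraction: float = 0.17  # of local adults: early local, late non-local
    # dental traits
    trait_probabilities: Optional[dict] = None  # origin -> {trait: p}
    trait_missing_rate: float = 0.15
    # grave goods
    n_weapon_goods: int = 15
    n_ornament_goods: int = 15
    n_neutral_goods: int = 35
    baseline_good_p: float = 0.30
    linked_high_p: float = 0.60
    linked_low_p: float = 0.04
    sex_linkage: float = 1.0  # 0 = no sex structure, 1 = full contrast
    origin_linkage: float = 0.0  # scenario B raises this
    n_origin_goods: int = 10  # goods made origin-linked under scenario B
    child_good_factor: float = 0.5  # goods rate multiplier for infants/children
    scenario: str = "A"  # "A" sex-structured, "B" origin-linked, "null" unstructured

    def __post_init__(self):
        if abs(sum(self.origin_weights) - 1.0) > 1e-9:
            raise ValueError("origin mixture weights must sum to 1")
        if self.scenario not in ("A", "B", "null"):
            raise ValueError("scenario must be 'A', 'B' or 'null'")
        if self.scenario == "B" and self.origin_linkage == 0.0:
            self.origin_linkage = 1.0
        if self.scenario == "null":
            self.sex_linkage = 0.0
            self.origin_linkage = 0.0

    @property
    def n_goods(self) -> int:
        return self.n_weapon_goods + self.n_ornament_goods + self.n_neutral_goods


@dataclass
class Roster:
    individuals: list  # of IndividualRecord
    origin: dict  # id -> "local" | "nonlocal" | "outlier"

    @property
    def ids(self) -> list:
        return [ind.id for ind in self.individuals]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_individuals(config: SyntheticConfig, seed) -> Roster:
    """Reproducible roster with latent origin truth.

    Cremations carry unknown sex and age; everyone, cremated or not, has a
    latent origin drawn from the configured mixture.
    """
    rng = _rng(seed)
    n = config.n_individuals
    n_crem = config.n_cremations
    ages = list(_AGE_WEIGHTS)
    age_p = np.array(list(_AGE_WEIGHTS.values()), dtype=float)
    age_p /= age_p.sum()
    individuals = []
    for i in range(n):
        ident = f"SN {i + 1}"
        if i < n - n_crem:
            sex = Sex.MALE if rng.random() < config.male_fraction else Sex.FEMALE
            age = ages[rng.choice(len(ages), p=age_p)]
            individuals.append(IndividualRecord(ident, sex, age, Ritual.INHUMATION))
        else:
            individuals.append(
                IndividualRecord(ident, Sex.UNKNOWN, AgeClass.UNKNOWN, Ritual.CREMATION)
            )
    origins = rng.choice(
        ["local", "nonlocal", "outlier"], size=n, p=np.array(config.origin_weights)
    )
    return Roster(individuals, {ind.id: o for ind, o in zip(individuals, origins)})


def _component(config: SyntheticConfig, origin: str):
    return {
        "local": (config.local_mean, config.local_sigma),
        "nonlocal": (config.nonlocal_mean, config.nonlocal_sigma),
        "outlier": (config.outlier_mean, config.outlier_sigma),
    }[origin]


def generate_isotopes(
    roster: Roster, config: SyntheticConfig, seed
) -> tuple[list[IsotopeSample], dict]:
    """Two-teeth-per-individual isotope design with injected mobility.

    Adults get an M1 (early) and an M3 (late) sample, children a dm2 and an
    M1.  Stable individuals draw both teeth from their origin component; a
    configurable fraction of non-local adults are "arrived in childhood"
    (early non-local, late local) and of local adults "outbound return"
    (early local, late non-local).  Five bone samples come from the local
    component regardless of origin, since bone remodels in vivo.  Cremations
    yield no enamel.

    Returns the samples and a truth table id -> mobility type.
    """
    rng = _rng(seed)
    samples: list[IsotopeSample] = []
    truth: dict[str, str] = {}

    def draw(origin: str) -> float:
        mean, sigma = _component(config, origin)
        value = rng.normal(mean, sigma)
        return float(value + rng.normal(0.0, config.measurement_two_se / 2.0))

    inhumed = [i for i in roster.individuals if i.ritual is Ritual.INHUMATION]
    for ind in inhumed:
        origin = roster.origin[ind.id]
        child = ind.age_class in (AgeClass.INFANT, AgeClass.CHILD)
        early_code, late_code = ("Ldm2-lower", "LM1-lower") if child else (
            "LM1-lower",
            "LM3-lower",
        )
        early_origin = late_origin = origin
        mobility = {
            "local": "stable_local",
            "nonlocal": "stable_nonlocal",
            "outlier": "distinct_origin",
        }[origin]
        if not child:
            if origin == "nonlocal" and rng.random() < config.arrived_fraction:
                late_origin, mobility = "local", "arrived_in_childhood"
            elif origin == "local" and rng.random() < config.outbound_fraction:
                late_origin, mobility = "nonlocal", "outbound_return"
        truth[ind.id] = mobility
        for code, comp in ((early_code, early_origin), (late_code, late_origin)):
            samples.append(
                IsotopeSample(
                    individual_id=ind.id,
                    material="enamel",
                    tooth=parse_tooth(code),
                    ratio=draw(comp),
                    two_se=config.measurement_two_se,
                )
            )
    adults = [i for i in inhumed if i.age_class.is_adult]
    for ind in adults[: config.n_bone_baseline]:
        samples.append(
            IsotopeSample(
                individual_id=ind.id,
                material="bone",
                tooth=None,
                ratio=draw("local"),
                two_se=config.measurement_two_se,
            )
        )
    return samples, truth


def generate_trait_scores(
    roster: Roster, config: SyntheticConfig, seed
) -> tuple[pd.DataFrame, list[TraitDefinition]]:
    """Bernoulli dental-trait presences on a minimal two-grade scale.

    Presence probability depends on the individual's latent origin; a
    configurable missingness rate knocks out individual-trait observations
    (unscorable teeth).  Grade 1 = present, grade 0 = absent.
    """
    rng = _rng(seed)
    probs = (
        config.trait_probabilities
        if config.trait_probabilities is not None
        else default_trait_probabilities()
    )
    traits = list(next(iter(probs.values())))
    rows = {}
    for ind in roster.individuals:
        p = probs[roster.origin[ind.id]]
        grades = (rng.random(len(traits)) < np.array([p[t] for t in traits])).astype(
            float
        )
        lost = rng.random(len(traits)) < config.trait_missing_rate
        grades[lost] = np.nan
        rows[ind.id] = grades
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=traits)
    defs = [
        TraitDefinition(
            name=t, tooth_class="synthetic", breakpoint=frozenset({1.0}),
            scale=frozenset({0.0, 1.0}),
        )
        for t in traits
    ]
    return scores, defs


def _goods_probability_table(config: SyntheticConfig) -> pd.DataFrame:
    """Per-good inclusion probabilities by (sex, origin-side) cell."""
    base, hi, lo = config.baseline_good_p, config.linked_high_p, config.linked_low_p
    s = config.sex_linkage
    o = config.origin_linkage
    goods = (
        [f"weapon_{i + 1}" for i in range(config.n_weapon_goods)]
        + [f"ornament_{i + 1}" for i in range(config.n_ornament_goods)]
        + [f"vessel_{i + 1}" for i in range(config.n_neutral_goods)]
    )
    tab = pd.DataFrame(
        base, index=goods, columns=["male", "female", "local", "nonlocal"]
    )
    hi_s = base + s * (hi - base)
    lo_s = base + s * (lo - base)
    tab.loc[tab.index.str.startswith("weapon"), ["male", "female"]] = [hi_s, lo_s]
    tab.loc[tab.index.str.startswith("ornament"), ["male", "female"]] = [lo_s, hi_s]
    origin_goods = [g for g in goods if g.startswith("vessel")][: config.n_origin_goods]
    hi_o = base + o * (hi - base)
    lo_o = base + o * (lo - base)
    tab.loc[origin_goods, ["local", "nonlocal"]] = [hi_o, lo_o]
    return tab


def generate_artifacts(
    roster: Roster, config: SyntheticConfig, seed
) -> tuple[BinaryArtifactMatrix, pd.DataFrame]:
    """Binary grave-good matrix with sex/age(/origin) structured inclusion.

    Scenario A (default): weapon-type goods favour males, ornament-type goods
    favour females, everything is origin-neutral.  Scenario B additionally
    links a subset of goods to origin for power analysis; "null" removes all
    structure.  Cremations keep their goods but have unknown sex and missing
    origin code.  Returns the matrix and the probability table used (truth).
    """
    rng = _rng(seed)
    tab = _goods_probability_table(config)
    goods = list(tab.index)
    presence = {}
    meta = {}
    for ind in roster.individuals:
        origin = roster.origin[ind.id]
        origin_side = "local" if origin == "local" else "nonlocal"
        if ind.sex is Sex.MALE:
            p_sex = tab["male"]
        elif ind.sex in (Sex.FEMALE, Sex.PROBABLE_FEMALE):
            p_sex = tab["female"]
        else:  # unknown sex: average profile
            p_sex = (tab["male"] + tab["female"]) / 2.0
        # combine sex and origin effects as deviations from the baseline
        p = p_sex + (tab[origin_side] - config.baseline_good_p)
        if ind.age_class in (AgeClass.INFANT, AgeClass.CHILD):
            p = p * config.child_good_factor
        p = p.clip(0.0, 1.0)
        presence[ind.id] = (rng.random(len(goods)) < p.to_numpy()).astype(int)
        meta[ind.id] = {
            "sex": ind.sex.value,
            "age_class": ind.age_class.value,
            "ritual": ind.ritual.value,
            "origin_code": 1
            if ind.ritual is Ritual.CREMATION
            else (0 if origin == "local" else 2),
        }
    matrix = BinaryArtifactMatrix(
        pd.DataFrame.from_dict(presence, orient="index", columns=goods),
        pd.DataFrame.from_dict(meta, orient="index"),
    )
    return matrix, tab


@dataclass
class SyntheticDataset:
    roster: Roster
    isotopes: list
    mobility_truth: dict
    trait_scores: pd.DataFrame
    trait_definitions: list
    artifacts: BinaryArtifactMatrix
    goods_probabilities: pd.DataFrame


def generate_dataset(config: SyntheticConfig, seed) -> SyntheticDataset:
    """Generate all three data strands from one seed."""
    ss = np.random.SeedSequence(seed)
    s_ind, s_iso, s_tr, s_art = ss.spawn(4)
    roster = generate_individuals(config, s_ind)
    isotopes, mobility = generate_isotopes(roster, config, s_iso)
    scores, defs = generate_trait_scores(roster, config, s_tr)
    artifacts, tab = generate_artifacts(roster, config, s_art)
    return SyntheticDataset(roster, isotopes, mobility, scores, defs, artifacts, tab)
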