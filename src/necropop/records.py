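"""Domain records shared across the pipeline stages.

The vocabulary mirrors standard bioarchaeological usage: individuals are
skeletons identified by grave labels (``"MV 21"``), isotope samples are single
enamel/bone measurements of the strontium isotope ratio (87Sr/86Sr), dental
traits are ASUDAS-graded crown/root variants, and the mortuary record is a
binary individual-by-grave-good incidence matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "AgeClass",
    "Ritual",
    "IndividualRecord",
    "ToothCode",
    "parse_tooth",
    "MINERALIZATION_RANK",
    "mineralization_rank",
    "IsotopeSample",
    "TraitDefinition",
    "GroupTraitFrequencies",
    "BinaryArtifactMatrix",
    "AnalysisConfig",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    PROBABLE_FEMALE = "probable_female"
    UNKNOWN = "unknown"


class AgeClass(str, Enum):
    INFANT = "infant"
    CHILD = "child"
    ADOLESCENT = "adolescent"
    YOUNG_ADULT = "young_adult"
    MIDDLE_ADULT = "middle_adult"
    OLD_ADULT = "old_adult"
    UNKNOWN = "unknown"

    @property
    def is_adult(self) -> bool:
        return self in (
            AgeClass.ADOLESCENT,
            AgeClass.YOUNG_ADULT,
            AgeClass.MIDDLE_ADULT,
            AgeClass.OLD_ADULT,
        )


class Ritual(str, Enum):
    INHUMATION = "inhumation"
    CREMATION = "cremation"


@dataclass(frozen=True)
class IndividualRecord:
    """One buried individual with its osteological metadata."""

    id: str
    sex: Sex = Sex.UNKNOWN
    age_class: AgeClass = AgeClass.UNKNOWN
    ritual: Ritual = Ritual.INHUMATION


# Crown mineralization chronology.  Deciduous crowns form in utero, the first
# permanent molar around birth, third molars last; this ordering is what makes
# the "earliest tooth = childhood residence, latest tooth = later childhood"
# sampling design work.  Ranks are shared across arches and sides.
MINERALIZATION_RANK = {
    "dm1": 0,
    "dm2": 1,
    "M1": 2,
    "I1": 3,
    "I2": 4,
    "C1": 5,
    "P3": 6,
    "P4": 7,
    "M2": 8,
    "M3": 9,
}

_TOOTH_RE = re.compile(
    r"^(?P<side>[LR])(?P<cls>dm|[ICPM])(?P<pos>\d)(?:-(?P<arch>upper|lower))?$"
)


@dataclass(frozen=True)
class ToothCode:
    """Parsed tooth designation: side, dental arch, class and position."""

    side: str  # "L" | "R"
    tooth_class: str  # "I", "C", "P", "M", "dm"
    position: int
    arch: Optional[str] = None  # "upper" | "lower" | None

    @property
    def key(self) -> str:
        """Class+position key used for the mineralization chronology."""
        return f"{self.tooth_class}{self.position}"

    def __str__(self) -> str:
        base = f"{self.side}{self.tooth_class}{self.position}"
        return f"{base}-{self.arch}" if self.arch else base


def parse_tooth(code: str) -> ToothCode:
    """Parse a compact tooth code such as ``"LM1-lower"`` or ``"Rdm2"``.

    The printed sources mark the arch typographically (superscript = upper,
    subscript = lower); files normalize that to an explicit ``-upper`` /
    ``-lower`` suffix.
    """
    m = _TOOTH_RE.match(code.strip())
    if m is None:
        raise ValueError(f"unparseable tooth code: {code!r}")
    cls = m.group("cls")
    pos = int(m.group("pos"))
    key = f"{cls}{pos}"
    if key not in MINERALIZATION_RANK:
        raise ValueError(f"unknown tooth {key!r} in code {code!r}")
    return ToothCode(m.group("side"), cls, pos, m.group("arch"))


def mineralization_rank(tooth: "ToothCode | str") -> int:
    if isinstance(tooth, str):
        tooth = parse_tooth(tooth)
    return MINERALIZATION_RANK[tooth.key]


@dataclass(frozen=True)
class IsotopeSample:
    """A single 87Sr/86Sr measurement on enamel or bone."""

    individual_id: str
    material: str  # "enamel" | "bone"
    tooth: Optional[ToothCode]
    ratio: float
    two_se: float

    def __post_init__(self):
        if self.material not in ("enamel", "bone"):
            raise ValueError(f"unknown material {self.material!r}")
        if not (0.70 < self.ratio < 0.72):
            raise ValueError(
                f"{self.individual_id}: ratio {self.ratio} outside plausible "
                "87Sr/86Sr bounds (0.70, 0.72)"
            )
        if self.two_se <= 0:
            raise ValueError(f"{self.individual_id}: non-positive 2SE")
        if self.material == "bone" and self.tooth is not None:
            raise ValueError(f"{self.individual_id}: bone sample carries a tooth code")
        if self.material == "enamel" and self.tooth is None:
            raise ValueError(f"{self.individual_id}: enamel sample lacks a tooth code")


@dataclass(frozen=True)
class TraitDefinition:
    """An ASUDAS trait with the grade set counted as 'present'."""

    name: str
    tooth_class: str
    breakpoint: frozenset
    scale: frozenset

    def __post_init__(self):
        if not self.breakpoint:
            raise ValueError(f"{self.name}: empty breakpoint")
        if not self.breakpoint <= self.scale:
            raise ValueError(f"{self.name}: breakpoint outside the grade scale")

    def is_present(self, grade) -> bool:
        if grade not in self.scale:
            raise ValueError(f"{self.name}: grade {grade!r} outside scale")
        return grade in self.breakpoint


@dataclass
class GroupTraitFrequencies:
    """Per-group trait incidence: k present out of n scored, per trait."""

    group: str
    counts: dict  # trait -> (k, n)

    def __post_init__(self):
        for trait, (k, n) in self.counts.items():
            if not (0 <= k <= n):
                raise ValueError(f"{self.group}/{trait}: k={k} outside [0, n={n}]")

    def percent(self, trait: str) -> float:
        k, n = self.counts[trait]
        return 100.0 * k / n

    @property
    def traits(self) -> list:
        return list(self.counts)


class BinaryArtifactMatrix:
    """Individual x grave-good presence/absence matrix with burial metadata.

    ``presence`` is a pandas DataFrame of {0,1} indexed by individual id;
    ``metadata`` carries sex, age_class, ritual and origin_code (0 local,
    1 missing, 2 non-local) aligned on the same index.
    """

    METADATA_COLS = ("sex", "age_class", "ritual", "origin_code")

    def __init__(self, presence: pd.DataFrame, metadata: pd.DataFrame):
        presence = presence.copy()
        vals = presence.to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary presence cell at individual "
                f"{presence.index[i]!r}, good {presence.columns[j]!r}: "
                f"{vals[i, j]!r}"
            )
        if presence.index.duplicated().any():
            dup = presence.index[presence.index.duplicated()][0]
            raise ValueError(f"duplicate individual id {dup!r}")
        missing = [c for c in self.METADATA_COLS if c not in metadata.columns]
        if missing:
            raise ValueError(f"metadata lacks columns: {missing}")
        if not metadata.index.equals(presence.index):
            metadata = metadata.loc[presence.index]
        bad_origin = set(metadata["origin_code"]) - {0, 1, 2}
        if bad_origin:
            raise ValueError(f"invalid origin codes: {sorted(bad_origin)}")
        self.presence = presence.astype(int)
        self.metadata = metadata.copy()

    @property
    def individuals(self) -> list:
        return list(self.presence.index)

    @property
    def goods(self) -> list:
        return list(self.presence.columns)

    @property
    def shape(self):
        return self.presence.shape

    def __eq__(self, other):
        return (
            isinstance(other, BinaryArtifactMatrix)
            and self.presence.equals(other.presence)
            and self.metadata[list(self.METADATA_COLS)].equals(
                other.metadata[list(self.METADATA_COLS)]
            )
        )


@dataclass
class AnalysisConfig:
    """Thresholds and seeds for a full pipeline run.

    All tunables live here so that every output can log the exact settings
    it was produced under.
    """

    local_range_bounds: Optional[tuple] = None  # explicit (lower, upper) override
    faunal_range: tuple = (0.7088, 0.7090)  # published pig-enamel baseline
    baseline_round_decimals: int = 4  # baselines are reported at 4 decimals
    mobility_delta: float = 0.0001  # local baseline 2-sigma
    correlation_r_threshold: float = 0.5
    min_trait_observations: int = 5
    vif_threshold: float = 5.0
    n_permutations: int = 9999
    rf_n_trees: int = 500
    rf_max_features: str = "sqrt"
    rf_importance_cutoff: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.mobility_delta <= 0 or self.vif_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.correlation_r_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.local_range_bounds is not None:
            lo, hi = self.local_range_bounds
            if not lo < hi:
                raise ValueError("local range bounds must be ordered")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["faunal_range"] = list(self.faunal_range)
        if self.local_range_bounds is not None:
            d["local_range_bounds"] = list(self.local_range_bounds)
        return d
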