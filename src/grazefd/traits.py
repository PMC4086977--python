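"""Species trait tables for grassland response-trait analysis.

Builds a coded species x trait matrix from long-format, database-style trait
entries.  Categorical attributes (life-form, canopy structure, leafing period,
life-span, vegetative spread) are mapped onto numeric codes in [0, 1];
flowering start is recorded as a month (1-12); canopy height and leaf size are
natural-log transformed; LDMC (leaf dry matter content, mg g-1) and SLA
(specific leaf area, mm2 mg-1) stay in their measurement units.  Where a
species has several database entries for one trait, the species value is the
replication-weighted mean of the entries.  Species values are fixed once the
table is built: year-to-year change in community-level trait values downstream
comes from abundance change only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "RawTraitEntry",
    "TraitScheme",
    "TraitTable",
    "TraitCodingError",
    "MissingTraitError",
    "DEFAULT_SCHEMES",
    "code_trait",
    "species_trait_mean",
    "build_trait_table",
]


class TraitCodingError(ValueError):
    """Raised when a raw value cannot be coded under its trait scheme."""


class MissingTraitError(ValueError):
    """Raised when required (species, trait) cells are absent; lists all gaps."""

    def __init__(self, gaps: list[tuple[str, str]]):
        self.gaps = gaps
        listing = "; ".join(f"{s}:{t}" for s, t in gaps)
        super().__init__(f"missing trait entries for {len(gaps)} (species, trait) cells: {listing}")


@dataclass(frozen=True)
class RawTraitEntry:
    """One database-style trait record.

    ``replication`` is the number of underlying measurements behind the entry
    and acts as the weight when entries are averaged per species.
    """

    species_id: str
    trait_name: str
    value: float | str
    replication: int = 1

    def __post_init__(self):
        if self.replication < 1:
            raise ValueError(f"replication must be >= 1, got {self.replication}")


@dataclass(frozen=True)
class TraitScheme:
    """Coding rule for one trait.

    kind is 'continuous', 'ordinal-coded' or 'binary-coded'.  ``coding_map``
    maps attribute labels to numeric codes for the coded kinds.  ``weight``
    enters the multi-trait Gower distance; the two vegetative-spread
    attributes each carry weight 0.5 so that vegetative spread as a whole
    weighs the same as any other trait.  ``scale`` records the admissible
    numeric range of the coded value.
    """

    trait_name: str
    kind: str = "continuous"
    coding_map: dict[str, float] = field(default_factory=dict)
    log_transform: bool = False
    weight: float = 1.0
    scale: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "ordinal-coded", "binary-coded"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.weight <= 0:
            raise ValueError("trait weight must be > 0")
        if self.coding_map and self.scale is not None:
            lo, hi = self.scale
            for label, v in self.coding_map.items():
                if not lo <= v <= hi:
                    raise ValueError(
                        f"coded value {v} for {label!r} outside declared range [{lo}, {hi}]"
                    )


def _default_schemes() -> dict[str, TraitScheme]:
    """The standard grassland response-trait coding used throughout.

    Life-form codes rank bud height (geophyte/therophyte 0 through
    phanerophyte 1); canopy structure ranks rosette 0 / hemirosette 0.5 /
    erosulate 1; leafing period, life-span and the two vegetative-spread
    attributes are 0/0.5/1 or 0/1 codes; flowering start is the month (1-12).
    """
    schemes = [
        TraitScheme(
            "life_form",
            "ordinal-coded",
            {"Geophyte": 0.0, "Therophyte": 0.0, "Hemicryptophyte": 0.333,
             "Chamaephyte": 0.667, "Phanerophyte": 1.0},
            scale=(0.0, 1.0),
        ),
        TraitScheme("canopy_height_m", "continuous", log_transform=True),
        TraitScheme(
            "canopy_structure",
            "ordinal-coded",
            {"Rosette": 0.0, "Hemirosette": 0.5, "Erosulate": 1.0},
            scale=(0.0, 1.0),
        ),
        TraitScheme("flowering_start_month", "ordinal-coded", scale=(1.0, 12.0)),
        TraitScheme("ldmc_mg_per_g", "continuous"),
        TraitScheme("leaf_size_mm2", "continuous", log_transform=True),
        TraitScheme(
            "leafing_period",
            "binary-coded",
            {"Evergreen": 0.0, "Summer green": 1.0},
            scale=(0.0, 1.0),
        ),
        TraitScheme(
            "life_span",
            "ordinal-coded",
            {"Annual": 0.0, "Biennial": 0.5, "Perennial": 1.0},
            scale=(0.0, 1.0),
        ),
        TraitScheme("sla_mm2_per_mg", "continuous"),
        TraitScheme(
            "veg_spread_rhizome",
            "binary-coded",
            {"Not rhizomatous": 0.0, "Rhizomatous": 1.0},
            weight=0.5,
            scale=(0.0, 1.0),
        ),
        TraitScheme(
            "veg_spread_stolon",
            "binary-coded",
            {"Not stoloniferous": 0.0, "Stoloniferous": 1.0},
            weight=0.5,
            scale=(0.0, 1.0),
        ),
    ]
    return {s.trait_name: s for s in schemes}


DEFAULT_SCHEMES: dict[str, TraitScheme] = _default_schemes()


def code_trait(entry: RawTraitEntry, scheme: TraitScheme) -> float:
    """Code one raw entry to a number under its trait scheme.

    Coded kinds look the label up in ``coding_map`` (numeric values are
    accepted as-is when they lie inside the declared scale, e.g. flowering
    month given directly as 5).  Continuous traits are parsed as numbers; the
    natural log is applied when the scheme says so.
    """
    if scheme.coding_map and isinstance(entry.value, str):
        if entry.value not in scheme.coding_map:
            raise TraitCodingError(
                f"trait {scheme.trait_name!r}: unknown attribute label {entry.value!r}"
            )
        return float(scheme.coding_map[entry.value])
    try:
        x = float(entry.value)
    except (TypeError, ValueError) as exc:
        raise TraitCodingError(
            f"trait {scheme.trait_name!r}: cannot parse value {entry.value!r}"
        ) from exc
    if scheme.scale is not None:
        lo, hi = scheme.scale
        if not lo <= x <= hi:
            raise TraitCodingError(
                f"trait {scheme.trait_name!r}: value {x} outside range [{lo}, {hi}]"
            )
    if scheme.log_transform:
        if x <= 0:
            raise TraitCodingError(
                f"trait {scheme.trait_name!r}: non-positive value {x} under log transform"
            )
        return math.log(x)
    return x


def species_trait_mean(entries: list[RawTraitEntry]) -> float:
    """Replication-weighted mean of already-coded values for one species+trait.

    Sum(value * replication) / Sum(replication).  All entries must refer to
    the same species and trait.
    """
    if not entries:
        raise ValueError("species_trait_mean requires at least one entry")
    keys = {(e.species_id, e.trait_name) for e in entries}
    if len(keys) > 1:
        raise ValueError(f"entries mix several (species, trait) pairs: {sorted(keys)}")
    num = sum(float(e.value) * e.replication for e in entries)
    den = sum(e.replication for e in entries)
    return num / den


@dataclass
class TraitTable:
    """Coded species x trait matrix with its coding schemes.

    ``data`` rows are species, columns traits; log-transformed traits are
    stored post-transform (recorded in the scheme).  ``provenance`` counts the
    raw entries behind each cell.
    """

    data: pd.DataFrame
    schemes: dict[str, TraitScheme]
    provenance: pd.DataFrame | None = None

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)

    def weights(self, subset: list[str] | None = None) -> dict[str, float]:
        names = subset if subset is not None else self.trait_names
        return {t: self.schemes[t].weight for t in names}

    def values_for(self, trait: str) -> pd.Series:
        if trait not in self.data.columns:
            raise KeyError(f"trait {trait!r} not in table")
        return self.data[trait]

    def __post_init__(self):
        if self.data.isna().any().any():
            bad = [
                (str(sp), str(tr))
                for sp in self.data.index
                for tr in self.data.columns
                if pd.isna(self.data.at[sp, tr])
            ]
            raise MissingTraitError(bad)


def build_trait_table(
    raw: list[RawTraitEntry],
    schemes: dict[str, TraitScheme] | list[TraitScheme] | None = None,
) -> TraitTable:
    """Code, average and assemble raw entries into a complete TraitTable.

    Every (species, trait) pair over the cross product of observed species and
    scheme traits must have at least one entry; any gap raises
    :class:`MissingTraitError` listing all offenders.  Coding (label mapping,
    log transform) is applied per entry before replication-weighted averaging,
    so e.g. height entries are averaged on the log scale.
    """
    if schemes is None:
        schemes = DEFAULT_SCHEMES
    if isinstance(schemes, list):
        schemes = {s.trait_name: s for s in schemes}
    for e in raw:
        if e.trait_name not in schemes:
            raise TraitCodingError(f"no scheme declared for trait {e.trait_name!r}")

    coded: dict[tuple[str, str], list[RawTraitEntry]] = {}
    for e in raw:
        v = code_trait(e, schemes[e.trait_name])
        coded.setdefault((e.species_id, e.trait_name), []).append(
            RawTraitEntry(e.species_id, e.trait_name, v, e.replication)
        )

    species = sorted({e.species_id for e in raw})
    trait_names = list(schemes)
    gaps = [(s, t) for s in species for t in trait_names if (s, t) not in coded]
    if gaps:
        raise MissingTraitError(gaps)

    data = pd.DataFrame(index=species, columns=trait_names, dtype=float)
    prov = pd.DataFrame(0, index=species, columns=trait_names, dtype=int)
    for (s, t), entries in coded.items():
        data.at[s, t] = species_trait_mean(entries)
        prov.at[s, t] = len(entries)
    return TraitTable(data=data, schemes=schemes, provenance=prov)
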