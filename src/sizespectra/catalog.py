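"""Group-level body-size / biomass catalog.

Each biological group carries a habitat realm, a trophic role, three
reference body sizes (minimum, median, maximum, in grams of carbon),
a global biomass total (Gt C), and a multiplicative "fold" uncertainty
describing the 95% confidence interval of that total under a lognormal
error model.

The packaged base catalog covers the 36 free-living groups
(16 terrestrial, 18 marine, 2 subterranean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

REALMS = ("terrestrial", "marine", "subterranean")
ROLES = ("producer", "consumer")

REQUIRED_COLUMNS = (
    "name",
    "realm",
    "role",
    "size_min",
    "size_median",
    "size_max",
    "biomass",
    "fold_uncertainty",
)

# Default composition conversions: 30% dry mass per wet mass,
# 50% carbon per dry mass.
DRY_PER_WET = 0.3
CARBON_PER_DRY = 0.5


class CatalogSchemaError(ValueError):
    """The catalog file does not have the expected columns/shape."""


class CatalogValidationError(ValueError):
    """A row violates a group-record invariant."""


@dataclass(frozen=True)
class GroupRecord:
    """One biological group's sizes and biomass.

    Sizes are in grams of carbon; biomass in gigatonnes of carbon.
    ``fold_uncertainty`` (lambda) is the factor by which the 95% bounds
    of the biomass deviate multiplicatively from the best estimate.
    """

    name: str
    realm: str
    role: str
    size_min: float
    size_median: float
    size_max: float
    biomass: float
    fold_uncertainty: float

    def __post_init__(self) -> None:
        if self.realm not in REALMS:
            raise CatalogValidationError(
                f"{self.name}: realm {self.realm!r} not one of {REALMS}"
            )
        if self.role not in ROLES:
            raise CatalogValidationError(
                f"{self.name}: role {self.role!r} not one of {ROLES}"
            )
        if not (0.0 < self.size_min <= self.size_median <= self.size_max):
            raise CatalogValidationError(
                f"{self.name}: sizes must satisfy 0 < min <= median <= max, "
                f"got ({self.size_min}, {self.size_median}, {self.size_max})"
            )
        if not self.biomass > 0:
            raise CatalogValidationError(f"{self.name}: biomass must be > 0")
        if not self.fold_uncertainty >= 1:
            raise CatalogValidationError(
                f"{self.name}: fold uncertainty must be >= 1"
            )

    @property
    def log_min(self) -> float:
        return math.log10(self.size_min)

    @property
    def log_median(self) -> float:
        return math.log10(self.size_median)

    @property
    def log_max(self) -> float:
        return math.log10(self.size_max)

    @property
    def decades(self) -> float:
        """Number of log10 units the group spans (max:min size ratio)."""
        return self.log_max - self.log_min


@dataclass(frozen=True)
class Catalog:
    """An ordered, uniquely named collection of group records."""

    records: tuple[GroupRecord, ...]
    variant_label: str = "base"

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise CatalogValidationError(f"duplicate group names: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def filter_realms(self, realms: Iterable[str]) -> "Catalog":
        realms = tuple(realms)
        for r in realms:
            if r not in REALMS:
                raise ValueError(f"unknown realm {r!r}")
        return Catalog(
            records=tuple(g for g in self.records if g.realm in realms),
            variant_label=self.variant_label,
        )

    @property
    def total_biomass(self) -> float:
        return float(sum(g.biomass for g in self.records))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [g.name for g in self.records],
                "realm": [g.realm for g in self.records],
                "role": [g.role for g in self.records],
                "size_min": [g.size_min for g in self.records],
                "size_median": [g.size_median for g in self.records],
                "size_max": [g.size_max for g in self.records],
                "biomass": [g.biomass for g in self.records],
                "fold_uncertainty": [g.fold_uncertainty for g in self.records],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_catalog(path: str | Path, variant_label: str = "base") -> Catalog:
    """Load and validate a catalog CSV.

    Raises :class:`CatalogSchemaError` for missing columns or an empty
    file, and :class:`CatalogValidationError` (naming the group) for rows
    violating record invariants.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CatalogSchemaError(f"{path}: empty catalog file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CatalogSchemaError(f"{path}: missing column(s) {missing}")
    records = []
    for _, row in frame.iterrows():
        records.append(
            GroupRecord(
                name=str(row["name"]),
                realm=str(row["realm"]),
                role=str(row["role"]),
                size_min=float(row["size_min"]),
                size_median=float(row["size_median"]),
                size_max=float(row["size_max"]),
                biomass=float(row["biomass"]),
                fold_uncertainty=float(row["fold_uncertainty"]),
            )
        )
    return Catalog(records=tuple(records), variant_label=variant_label)


def base_catalog_path() -> Path:
    """Path to the packaged 36-group base catalog."""
    return Path(resources.files("sizespectra").joinpath("data/base_catalog.csv"))


def load_base_catalog() -> Catalog:
    return load_catalog(base_catalog_path(), variant_label="base")


def convert_to_carbon(
    value: float,
    unit: str,
    shape: str = "none",
    conversion: Optional[float] = None,
) -> float:
    """Convert a reported body-size measurement to grams of carbon.

    ``unit`` is one of ``wet_g``, ``dry_g``, ``carbon_g``, or
    ``length_diameter``. For diameters, ``shape`` selects the biovolume
    rule — ``sphere`` ((4/3)*pi*r^3), ``tube`` (treated as a cylinder of
    length = diameter unless a taxon factor says otherwise is folded in),
    or ``cube`` (diameter cubed; the packing rule used for hard corals) —
    and ``conversion`` must supply the biovolume-to-carbon factor.
    For masses, ``conversion`` overrides the default composition factors
    (30% dry per wet, 50% C per dry).
    """
    if not value > 0:
        raise ValueError("measurement must be positive")
    if unit == "carbon_g":
        return float(value)
    if unit == "dry_g":
        factor = CARBON_PER_DRY if conversion is None else conversion
        return float(value * factor)
    if unit == "wet_g":
        factor = DRY_PER_WET * CARBON_PER_DRY if conversion is None else conversion
        return float(value * factor)
    if unit == "length_diameter":
        if shape == "none" or conversion is None:
            raise ValueError(
                "diameter measurements need a body shape (sphere/tube/cube) "
                "and a biovolume-to-carbon conversion factor"
            )
        volume = biovolume(value, shape)
        return float(volume * conversion)
    raise ValueError(f"unknown unit {unit!r}")


def biovolume(diameter: float, shape: str) -> float:
    """Body volume from a reported diameter, in cubic diameter units."""
    if not diameter > 0:
        raise ValueError("diameter must be positive")
    if shape == "sphere":
        return (4.0 / 3.0) * math.pi * (diameter / 2.0) ** 3
    if shape == "tube":
        # cylinder with length equal to the reported diameter
        return math.pi * (diameter / 2.0) ** 2 * diameter
    if shape == "cube":
        return diameter**3
    raise ValueError(f"unknown shape {shape!r}")


@dataclass(frozen=True)
class SizeRangeStats:
    """Per-group size spans and their trend against median size."""

    decades: pd.Series
    mean_decades: float
    sd_decades: float
    slope: float
    intercept: float
    p_value: float
    overall_span: float


def size_range_stats(catalog: Catalog) -> SizeRangeStats:
    """Size range (log10 max:min ratio) statistics across groups.

    Regresses each group's span in decades on its log10 median size
    (ordinary least squares, two-sided t-test on the slope). A near-zero
    slope means groups of all sizes span similar numbers of orders of
    magnitude, which justifies tallying biomass on log size bins without
    normalization.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    if len(catalog) < 3:
        raise ValueError("regression undefined for fewer than 3 groups")
    decades = pd.Series(
        {g.name: g.decades for g in catalog}, name="decades", dtype=float
    )
    log_median = np.array([g.log_median for g in catalog])
    res = stats.linregress(log_median, decades.to_numpy())
    overall = math.log10(
        max(g.size_max for g in catalog) / min(g.size_min for g in catalog)
    )
    return SizeRangeStats(
        decades=decades,
        mean_decades=float(decades.mean()),
        sd_decades=float(decades.std(ddof=1)),
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        overall_span=overall,
    )
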