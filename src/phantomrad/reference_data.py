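"""Curated reference fixtures for the five-tissue breast phantom.

Packaged CSVs hold, at printed precision, the published characterization
dataset of a heterogeneous breast phantom: component recipes, elemental
weight fractions of the tissue-mimicking materials (TMMs) and of the
matching ICRU reference breast tissues, mass densities, measured/literature
T1/T2 relaxation times at 0.5 T, and measured/literature CT numbers.

Tissues are keyed by canonical slug so records join across tables:
``skin, adipose, fibroglandular, pectoral_muscle, carcinoma``.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

from .chem_core import (
    ElementalComposition,
    Recipe,
    _data_file,
    lookup_compound,
)
from .errors import DataLoadError, InvalidInputError, UnknownTissueError

#: canonical tissue order used by every report
TISSUES = ("skin", "adipose", "fibroglandular", "pectoral_muscle", "carcinoma")

COMPOSITION_SOURCES = ("tmm", "icru")


@dataclass(frozen=True)
class DensityRecord:
    tissue: str
    mass_density: float  # g/cm^3

    def __post_init__(self):
        if self.mass_density <= 0:
            raise InvalidInputError(f"density of {self.tissue!r} must be positive")


@dataclass(frozen=True)
class RelaxationRecord:
    """T1/T2 of one tissue at one field strength; times in seconds."""

    tissue: str
    field_strength: float  # tesla
    t1: float | None
    t2: float | None
    source: str  # measured | literature | none

    def __post_init__(self):
        if self.source not in ("measured", "literature", "none"):
            raise InvalidInputError(f"unknown relaxation source {self.source!r}")
        if self.source != "none":
            if self.t1 is None or self.t2 is None or not self.t1 > self.t2 > 0:
                raise InvalidInputError(
                    f"relaxation record for {self.tissue!r} must satisfy t1 > t2 > 0"
                )


@dataclass(frozen=True)
class HURecord:
    """A measured or literature CT number (mean +/- SD) for one tissue."""

    tissue: str
    mean_hu: float
    sd_hu: float
    source: str  # measured | reference
    citation_tag: str = ""

    def __post_init__(self):
        if self.sd_hu < 0:
            raise InvalidInputError(f"HU record for {self.tissue!r} has negative SD")
        if self.source not in ("measured", "reference"):
            raise InvalidInputError(f"unknown HU source {self.source!r}")


def _read_rows(name: str) -> list[dict]:
    try:
        with _data_file(name).open(newline="") as fh:
            rows = list(csv.DictReader(fh))
    except OSError as exc:
        raise DataLoadError(f"cannot read packaged fixture {name}: {exc}") from exc
    if not rows:
        raise DataLoadError(f"packaged fixture {name} is empty")
    return rows


@lru_cache(maxsize=1)
def load_densities() -> Mapping[str, float]:
    """Mass density (g/cm^3) per tissue slug."""
    return {
        r["tissue"]: DensityRecord(r["tissue"], float(r["mass_density"])).mass_density
        for r in _read_rows("densities.csv")
    }


def load_compositions(source: str = "tmm") -> list[ElementalComposition]:
    """The five tissue compositions, fractions as printed, densities attached.

    ``source`` is ``"tmm"`` (the fabricated tissue-mimicking materials) or
    ``"icru"`` (the ICRU reference breast tissues).
    """
    if source not in COMPOSITION_SOURCES:
        raise InvalidInputError(
            f"composition source must be one of {COMPOSITION_SOURCES}, got {source!r}"
        )
    rows = _read_rows(f"{source}_compositions.csv")
    densities = load_densities()
    grouped: dict[str, dict[str, float]] = {}
    for row in rows:
        grouped.setdefault(row["material"], {})[row["element"]] = float(
            row["weight_fraction"]
        )
    missing = set(TISSUES) - set(grouped)
    if missing:
        raise DataLoadError(
            f"{source}_compositions.csv is missing tissues: {sorted(missing)}"
        )
    return [
        ElementalComposition(
            material_name=tissue,
            weight_fractions=grouped[tissue],
            mass_density=densities[tissue],
            provenance="from_table",
        )
        for tissue in TISSUES
    ]


def get_composition(tissue: str, source: str = "tmm") -> ElementalComposition:
    for comp in load_compositions(source):
        if comp.material_name == tissue:
            return comp
    raise UnknownTissueError(tissue)


def load_recipes() -> list[Recipe]:
    """The five gram-denominated component recipes, densities attached."""
    rows = _read_rows("recipes.csv")
    densities = load_densities()
    grouped: dict[str, list] = {}
    for row in rows:
        grouped.setdefault(row["material"], []).append(
            (lookup_compound(row["component"]), float(row["grams"]))
        )
    missing = set(TISSUES) - set(grouped)
    if missing:
        raise DataLoadError(f"recipes.csv is missing tissues: {sorted(missing)}")
    return [
        Recipe(tissue, tuple(grouped[tissue]), mass_density=densities.get(tissue))
        for tissue in TISSUES
    ]


def get_recipe(tissue: str) -> Recipe:
    for recipe in load_recipes():
        if recipe.material_name == tissue:
            return recipe
    raise UnknownTissueError(tissue)


def load_relaxation_records() -> list[RelaxationRecord]:
    """T1/T2 records at 0.5 T: five measured, two literature, three without
    a natural-tissue reference at this field strength."""
    records = []
    for row in _read_rows("relaxation.csv"):
        records.append(
            RelaxationRecord(
                tissue=row["tissue"],
                field_strength=float(row["field_T"]),
                t1=float(row["t1_s"]) if row["t1_s"] else None,
                t2=float(row["t2_s"]) if row["t2_s"] else None,
                source=row["source"],
            )
        )
    return records


def load_hu_records() -> list[HURecord]:
    """Measured and literature CT numbers per tissue.

    Literature rows carry anonymous citation tags (L1, L2, ...) that
    distinguish distinct sources; one literature entry that gives only a
    plausible HU range rather than a mean +/- SD is not representable here
    and is omitted.
    """
    return [
        HURecord(
            tissue=row["tissue"],
            mean_hu=float(row["mean_hu"]),
            sd_hu=float(row["sd_hu"]),
            source=row["source"],
            citation_tag=row.get("citation_tag", "") or "",
        )
        for row in _read_rows("hu.csv")
    ]


@dataclass(frozen=True)
class ReportedCharacterization:
    """One published phantom-or-reference row: n_e, Z_eff and error columns."""

    tissue: str
    role: str  # phantom | reference
    ne: float | None
    ne_error_pct: float | None
    zeff: float | None
    zeff_error_pct: float | None


def load_reported_characterization() -> list[ReportedCharacterization]:
    """The published per-tissue n_e / Z_eff table, at printed precision."""

    def opt(v):
        return float(v) if v not in ("", None) else None

    return [
        ReportedCharacterization(
            tissue=row["tissue"],
            role=row["role"],
            ne=opt(row["ne"]),
            ne_error_pct=opt(row["ne_error_pct"]),
            zeff=opt(row["zeff"]),
            zeff_error_pct=opt(row["zeff_error_pct"]),
        )
        for row in _read_rows("reported_characterization.csv")
    ]
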