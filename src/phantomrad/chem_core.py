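"""Chemical bookkeeping for tissue-mimicking materials.

Parses chemical formulas, computes molar masses and per-element mass
fractions, and converts a gram-denominated recipe of compounds into the
elemental weight fractions that all radiological metrics consume.

Atomic weights are the IUPAC standard values shipped in
``data/elements.csv``; the compound database in ``data/compounds.csv`` maps
the recipe component names (water, sugars, oils, surfactants, gelling
agents, salts) to fixed surrogate formulas, including average formulas with
fractional stoichiometry for polymeric/surfactant components.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence, Union

from .errors import (
    DataLoadError,
    FormulaParseError,
    InvalidInputError,
    UnknownCompoundError,
    UnknownElementError,
)

logger = logging.getLogger(__name__)

#: elements a composition may deviate from unity by before a warning is logged
NORMALIZATION_WARN_TOL = 0.01

ElementCountMap = dict  # element symbol -> (possibly fractional) atom count


@dataclass(frozen=True)
class ElementRecord:
    """One row of the packaged element table: Z and the standard atomic weight."""

    symbol: str
    atomic_number: int
    atomic_weight: float  # g/mol

    def __post_init__(self):
        if self.atomic_number < 1 or self.atomic_weight <= 0:
            raise InvalidInputError(
                f"invalid element record {self.symbol}: Z={self.atomic_number}, "
                f"A={self.atomic_weight}"
            )


def _data_file(name: str):
    path = resources.files("phantomrad.data").joinpath(name)
    if not path.is_file():
        raise DataLoadError(f"packaged data file {name!r} is missing")
    return path


@lru_cache(maxsize=1)
def element_table() -> Mapping[str, ElementRecord]:
    """The packaged element table, keyed by IUPAC symbol."""
    table = {}
    with _data_file("elements.csv").open() as fh:
        for row in csv.DictReader(fh):
            rec = ElementRecord(
                row["symbol"], int(row["atomic_number"]), float(row["atomic_weight"])
            )
            if rec.symbol in table:
                raise DataLoadError(f"duplicate element symbol {rec.symbol!r} in elements.csv")
            table[rec.symbol] = rec
    return table


def get_element(symbol: str, context: str = "") -> ElementRecord:
    try:
        return element_table()[symbol]
    except KeyError:
        raise UnknownElementError(symbol, context) from None


# ---------------------------------------------------------------------------
# formula parsing

def parse_formula(formula: str) -> ElementCountMap:
    """Parse a chemical formula into an element -> count map.

    Supports real-valued counts and nested parenthesized groups with
    multipliers, e.g. ``"C14H22O(C2H4O)9.5"`` -> ``{C: 33, H: 60, O: 10.5}``.
    Symbols are validated against the packaged element table.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaParseError("empty formula", formula or "", 0)
    counts, pos = _parse_group(formula, 0, top=True)
    if pos != len(formula):
        raise FormulaParseError("unexpected character", formula, pos)
    if not any(c > 0 for c in counts.values()):
        raise FormulaParseError("formula has no atoms", formula, 0)
    return counts


def _parse_group(s: str, pos: int, top: bool = False) -> tuple[ElementCountMap, int]:
    counts: ElementCountMap = {}
    n = len(s)
    while pos < n:
        ch = s[pos]
        if ch == "(":
            inner, pos = _parse_group(s, pos + 1)
            if pos >= n or s[pos] != ")":
                raise FormulaParseError("unbalanced parenthesis", s, pos)
            mult, pos = _parse_count(s, pos + 1)
            for sym, c in inner.items():
                counts[sym] = counts.get(sym, 0.0) + c * mult
        elif ch == ")":
            if top:
                raise FormulaParseError("unbalanced parenthesis", s, pos)
            return counts, pos
        elif ch.isalpha() and ch.isupper():
            sym, pos = _parse_symbol(s, pos)
            mult, pos = _parse_count(s, pos)
            counts[sym] = counts.get(sym, 0.0) + mult
        else:
            raise FormulaParseError("unexpected character", s, pos)
    return counts, pos


def _parse_symbol(s: str, pos: int) -> tuple[str, int]:
    table = element_table()
    if pos + 1 < len(s) and s[pos + 1].islower():
        two = s[pos : pos + 2]
        if two in table:
            return two, pos + 2
        raise UnknownElementError(two, f"in formula {s!r}")
    one = s[pos]
    if one in table:
        return one, pos + 1
    raise UnknownElementError(one, f"in formula {s!r}")


def _parse_count(s: str, pos: int) -> tuple[float, int]:
    start = pos
    n = len(s)
    while pos < n and s[pos].isdigit():
        pos += 1
    if pos < n and s[pos] == ".":
        pos += 1
        if pos >= n or not s[pos].isdigit():
            raise FormulaParseError("malformed count", s, pos)
        while pos < n and s[pos].isdigit():
            pos += 1
    if pos == start:
        return 1.0, pos
    return float(s[start:pos]), pos


def unparse_formula(counts: Mapping[str, float]) -> str:
    """Canonical formula string in Hill order (C, H, then alphabetical)."""
    if not counts:
        raise InvalidInputError("cannot unparse an empty element-count map")
    symbols = sorted(counts)
    if "C" in counts:
        head = ["C"] + (["H"] if "H" in counts else [])
        symbols = head + [s for s in symbols if s not in head]
    parts = []
    for sym in symbols:
        c = counts[sym]
        if c == 0:
            continue
        if c == 1:
            parts.append(sym)
        elif float(c).is_integer():
            parts.append(f"{sym}{int(c)}")
        else:
            parts.append(f"{sym}{c:g}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# molar masses and mass fractions

def molar_mass(counts: Mapping[str, float]) -> float:
    """Molar mass in g/mol: sum of count times standard atomic weight."""
    if not counts:
        raise InvalidInputError("molar_mass of an empty element-count map")
    return sum(c * get_element(sym).atomic_weight for sym, c in counts.items())


@dataclass(frozen=True)
class CompoundSpec:
    """A named compound with a fixed (possibly average) formula."""

    name: str
    formula: str
    element_counts: ElementCountMap
    molar_mass: float  # g/mol
    notes: str = ""

    def __post_init__(self):
        expected = molar_mass(self.element_counts)
        if abs(self.molar_mass - expected) > 1e-9 * expected:
            raise InvalidInputError(
                f"molar mass of {self.name!r} ({self.molar_mass}) does not match "
                f"its element counts ({expected})"
            )

    @classmethod
    def from_formula(cls, name: str, formula: str, notes: str = "") -> "CompoundSpec":
        counts = parse_formula(formula)
        return cls(name, formula, counts, molar_mass(counts), notes)


def element_mass_fractions(
    compound: Union[CompoundSpec, Mapping[str, float]]
) -> dict[str, float]:
    """Mass fraction of each element in a compound: count * A / molar mass."""
    counts = compound.element_counts if isinstance(compound, CompoundSpec) else compound
    mm = molar_mass(counts)
    return {
        sym: c * get_element(sym).atomic_weight / mm
        for sym, c in counts.items()
        if c > 0
    }


# ---------------------------------------------------------------------------
# compound database

def _normalize_name(name: str) -> str:
    return " ".join(name.split()).lower()


@lru_cache(maxsize=1)
def compound_database() -> Mapping[str, CompoundSpec]:
    """The packaged compound database keyed by (case-insensitive) name."""
    db = {}
    with _data_file("compounds.csv").open() as fh:
        for row in csv.DictReader(fh):
            spec = CompoundSpec.from_formula(
                row["name"], row["formula"], row.get("notes", "") or ""
            )
            db[_normalize_name(spec.name)] = spec
    return db


def lookup_compound(
    name: str, db: Mapping[str, CompoundSpec] | None = None
) -> CompoundSpec:
    db = compound_database() if db is None else db
    key = _normalize_name(name)
    if key in db:
        return db[key]
    # tolerate lookup against a db keyed by display name
    for spec in db.values():
        if _normalize_name(spec.name) == key:
            return spec
    raise UnknownCompoundError(name)


# ---------------------------------------------------------------------------
# recipes and compositions

@dataclass(frozen=True)
class Recipe:
    """A named list of (compound, mass in grams) with an optional density."""

    material_name: str
    components: tuple  # of (CompoundSpec | str, grams)
    mass_density: float | None = None  # g/cm^3

    def __post_init__(self):
        for _, mass in self.components:
            if mass < 0:
                raise InvalidInputError(
                    f"recipe {self.material_name!r} has a negative component mass"
                )
        if self.mass_density is not None and self.mass_density <= 0:
            raise InvalidInputError(
                f"recipe {self.material_name!r} has non-positive density"
            )

    @property
    def total_mass(self) -> float:
        return sum(mass for _, mass in self.components)


@dataclass(frozen=True)
class ElementalComposition:
    """Element -> weight fraction (mass basis) plus mass density.

    ``weight_fractions`` are stored as given (reference tables are kept at
    printed precision); metric code normalizes by the stored total, and
    :meth:`normalized` returns an explicitly rescaled copy.
    """

    material_name: str
    weight_fractions: Mapping[str, float]
    mass_density: float | None = None  # g/cm^3
    provenance: str = "synthetic"  # from_recipe | from_table | synthetic

    def __post_init__(self):
        if not self.weight_fractions:
            raise InvalidInputError(
                f"composition {self.material_name!r} has no elements"
            )
        for sym, w in self.weight_fractions.items():
            if not (0.0 <= w <= 1.0 + 1e-9):
                raise InvalidInputError(
                    f"composition {self.material_name!r}: weight fraction of "
                    f"{sym} is {w}, outside [0, 1]"
                )
        if not any(w > 0 for w in self.weight_fractions.values()):
            raise InvalidInputError(
                f"composition {self.material_name!r} has all-zero fractions"
            )
        if self.mass_density is not None and self.mass_density <= 0:
            raise InvalidInputError(
                f"composition {self.material_name!r} has non-positive density"
            )
        if self.provenance not in ("from_recipe", "from_table", "synthetic"):
            raise InvalidInputError(f"unknown provenance {self.provenance!r}")

    @property
    def total(self) -> float:
        return sum(self.weight_fractions.values())

    def elements(self) -> list[str]:
        return [s for s, w in self.weight_fractions.items() if w > 0]

    def normalized(self) -> "ElementalComposition":
        t = self.total
        return replace(
            self,
            weight_fractions={s: w / t for s, w in self.weight_fractions.items()},
        )

    def with_density(self, density: float) -> "ElementalComposition":
        return replace(self, mass_density=density)


def composition_from_recipe(
    recipe: Recipe, db: Mapping[str, CompoundSpec] | None = None
) -> ElementalComposition:
    """Elemental weight fractions of a recipe.

    Each component's mass is split over its elements via
    :func:`element_mass_fractions`; elemental masses are pooled over
    components and divided by the total recipe mass.
    """
    total = recipe.total_mass
    if total <= 0:
        raise InvalidInputError(
            f"recipe {recipe.material_name!r} has zero total mass"
        )
    elemental_mass: dict[str, float] = {}
    for compound, mass in recipe.components:
        spec = compound if isinstance(compound, CompoundSpec) else lookup_compound(compound, db)
        for sym, frac in element_mass_fractions(spec).items():
            elemental_mass[sym] = elemental_mass.get(sym, 0.0) + mass * frac
    return ElementalComposition(
        material_name=recipe.material_name,
        weight_fractions={s: m / total for s, m in elemental_mass.items()},
        mass_density=recipe.mass_density,
        provenance="from_recipe",
    )


def normalize_composition(
    raw: Mapping[str, float],
    material_name: str = "material",
    mass_density: float | None = None,
    provenance: str = "synthetic",
) -> ElementalComposition:
    """Scale raw per-element weights to fractions summing to one.

    Logs a warning (but proceeds) when the input total deviates from unity
    by more than 1%, which catches transcription problems in near-normalized
    reference rows without rejecting rows carrying rounding residue.
    """
    if not raw:
        raise InvalidInputError("normalize_composition of an empty map")
    for sym in raw:
        get_element(sym, f"in composition {material_name!r}")
    total = sum(raw.values())
    if total <= 0:
        raise InvalidInputError(
            f"composition {material_name!r} has no positive weights"
        )
    if abs(total - 1.0) > NORMALIZATION_WARN_TOL:
        logger.warning(
            "composition %r weights sum to %.6g; normalizing", material_name, total
        )
    return ElementalComposition(
        material_name=material_name,
        weight_fractions={s: w / total for s, w in raw.items()},
        mass_density=mass_density,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# CSV dialects (recipe and composition files)

def read_recipe_csv(
    path, db: Mapping[str, CompoundSpec] | None = None,
    densities: Mapping[str, float] | None = None,
) -> list[Recipe]:
    """Read recipes from a CSV with columns ``material,component,grams``."""
    try:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    except OSError as exc:
        raise DataLoadError(f"cannot read recipe file {path}: {exc}") from exc
    if not rows or not {"material", "component", "grams"} <= set(rows[0]):
        raise DataLoadError(
            f"recipe file {path} must have columns material,component,grams"
        )
    grouped: dict[str, list] = {}
    for row in rows:
        grouped.setdefault(row["material"], []).append(
            (lookup_compound(row["component"], db), float(row["grams"]))
        )
    densities = densities or {}
    return [
        Recipe(name, tuple(comps), mass_density=densities.get(name))
        for name, comps in grouped.items()
    ]


def write_recipe_csv(path, recipes: Iterable[Recipe]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["material", "component", "grams"])
        for recipe in recipes:
            for compound, mass in recipe.components:
                name = compound.name if isinstance(compound, CompoundSpec) else compound
                writer.writerow([recipe.material_name, name, f"{mass:g}"])


def read_composition_csv(
    path, densities: Mapping[str, float] | None = None,
    provenance: str = "from_table",
) -> list[ElementalComposition]:
    """Read compositions from a CSV with columns ``material,element,weight_fraction``."""
    try:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    except OSError as exc:
        raise DataLoadError(f"cannot read composition file {path}: {exc}") from exc
    if not rows or not {"material", "element", "weight_fraction"} <= set(rows[0]):
        raise DataLoadError(
            f"composition file {path} must have columns material,element,weight_fraction"
        )
    grouped: dict[str, dict[str, float]] = {}
    for row in rows:
        get_element(row["element"], f"in {path}")
        grouped.setdefault(row["material"], {})[row["element"]] = float(
            row["weight_fraction"]
        )
    densities = densities or {}
    return [
        ElementalComposition(name, fracs, densities.get(name), provenance)
        for name, fracs in grouped.items()
    ]


def write_composition_csv(path, compositions: Iterable[ElementalComposition]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["material", "element", "weight_fraction"])
        for comp in compositions:
            for sym, w in comp.weight_fractions.items():
                writer.writerow([comp.material_name, sym, repr(float(w))])
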