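"""Ionizing-radiation metrics for elemental mixtures.

Implements the standard dosimetric characterization of a material given its
elemental weight fractions w_i and mass density rho_m:

* mean atomic-number-to-weight ratio  <Z/A> = sum_i w_i Z_i / A_i
* electron density                    n_e = rho_m * N_A * <Z/A>   [e-/cm^3]
* effective atomic number             Z_eff = (sum_n a_n Z_n^p)^(1/p)
  with p = 2.94 and a_n the fraction each element contributes to the total
  electron count (the power-law form used for photoelectric-dominated
  diagnostic energies)
* mixture-rule mass attenuation       (mu/rho)_mix(E) = sum_i w_i (mu/rho)_i(E)
  on a 10-150 keV grid, with elemental values log-log interpolated from the
  packaged table, plus the derived linear attenuation and a single-energy
  CT-number prediction relative to water.

Weight fractions are normalized by their stored total before every metric,
so results are invariant under renormalization of the input row.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .chem_core import (
    CompoundSpec,
    ElementalComposition,
    _data_file,
    element_mass_fractions,
    get_element,
)
from .errors import (
    DataLoadError,
    EnergyRangeError,
    InvalidInputError,
    MissingDensityError,
    UnknownElementError,
)

#: CODATA-exact Avogadro constant, 1/mol
AVOGADRO = 6.02214076e23
#: exponent of the effective-atomic-number power law
DEFAULT_ZEFF_EXPONENT = 2.94


@dataclass(frozen=True)
class PhysicalConstants:
    avogadro: float = AVOGADRO
    zeff_exponent: float = DEFAULT_ZEFF_EXPONENT


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class EnergyGrid:
    """Strictly increasing photon energies in keV."""

    energies: tuple

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or len(e) == 0:
            raise InvalidInputError("energy grid must be a non-empty 1-D sequence")
        if not np.all(np.diff(e) > 0):
            raise InvalidInputError("energy grid must be strictly increasing")
        object.__setattr__(self, "energies", tuple(e.tolist()))

    @classmethod
    def default(cls, start: float = 10.0, stop: float = 150.0, step: float = 1.0):
        """Diagnostic energy range, 10-150 keV inclusive at 1 keV steps."""
        n = int(round((stop - start) / step)) + 1
        return cls(tuple(np.linspace(start, stop, n).tolist()))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.energies, dtype=float)

    def __len__(self):
        return len(self.energies)


class AttenuationTable:
    """Per-element tabulated mass attenuation mu/rho(E), cm^2/g.

    Queries use log-log linear interpolation, exact at tabulation points;
    energies outside an element's tabulated support raise
    :class:`EnergyRangeError`.
    """

    def __init__(self, data: Mapping[str, tuple]):
        if not data:
            raise InvalidInputError("attenuation table has no elements")
        self._data = {}
        for sym, (energies, values) in data.items():
            e = np.asarray(energies, dtype=float)
            v = np.asarray(values, dtype=float)
            if len(e) < 2 or len(e) != len(v):
                raise InvalidInputError(
                    f"attenuation table for {sym!r} needs >= 2 matched points"
                )
            if not np.all(np.diff(e) > 0):
                raise InvalidInputError(
                    f"attenuation energies for {sym!r} must be strictly increasing"
                )
            if not np.all(v > 0):
                raise InvalidInputError(
                    f"attenuation values for {sym!r} must be positive"
                )
            self._data[sym] = (e, v)

    @property
    def elements(self) -> list[str]:
        return list(self._data)

    def tabulation(self, element: str) -> tuple[np.ndarray, np.ndarray]:
        if element not in self._data:
            raise UnknownElementError(element, "not in attenuation table")
        e, v = self._data[element]
        return e.copy(), v.copy()

    def interpolate(self, element: str, energy) -> np.ndarray | float:
        """Log-log interpolated mu/rho for one element; scalar in, scalar out."""
        if element not in self._data:
            raise UnknownElementError(element, "not in attenuation table")
        e, v = self._data[element]
        energy_arr = np.atleast_1d(np.asarray(energy, dtype=float))
        if np.any(energy_arr < e[0]) or np.any(energy_arr > e[-1]):
            raise EnergyRangeError(
                f"energy out of tabulated range [{e[0]:g}, {e[-1]:g}] keV "
                f"for element {element!r}"
            )
        out = np.exp(np.interp(np.log(energy_arr), np.log(e), np.log(v)))
        return float(out[0]) if np.isscalar(energy) or np.ndim(energy) == 0 else out

    @classmethod
    def from_csv(cls, path) -> "AttenuationTable":
        """Load a table from CSV columns ``element,energy_keV,mac_cm2_per_g``."""
        try:
            with open(path, newline="") as fh:
                rows = list(csv.DictReader(fh))
        except OSError as exc:
            raise DataLoadError(f"cannot read attenuation table {path}: {exc}") from exc
        if not rows or not {"element", "energy_keV", "mac_cm2_per_g"} <= set(rows[0]):
            raise DataLoadError(
                f"attenuation table {path} must have columns "
                "element,energy_keV,mac_cm2_per_g"
            )
        grouped: dict[str, list] = {}
        for row in rows:
            grouped.setdefault(row["element"], []).append(
                (float(row["energy_keV"]), float(row["mac_cm2_per_g"]))
            )
        data = {}
        for sym, pts in grouped.items():
            pts.sort()
            data[sym] = ([p[0] for p in pts], [p[1] for p in pts])
        return cls(data)


@lru_cache(maxsize=1)
def default_attenuation_table() -> AttenuationTable:
    """The packaged elemental table (13 elements, 5-200 keV)."""
    return AttenuationTable.from_csv(_data_file("xcom_mac.csv"))


def interpolate_elemental_mac(table: AttenuationTable, element: str, energy):
    """Functional alias for :meth:`AttenuationTable.interpolate`."""
    return table.interpolate(element, energy)


@dataclass(frozen=True)
class MacCurve:
    """An attenuation curve on an energy grid (cm^2/g, or 1/cm when scaled)."""

    material_name: str
    grid: EnergyGrid
    values: tuple
    units: str = "cm^2/g"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if len(v) != len(self.grid):
            raise InvalidInputError(
                f"curve for {self.material_name!r}: {len(v)} values on a "
                f"{len(self.grid)}-point grid"
            )
        if not np.all(v > 0):
            raise InvalidInputError(
                f"curve for {self.material_name!r} must be positive everywhere"
            )
        object.__setattr__(self, "values", tuple(v.tolist()))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


# ---------------------------------------------------------------------------
# scalar metrics

def _normalized_fractions(comp: ElementalComposition) -> dict[str, float]:
    total = comp.total
    if total <= 0:
        raise InvalidInputError(
            f"composition {comp.material_name!r} has no positive weight"
        )
    return {s: w / total for s, w in comp.weight_fractions.items() if w > 0}


def mean_z_over_a(comp: ElementalComposition) -> float:
    """Mass-fraction-weighted mean Z/A; in (0, 1] for real elements."""
    return sum(
        w * get_element(s, f"in {comp.material_name!r}").atomic_number
        / get_element(s).atomic_weight
        for s, w in _normalized_fractions(comp).items()
    )


def electron_density(
    comp: ElementalComposition, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Electrons per cm^3: rho_m * N_A * <Z/A>."""
    if comp.mass_density is None:
        raise MissingDensityError(comp.material_name)
    return comp.mass_density * constants.avogadro * mean_z_over_a(comp)


def electron_fractions(comp: ElementalComposition) -> dict[str, float]:
    """Fraction of the mixture's electrons contributed by each element."""
    za = {
        s: w * get_element(s, f"in {comp.material_name!r}").atomic_number
        / get_element(s).atomic_weight
        for s, w in _normalized_fractions(comp).items()
    }
    total = sum(za.values())
    return {s: v / total for s, v in za.items()}


def effective_atomic_number(
    comp: ElementalComposition, exponent: float = DEFAULT_ZEFF_EXPONENT
) -> float:
    """Power-law effective atomic number over electron fractions.

    Bounded by the smallest and largest Z present; equals Z exactly for a
    single-element material at any exponent.
    """
    if exponent <= 0:
        raise InvalidInputError("Z_eff exponent must be positive")
    total = sum(
        a * get_element(s).atomic_number ** exponent
        for s, a in electron_fractions(comp).items()
    )
    return total ** (1.0 / exponent)


# ---------------------------------------------------------------------------
# attenuation curves

def mixture_mac(
    comp: ElementalComposition,
    grid: EnergyGrid | None = None,
    table: AttenuationTable | None = None,
) -> MacCurve:
    """Weight-fraction-weighted sum of elemental attenuation curves."""
    grid = grid or EnergyGrid.default()
    table = table or default_attenuation_table()
    energies = grid.as_array()
    values = np.zeros_like(energies)
    for sym, w in _normalized_fractions(comp).items():
        try:
            values += w * table.interpolate(sym, energies)
        except UnknownElementError:
            raise UnknownElementError(
                sym, f"required by material {comp.material_name!r}"
            ) from None
    return MacCurve(comp.material_name, grid, tuple(values.tolist()))


def linear_attenuation(curve: MacCurve, density: float) -> MacCurve:
    """mu(E) = (mu/rho)(E) * rho, in 1/cm."""
    if density <= 0:
        raise InvalidInputError("density must be positive")
    return MacCurve(
        curve.material_name,
        curve.grid,
        tuple(density * v for v in curve.values),
        units="1/cm",
    )


def water_composition(density: float = 1.0) -> ElementalComposition:
    """Liquid water from its formula; the CT-number reference material."""
    return ElementalComposition(
        "water",
        element_mass_fractions(CompoundSpec.from_formula("water", "H2O")),
        mass_density=density,
        provenance="synthetic",
    )


def predicted_hu(
    comp: ElementalComposition,
    energy: float = 70.0,
    table: AttenuationTable | None = None,
    water: ElementalComposition | None = None,
) -> float:
    """Monoenergetic CT number: 1000 * (mu - mu_water) / mu_water.

    A single effective energy (default 70 keV) stands in for the scanner
    spectrum, so this is an indicative value for ranking materials, not a
    prediction of any particular acquisition.
    """
    table = table or default_attenuation_table()
    water = water or water_composition()
    if comp.mass_density is None:
        raise MissingDensityError(comp.material_name)
    if water.mass_density is None:
        raise MissingDensityError(water.material_name)
    mu = comp.mass_density * sum(
        w * table.interpolate(s, energy)
        for s, w in _normalized_fractions(comp).items()
    )
    mu_w = water.mass_density * sum(
        w * table.interpolate(s, energy)
        for s, w in _normalized_fractions(water).items()
    )
    return 1000.0 * (mu - mu_w) / mu_w


# ---------------------------------------------------------------------------
# characterization bundle

@dataclass(frozen=True)
class CharacterizationResult:
    """The scalar radiological summary of one material."""

    material_name: str
    z_over_a: float
    electron_density: float | None  # e-/cm^3; None when no density is set
    z_eff: float
    mac: MacCurve | None = None


def characterize(
    comp: ElementalComposition,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    grid: EnergyGrid | None = None,
    table: AttenuationTable | None = None,
    with_mac: bool = False,
) -> CharacterizationResult:
    """Compute <Z/A>, n_e, Z_eff (and optionally the MAC curve) for one material."""
    ne = None
    if comp.mass_density is not None:
        ne = electron_density(comp, constants)
    mac = mixture_mac(comp, grid, table) if with_mac else None
    return CharacterizationResult(
        material_name=comp.material_name,
        z_over_a=mean_z_over_a(comp),
        electron_density=ne,
        z_eff=effective_atomic_number(comp, constants.zeff_exponent),
        mac=mac,
    )
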