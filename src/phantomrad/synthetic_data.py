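"""Synthetic generators and brute-force oracles.

Random recipes over the packaged compound palette make every pipeline stage
testable without external data, and the oracles recompute compositions and
radiological metrics by an independent route (explicit atom/electron
bookkeeping, no reuse of the weight-fraction algebra) so the two code paths
can be compared to near machine precision.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .chem_core import (
    CompoundSpec,
    ElementalComposition,
    Recipe,
    compound_database,
    get_element,
)
from .errors import InvalidInputError
from .radiometrics import AVOGADRO, DEFAULT_ZEFF_EXPONENT, AttenuationTable


def default_palette() -> tuple[CompoundSpec, ...]:
    """All compounds in the packaged database, in file order."""
    return tuple(compound_database().values())


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the random-recipe generator.

    Defaults mirror the fabricated recipes: a handful of components drawn
    from the same 14-compound palette, masses on the gram scale used on the
    bench, and densities bracketing soft tissue.
    """

    seed: int = 0
    n_components: int = 4
    compound_palette: tuple = ()
    mass_range: tuple = (0.5, 200.0)  # grams
    density_range: tuple = (0.9, 1.1)  # g/cm^3

    def __post_init__(self):
        if self.n_components < 1:
            raise InvalidInputError("n_components must be >= 1")
        for lo, hi in (self.mass_range, self.density_range):
            if not (0 < lo <= hi):
                raise InvalidInputError("ranges must be positive and ordered")
        if not self.compound_palette:
            object.__setattr__(self, "compound_palette", default_palette())


def random_recipe(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> Recipe:
    """One reproducible random recipe; same spec (and no rng) -> same recipe."""
    if not spec.compound_palette:
        raise InvalidInputError("compound palette is empty")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    k = min(spec.n_components, len(spec.compound_palette))
    idx = rng.choice(len(spec.compound_palette), size=k, replace=False)
    masses = rng.uniform(*spec.mass_range, size=k)
    density = float(rng.uniform(*spec.density_range))
    components = tuple(
        (spec.compound_palette[i], float(m)) for i, m in zip(idx, masses)
    )
    return Recipe(f"synthetic-{spec.seed}", components, mass_density=density)


def random_recipes(spec: SyntheticSpec, n: int) -> list[Recipe]:
    """``n`` recipes from one generator stream seeded by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(n):
        r = random_recipe(spec, rng)
        out.append(Recipe(f"synthetic-{spec.seed}-{i}", r.components, r.mass_density))
    return out


# ---------------------------------------------------------------------------
# brute-force oracles

def _atom_moles(recipe: Recipe) -> dict[str, float]:
    """Moles of each element in the recipe, by explicit atom enumeration."""
    moles: dict[str, float] = {}
    for compound, mass in recipe.components:
        if not isinstance(compound, CompoundSpec):
            raise InvalidInputError(
                "oracle paths require resolved CompoundSpec components"
            )
        # molar mass recomputed inline: independent of chem_core.molar_mass use
        denom = sum(
            c * get_element(s).atomic_weight for s, c in compound.element_counts.items()
        )
        compound_moles = mass / denom
        for sym, count in compound.element_counts.items():
            moles[sym] = moles.get(sym, 0.0) + compound_moles * count
    return moles


def oracle_composition(recipe: Recipe) -> ElementalComposition:
    """Elemental weight fractions via atom-by-atom mass accumulation."""
    total = recipe.total_mass
    if total <= 0:
        raise InvalidInputError(
            f"recipe {recipe.material_name!r} has zero total mass"
        )
    masses = {
        sym: n * get_element(sym).atomic_weight
        for sym, n in _atom_moles(recipe).items()
    }
    grand = sum(masses.values())
    return ElementalComposition(
        material_name=recipe.material_name,
        weight_fractions={s: m / grand for s, m in masses.items()},
        mass_density=recipe.mass_density,
        provenance="from_recipe",
    )


def _electron_moles(obj: Union[Recipe, ElementalComposition]) -> dict[str, float]:
    if isinstance(obj, Recipe):
        atom = _atom_moles(obj)
    else:
        # per gram of material: w_e / A_e moles of atoms of each element
        atom = {
            s: w / get_element(s).atomic_weight
            for s, w in obj.weight_fractions.items()
            if w > 0
        }
    return {s: n * get_element(s).atomic_number for s, n in atom.items()}


def oracle_z_over_a(obj: Union[Recipe, ElementalComposition]) -> float:
    """<Z/A> as total electrons over total nucleon-scale mass."""
    electrons = _electron_moles(obj)
    if isinstance(obj, Recipe):
        mass = sum(
            n * get_element(s).atomic_weight for s, n in _atom_moles(obj).items()
        )
    else:
        mass = sum(w for w in obj.weight_fractions.values() if w > 0)
    return sum(electrons.values()) / mass


def oracle_electron_density(obj: Union[Recipe, ElementalComposition]) -> float:
    density = obj.mass_density
    if density is None:
        raise InvalidInputError(f"{obj.material_name!r} has no density for the oracle")
    return density * AVOGADRO * oracle_z_over_a(obj)


def oracle_zeff(
    obj: Union[Recipe, ElementalComposition],
    exponent: float = DEFAULT_ZEFF_EXPONENT,
) -> float:
    """Effective atomic number evaluated on raw electron counts."""
    electrons = _electron_moles(obj)
    total = sum(electrons.values())
    acc = sum(
        (n / total) * get_element(s).atomic_number ** exponent
        for s, n in electrons.items()
    )
    return acc ** (1.0 / exponent)


# ---------------------------------------------------------------------------
# synthetic attenuation tables

def synthetic_attenuation_table(
    seed: int,
    elements: Sequence[str],
    n_points: int = 30,
    energy_range: tuple = (5.0, 200.0),
) -> tuple[AttenuationTable, dict[str, tuple[float, float]]]:
    """Exact power-law curves mu/rho = c * E^(-k) per element.

    Being exactly log-log linear, interpolated values have the closed form
    c * E^(-k) at every energy, and every curve is strictly decreasing.
    Returns the table together with the (c, k) parameters per element.
    """
    if not elements:
        raise InvalidInputError("element list is empty")
    rng = np.random.default_rng(seed)
    energies = np.geomspace(*energy_range, n_points)
    data = {}
    params = {}
    for sym in elements:
        c = float(10.0 ** rng.uniform(-1, 1))
        k = float(rng.uniform(0.5, 3.0))
        data[sym] = (energies, c * energies ** (-k))
        params[sym] = (c, k)
    return AttenuationTable(data), params
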