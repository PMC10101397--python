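"""Electron density, effective atomic number, and attenuation curves."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from phantomrad import (
    AttenuationTable,
    EnergyGrid,
    PhysicalConstants,
    characterize,
    effective_atomic_number,
    electron_density,
    electron_fractions,
    linear_attenuation,
    mean_z_over_a,
    mixture_mac,
    predicted_hu,
    water_composition,
)
from phantomrad.chem_core import ElementalComposition
from phantomrad.errors import (
    EnergyRangeError,
    InvalidInputError,
    MissingDensityError,
    UnknownElementError,
)
from phantomrad.synthetic_data import (
    SyntheticSpec,
    oracle_composition,
    random_recipes,
    synthetic_attenuation_table,
)


def comp(fracs, density=None, name="test"):
    return ElementalComposition(name, fracs, density, "synthetic")


class TestScalarMetrics:
    def test_single_element_z_over_a(self):
        assert mean_z_over_a(comp({"H": 1.0})) == pytest.approx(1 / 1.008, rel=1e-9)
        assert mean_z_over_a(comp({"O": 1.0})) == pytest.approx(8 / 15.999, rel=1e-9)

    def test_skin_tmm_z_over_a(self, tmm_compositions):
        assert mean_z_over_a(tmm_compositions["skin"]) == pytest.approx(0.5481, abs=5e-4)

    def test_electron_density_examples(self, tmm_compositions):
        assert electron_density(tmm_compositions["skin"]) == pytest.approx(
            3.59776e23, rel=5e-3
        )
        assert electron_density(tmm_compositions["adipose"]) == pytest.approx(
            3.19937e23, rel=5e-3
        )

    def test_electron_density_linear_in_density(self):
        c1 = comp({"H": 0.1119, "O": 0.8881}, density=1.0)
        c2 = comp({"H": 0.1119, "O": 0.8881}, density=2.0)
        assert electron_density(c2) == pytest.approx(
            2 * electron_density(c1), rel=1e-14
        )

    def test_electron_density_invariant_under_renormalization(self):
        a = comp({"H": 0.1119, "O": 0.8881}, density=1.0)
        b = comp({"H": 0.1119 / 2, "O": 0.8881 / 2}, density=1.0)
        assert electron_density(a) == pytest.approx(electron_density(b), rel=1e-14)

    def test_missing_density_names_material(self):
        with pytest.raises(MissingDensityError, match="nameless"):
            electron_density(comp({"H": 1.0}, name="nameless"))

    def test_unknown_element_rejected(self):
        with pytest.raises(UnknownElementError):
            mean_z_over_a(comp({"Zz": 1.0}))

    def test_electron_fractions(self):
        assert electron_fractions(comp({"O": 1.0})) == {"O": 1.0}
        water = electron_fractions(comp({"H": 0.1119, "O": 0.8881}))
        assert water["H"] == pytest.approx(0.200, abs=1e-3)
        assert water["O"] == pytest.approx(0.800, abs=1e-3)
        assert sum(water.values()) == pytest.approx(1.0, abs=1e-12)
        half = electron_fractions(comp({"H": 0.5, "O": 0.5}))
        assert half["H"] == pytest.approx(0.665, abs=1e-3)

    @pytest.mark.parametrize("exponent", [1.0, 2.94, 3.5])
    @pytest.mark.parametrize("element,z", [("H", 1), ("O", 8), ("Ca", 20)])
    def test_zeff_single_element_identity(self, element, z, exponent):
        assert effective_atomic_number(
            comp({element: 1.0}), exponent
        ) == pytest.approx(z, rel=1e-12)

    def test_zeff_water(self):
        assert effective_atomic_number(
            comp({"H": 0.1119, "O": 0.8881})
        ) == pytest.approx(7.42, abs=0.01)

    def test_zeff_icru_adipose(self, icru_compositions):
        assert effective_atomic_number(icru_compositions["adipose"]) == pytest.approx(
            6.330516684, rel=5e-3
        )

    def test_zeff_bounded_by_present_z(self, tmm_compositions):
        for c in tmm_compositions.values():
            zeff = effective_atomic_number(c)
            zs = [
                {"H": 1, "C": 6, "N": 7, "O": 8, "Na": 11, "Mg": 12, "Al": 13,
                 "Si": 14, "P": 15, "S": 16, "Cl": 17, "K": 19, "Ca": 20}[el]
                for el in c.elements()
            ]
            assert min(zs) <= zeff <= max(zs)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_zeff_increases_with_high_z_trace(self, seed):
        recipe = random_recipes(SyntheticSpec(seed=seed, n_components=3), 1)[0]
        base = oracle_composition(recipe).weight_fractions
        if "Ca" in base:
            return
        spiked = {el: 0.99 * w for el, w in base.items()}
        spiked["Ca"] = 0.01
        assert effective_atomic_number(comp(spiked)) > effective_atomic_number(
            comp(base)
        )


class TestInterpolation:
    def test_exact_at_tabulation_points(self, mac_table):
        for element in ("H", "O", "Cl"):
            energies, values = mac_table.tabulation(element)
            got = mac_table.interpolate(element, energies)
            np.testing.assert_allclose(got, values, rtol=1e-12)

    def test_between_points_brackets(self, mac_table):
        energies, values = mac_table.tabulation("O")
        mid = 0.5 * (energies[3] + energies[4])
        got = mac_table.interpolate("O", mid)
        lo, hi = sorted((values[3], values[4]))
        assert lo < got < hi

    def test_geometric_midpoint_closed_form(self):
        table, params = synthetic_attenuation_table(seed=3, elements=["H", "O"])
        c, k = params["O"]
        energies, _ = table.tabulation("O")
        e_mid = float(np.sqrt(energies[0] * energies[1]))
        assert table.interpolate("O", e_mid) == pytest.approx(
            c * e_mid ** (-k), rel=1e-12
        )

    def test_out_of_range_rejected(self, mac_table):
        with pytest.raises(EnergyRangeError):
            mac_table.interpolate("O", 1.0)
        with pytest.raises(EnergyRangeError):
            mac_table.interpolate("O", 500.0)

    def test_missing_element_rejected(self, mac_table):
        with pytest.raises(UnknownElementError):
            mac_table.interpolate("Fe", 50.0)


class TestMixtureMac:
    def test_single_element_collapses(self, mac_table):
        grid = EnergyGrid.default()
        curve = mixture_mac(comp({"O": 1.0}), grid, mac_table)
        np.testing.assert_allclose(
            curve.as_array(),
            mac_table.interpolate("O", grid.as_array()),
            rtol=1e-12,
        )

    def test_fifty_fifty_mixture_is_mean(self, mac_table):
        grid = EnergyGrid.default()
        mix = mixture_mac(comp({"H": 0.5, "C": 0.5}), grid, mac_table).as_array()
        mean = 0.5 * (
            mac_table.interpolate("H", grid.as_array())
            + mac_table.interpolate("C", grid.as_array())
        )
        np.testing.assert_allclose(mix, mean, rtol=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 0.7, 1.0])
    def test_linearity_in_weight_fractions(
        self, alpha, tmm_compositions, icru_compositions, mac_table
    ):
        grid = EnergyGrid.default()
        a = tmm_compositions["skin"].normalized()
        b = icru_compositions["skin"].normalized()
        blend_fracs = {
            el: alpha * a.weight_fractions.get(el, 0.0)
            + (1 - alpha) * b.weight_fractions.get(el, 0.0)
            for el in set(a.weight_fractions) | set(b.weight_fractions)
        }
        blend = mixture_mac(
            comp({e: w for e, w in blend_fracs.items() if w > 0}), grid, mac_table
        ).as_array()
        expected = (
            alpha * mixture_mac(a, grid, mac_table).as_array()
            + (1 - alpha) * mixture_mac(b, grid, mac_table).as_array()
        )
        np.testing.assert_allclose(blend, expected, rtol=1e-12)

    def test_all_packaged_curves_strictly_decreasing(
        self, mac_table, tmm_compositions, icru_compositions
    ):
        grid = EnergyGrid.default()
        for element in mac_table.elements:
            vals = mac_table.interpolate(element, grid.as_array())
            assert np.all(np.diff(vals) < 0), element
        for c in list(tmm_compositions.values()) + list(icru_compositions.values()):
            vals = mixture_mac(c, grid, mac_table).as_array()
            assert np.all(np.diff(vals) < 0), c.material_name

    def test_unknown_element_names_material(self, mac_table):
        table, _ = synthetic_attenuation_table(seed=0, elements=["H"])
        with pytest.raises(UnknownElementError, match="watery"):
            mixture_mac(comp({"H": 0.1, "O": 0.9}, name="watery"), table=table)


class TestLinearAttenuationAndHu:
    def test_unit_density_identity(self, mac_table):
        curve = mixture_mac(water_composition(), table=mac_table)
        mu = linear_attenuation(curve, 1.0)
        np.testing.assert_allclose(mu.as_array(), curve.as_array(), rtol=1e-15)
        assert mu.units == "1/cm"

    def test_density_doubling(self, mac_table):
        curve = mixture_mac(water_composition(), table=mac_table)
        np.testing.assert_allclose(
            linear_attenuation(curve, 2.0).as_array(),
            2 * linear_attenuation(curve, 1.0).as_array(),
            rtol=1e-15,
        )
        with pytest.raises(InvalidInputError):
            linear_attenuation(curve, 0.0)

    def test_water_is_zero_hu(self):
        assert predicted_hu(water_composition()) == 0.0

    def test_vanishing_density_approaches_air_hu(self):
        ghost = comp({"H": 0.1119, "O": 0.8881}, density=1e-9)
        assert predicted_hu(ghost) == pytest.approx(-1000.0, abs=1e-5)

    def test_adipose_tmm_is_negative_hu(self, tmm_compositions):
        hu = predicted_hu(tmm_compositions["adipose"], energy=70.0)
        assert hu < 0


def test_characterize_bundles_consistently(tmm_compositions):
    res = characterize(tmm_compositions["skin"], with_mac=True)
    assert res.electron_density == pytest.approx(
        tmm_compositions["skin"].mass_density
        * PhysicalConstants().avogadro
        * res.z_over_a,
        rel=1e-14,
    )
    assert res.mac is not None and len(res.mac.values) == len(res.mac.grid)


def test_energy_grid_validation():
    assert len(EnergyGrid.default()) == 141
    assert EnergyGrid.default().energies[0] == 10.0
    assert EnergyGrid.default().energies[-1] == 150.0
    with pytest.raises(InvalidInputError):
        EnergyGrid((10.0, 10.0, 20.0))


def test_attenuation_table_validation():
    with pytest.raises(InvalidInputError):
        AttenuationTable({"H": ([10.0, 20.0], [1.0, -1.0])})
    with pytest.raises(InvalidInputError):
        AttenuationTable({})
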