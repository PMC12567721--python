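"""Headspace physics: ideal-gas mass, Raoult mole-fraction adjustment, importer."""

import pytest

from odorsafe import (
    ChemicalRecord,
    HeadspaceScenario,
    InputError,
    LoadError,
    adjusted_headspace_mass,
    headspace_mass,
    mole_fraction,
    parse_epi_suite_vp,
    partial_pressure,
)


class TestHeadspaceMass:
    def test_rose_oxide_reference_value(self):
        """0.657 mmHg, 154.25 g/mol, 0.1 L, 298 K -> 546 ug within 0.5 %."""
        mass = headspace_mass(0.657, 154.25, HeadspaceScenario())
        assert mass == pytest.approx(546, rel=0.005)

    def test_zero_vapor_pressure_gives_zero_mass(self):
        assert headspace_mass(0.0, 154.25) == 0.0

    def test_hand_arithmetic_oracle(self):
        # 7.6*0.001316*100*0.1*1e6 / (0.082*298), frozen by hand
        assert headspace_mass(7.6, 100.0) == pytest.approx(4093.1, rel=1e-3)

    def test_constants_modes_agree_within_0p2_percent(self):
        printed = headspace_mass(0.657, 154.25, HeadspaceScenario(constants_mode="paper_printed"))
        precise = headspace_mass(0.657, 154.25, HeadspaceScenario(constants_mode="high_precision"))
        assert abs(printed - precise) / precise < 0.002

    @pytest.mark.parametrize("vp,mw", [(-1.0, 100.0), (1.0, 0.0), (1.0, -5.0)])
    def test_invalid_inputs_rejected(self, vp, mw):
        with pytest.raises(InputError):
            headspace_mass(vp, mw)

    def test_scenario_invariants(self):
        with pytest.raises(InputError):
            HeadspaceScenario(volume_L=0.0)
        with pytest.raises(InputError):
            HeadspaceScenario(temperature_K=-1.0)
        with pytest.raises(InputError):
            HeadspaceScenario(constants_mode="nonsense")

    def test_nonstandard_temperature_warns(self, caplog):
        with caplog.at_level("WARNING"):
            HeadspaceScenario(temperature_K=310.0)
        assert any("298" in r.message for r in caplog.records)


class TestMoleFraction:
    def test_neat_solution_is_unity(self):
        assert mole_fraction(100.0, 154.25, "water") == 1.0

    def test_zero_concentration_is_zero(self):
        assert mole_fraction(0.0, 154.25, "water") == 0.0

    def test_one_percent_in_water(self):
        # (1/154.25) / (1/154.25 + 99/18.02), frozen by hand
        assert mole_fraction(1.0, 154.25, "water") == pytest.approx(0.0011786, rel=1e-3)

    def test_fifty_percent_ethanol_mw_in_water(self):
        # (50/46.07) / (50/46.07 + 50/18.02), frozen by hand
        assert mole_fraction(50.0, 46.07, "water") == pytest.approx(0.28117, rel=1e-3)

    def test_mixed_solvent_moles(self):
        # 50:50 ethanol/water has fewer moles/gram than water -> larger fraction
        x_w = mole_fraction(10.0, 154.25, "water")
        x_e = mole_fraction(10.0, 154.25, "ethanol_water_50_50")
        assert x_e > x_w

    def test_out_of_range_concentration_rejected(self):
        for bad in (-0.1, 100.1):
            with pytest.raises(InputError):
                mole_fraction(bad, 154.25, "water")


class TestPartialPressure:
    @pytest.mark.parametrize("x,vp,expected", [(1.0, 0.657, 0.657), (0.5, 0.657, 0.3285)])
    def test_linear_scaling(self, x, vp, expected):
        assert partial_pressure(x, vp) == pytest.approx(expected)

    def test_dilute_case(self):
        x = mole_fraction(1.0, 154.25, "water")
        assert partial_pressure(x, 0.657) == pytest.approx(7.75e-4, rel=1e-2)

    def test_bounds_enforced(self):
        with pytest.raises(InputError):
            partial_pressure(1.5, 1.0)


class TestAdjustedMass:
    def test_neat_limit_equals_neat_mass(self, rose_oxide, default_scenario):
        neat = headspace_mass(rose_oxide.vp_mmHg, rose_oxide.mw, default_scenario)
        adj = adjusted_headspace_mass(100.0, rose_oxide, "water", default_scenario)
        assert adj == pytest.approx(neat, rel=1e-12)
        assert adj == pytest.approx(546, rel=0.005)

    def test_zero_concentration_gives_zero(self, rose_oxide):
        assert adjusted_headspace_mass(0.0, rose_oxide, "water") == 0.0

    def test_composition_of_component_operations(self, default_scenario):
        rec = ChemicalRecord(id="e", name="ethanol", smiles="CCO", mw=46.07, vp_mmHg=10.0)
        x = mole_fraction(50.0, 46.07, "water")
        expected = x * headspace_mass(10.0, 46.07, default_scenario)
        got = adjusted_headspace_mass(50.0, rec, "water", default_scenario)
        assert got == pytest.approx(expected, rel=1e-12)


class TestEpiSuiteImporter:
    PREDICTED_ONLY = (
        "MPBPVP v1.43 output (synthetic example)\n"
        "  Vapor Pressure Estimations (25 deg C):\n"
        "  VP: 0.703 mm Hg (Antoine Method)\n"
        "  VP: 0.611 mm Hg (Grain Method)\n"
        "  Selected VP: 0.657 mm Hg (Mean of Antoine & Grain methods)\n"
    )
    WITH_EXPERIMENTAL = PREDICTED_ONLY + (
        "  Experimental Database:  VP = 0.900 mm Hg at 25 deg C\n"
    )

    def test_predicted_value_extracted(self):
        vp, source = parse_epi_suite_vp(self.PREDICTED_ONLY)
        assert vp == pytest.approx(0.657)
        assert source == "predicted"

    def test_experimental_preferred_when_present(self):
        vp, source = parse_epi_suite_vp(self.WITH_EXPERIMENTAL)
        assert vp == pytest.approx(0.900)
        assert source == "experimental"

    def test_missing_vp_is_load_error(self):
        with pytest.raises(LoadError):
            parse_epi_suite_vp("no vapor pressure here")
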